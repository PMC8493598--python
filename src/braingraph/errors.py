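"""Exception hierarchy shared across the pipeline stages."""


class BraingraphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BraingraphError, ValueError):
    """A numeric parameter is outside its documented valid range."""


class InputError(BraingraphError, ValueError):
    """Input data violate a structural precondition (shape, finiteness, ...)."""


class ConfigurationError(BraingraphError, ValueError):
    """A configuration file or mapping is malformed; message names the key."""


class SubjectExclusionError(BraingraphError):
    """Signal that a subject must be excluded (e.g. too few clean volumes).

    Mirrors the practice of dropping high-motion participants rather than
    producing unusable residuals; callers decide whether to drop or abort.
    """


class MetricUndefinedError(BraingraphError):
    """A graph metric is undefined on this input (e.g. Lp of an empty graph)."""
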