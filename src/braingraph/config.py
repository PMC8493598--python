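"""Pipeline configuration: a single YAML file holding every fixed constant.

All study constants (discard count, FD threshold and scrub window, band-pass
edges, TR, sparsity grid, null-ensemble size, FDR q) live here as defaults —
stage logic never hard-codes them. Configs round-trip losslessly through
YAML, and a stable hash of the canonical form is stamped on every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


def _from_mapping(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"{where}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    return cls(**data)


@dataclass
class PreprocessParams:
    n_discard: int = 10
    fd_threshold_mm: float = 0.2
    n_before: int = 1
    n_after: int = 2
    low_hz: float = 0.01
    high_hz: float = 0.08
    tr_s: float = 2.0
    min_dof: int = 10

    def validate(self):
        if self.n_discard < 0:
            raise ConfigurationError("preprocess.n_discard must be >= 0")
        if self.fd_threshold_mm <= 0:
            raise ConfigurationError("preprocess.fd_threshold_mm must be > 0")
        if not (0 < self.low_hz < self.high_hz < 0.5 / self.tr_s):
            raise ConfigurationError(
                "preprocess band must satisfy 0 < low_hz < high_hz < Nyquist"
            )


@dataclass
class NetworkParams:
    grid_start: float = 0.05
    grid_stop: float = 0.50
    grid_step: float = 0.01
    threshold_mode: str = "positive"   # or "absolute"

    def validate(self):
        if not (0 < self.grid_start < self.grid_stop < 1):
            raise ConfigurationError("network grid bounds must be in (0, 1)")
        if self.threshold_mode not in ("positive", "absolute"):
            raise ConfigurationError(
                "network.threshold_mode must be 'positive' or 'absolute'"
            )

    def grid(self):
        from .network import sparsity_grid
        return sparsity_grid(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class NullParams:
    n_null: int = 1000
    swaps_per_edge: int = 100

    def validate(self):
        if self.n_null < 1 or self.swaps_per_edge < 0:
            raise ConfigurationError("null params out of range")


@dataclass
class StatsParams:
    q: float = 0.05
    covariates: tuple = ("age", "gender", "mean_fd")
    clinical: tuple = ()
    patient_groups: tuple | None = None

    def validate(self):
        if not (0 < self.q < 1):
            raise ConfigurationError("stats.q must be in (0, 1)")


@dataclass
class CohortParams:
    """Synthetic-cohort design (see synthetic.CohortSpec for semantics)."""

    groups: list = field(default_factory=lambda: [["T2DM-C", 37], ["T2DM-NC", 30], ["HC", 41]])
    n_timepoints: int = 200
    n_rois: int = 116
    n_modules: int = 8
    r_within: float = 0.6
    r_between: float = 0.1
    group_effect: dict = field(
        default_factory=lambda: {"T2DM-C": 1.25, "T2DM-NC": 1.1, "HC": 1.0}
    )
    noise_sd: float = 0.2
    subject_sigma: float = 0.1
    spike_rate: float = 0.02
    spike_magnitude_mm: float = 0.5
    #: clinical covariates: name -> {mean, sd, partial_with, target_r};
    #: None keeps the generator's defaults
    covariate_model: dict | None = None

    def validate(self):
        if not (0 <= self.r_between <= self.r_within < 1):
            raise ConfigurationError(
                "cohort correlations must satisfy 0 <= r_between <= r_within < 1"
            )
        if self.covariate_model is not None:
            allowed = {"mean", "sd", "partial_with", "target_r"}
            for name, entry in self.covariate_model.items():
                if not isinstance(entry, dict) or not set(entry) <= allowed:
                    raise ConfigurationError(
                        f"cohort.covariate_model[{name!r}]: keys must be "
                        f"subset of {sorted(allowed)}"
                    )

    def to_spec(self, seed: int):
        from .synthetic import CohortSpec, CovariateSpec
        extra = {}
        if self.covariate_model is not None:
            extra["covariate_model"] = {
                name: CovariateSpec(**entry)
                for name, entry in self.covariate_model.items()
            }
        return CohortSpec(
            groups=tuple((g, int(n)) for g, n in self.groups),
            n_timepoints=self.n_timepoints,
            n_rois=self.n_rois,
            n_modules=self.n_modules,
            r_within=self.r_within,
            r_between=self.r_between,
            group_effect=dict(self.group_effect),
            noise_sd=self.noise_sd,
            subject_sigma=self.subject_sigma,
            spike_rate=self.spike_rate,
            spike_magnitude_mm=self.spike_magnitude_mm,
            seed=seed,
            **extra,
        )


@dataclass
class PipelineConfig:
    input_dir: str = "cohort"
    output_dir: str = "results"
    seed: int = 0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    nulls: NullParams = field(default_factory=NullParams)
    stats: StatsParams = field(default_factory=StatsParams)
    cohort: CohortParams = field(default_factory=CohortParams)

    def validate(self) -> "PipelineConfig":
        for section in (self.preprocess, self.network, self.nulls,
                        self.stats, self.cohort):
            section.validate()
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stats"]["covariates"] = list(self.stats.covariates)
        d["stats"]["clinical"] = list(self.stats.clinical)
        if self.stats.patient_groups is not None:
            d["stats"]["patient_groups"] = list(self.stats.patient_groups)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
        data = dict(data)
        sections = {
            "preprocess": PreprocessParams,
            "network": NetworkParams,
            "nulls": NullParams,
            "stats": StatsParams,
            "cohort": CohortParams,
        }
        kwargs = {}
        for key, scls in sections.items():
            if key in data:
                sub = data.pop(key)
                if key == "stats" and isinstance(sub, dict):
                    for tup_key in ("covariates", "clinical", "patient_groups"):
                        if tup_key in sub and sub[tup_key] is not None:
                            sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = _from_mapping(scls, sub, key)
        known = {"input_dir", "output_dir", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
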