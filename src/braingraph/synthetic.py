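"""Synthetic cohorts of ROI time series, motion traces, and covariates.

The generator emulates the data structure the analysis pipeline assumes: a
three-group cohort (two patient groups and healthy controls; default sizes
37/30/41), 200 volumes per subject at TR = 2 s of which the first 10 are
later discarded, and 116 regions whose signals follow a modular correlation
structure (blocks of regions with high within-module and low between-module
correlation). Group differences are expressed purely as a multiplicative
scaling of within-module correlation — a connectivity-topology effect, not a
mean-signal effect — so the downstream contrast isolates the mechanism of
interest. Motion traces are smooth low-amplitude drifts with occasional
one-volume translation spikes that the scrubbing stage must catch. Clinical
covariates can be tied to a named network metric at a target partial
correlation.

Everything is deterministic given the CohortSpec seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._aal import default_labels
from .errors import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)

#: metric AUCs a clinical covariate may be anchored to (computable without
#: null ensembles, so the pilot pass stays cheap)
ANCHORABLE_METRICS = ("Cp", "Lp", "Eg", "Eloc")


def default_partition(n_rois: int = 116, n_modules: int = 8) -> np.ndarray:
    """Module assignment: ``n_modules`` contiguous blocks of near-equal size.

    116 regions in 8 modules gives blocks of 14-15, which produce
    small-world binary graphs across the usual sparsity grid.
    """
    if n_modules < 1 or n_modules > n_rois:
        raise ParameterError("need 1 <= n_modules <= n_rois")
    sizes = np.full(n_modules, n_rois // n_modules)
    sizes[: n_rois % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def make_module_covariance(
    partition: np.ndarray, r_within: float, r_between: float
) -> np.ndarray:
    """Block-structured correlation matrix.

    Entry (i, j) is ``r_within`` when i and j share a module, ``r_between``
    otherwise, with unit diagonal. If the construction is not positive
    semi-definite (possible only for exotic parameter choices) it is
    projected to the nearest PSD matrix with unit diagonal and the
    adjustment is logged.
    """
    partition = np.asarray(partition)
    if partition.ndim != 1:
        raise ParameterError("partition must be 1-D")
    for name, v in (("r_within", r_within), ("r_between", r_between)):
        if not (0 <= v < 1):
            raise ParameterError(f"{name} must be in [0, 1), got {v}")
    same = partition[:, None] == partition[None, :]
    cov = np.where(same, r_within, r_between)
    np.fill_diagonal(cov, 1.0)
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        logger.warning(
            "module covariance not PSD (min eigenvalue %.3g); projecting",
            w.min(),
        )
        cov = nearest_psd_correlation(cov)
    return cov


def nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping followed by diagonal renormalization to 1."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() < -1e-8:
        raise ParameterError(
            f"covariance is not positive semi-definite (min eig {w.min():.3g})"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_subject_timeseries(
    cov: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """T x R draw with independent rows from N(0, cov)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    factor = _psd_factor(np.asarray(cov, dtype=float))
    z = rng.standard_normal((int(n_timepoints), cov.shape[0]))
    return z @ factor.T


def simulate_motion(
    n_timepoints: int,
    spike_rate: float = 0.02,
    spike_magnitude_mm: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """T x 6 rigid-body trace: bounded smooth drift plus one-volume spikes.

    Drift steps are clipped so that, with ``spike_rate = 0``, every FD value
    stays strictly below the 0.2 mm scrubbing threshold. A spike is a
    translation jump of ``spike_magnitude_mm`` on one random axis at one
    volume, returning to baseline at the next.
    """
    if not (0 <= spike_rate <= 1):
        raise ParameterError("spike_rate must be in [0, 1]")
    if spike_magnitude_mm < 0:
        raise ParameterError("spike_magnitude_mm must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = int(n_timepoints)
    # per-step drift: |FD contribution| <= 3*0.02 + 50*3*0.0004 = 0.12 < 0.2
    dt = np.clip(rng.normal(0.0, 0.005, size=(t, 3)), -0.02, 0.02)
    dr = np.clip(rng.normal(0.0, 1e-4, size=(t, 3)), -4e-4, 4e-4)
    motion = np.cumsum(np.hstack([dt, dr]), axis=0)
    motion[0] = 0.0
    spikes = rng.random(t) < spike_rate
    spikes[0] = False
    for v in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        motion[v, axis] += spike_magnitude_mm
    return motion


@dataclass(frozen=True)
class CovariateSpec:
    """One clinical covariate: its scale and an optional tie to a metric.

    When ``partial_with`` names a metric AUC (e.g. ``"Eloc"``), the
    covariate is constructed so its partial correlation with that subject-
    level metric is ``target_r`` in expectation.
    """

    mean: float
    sd: float
    partial_with: str | None = None
    target_r: float = 0.0


@dataclass
class CohortSpec:
    """Design of a synthetic cohort; defaults mirror the emulated study."""

    groups: tuple = (("T2DM-C", 37), ("T2DM-NC", 30), ("HC", 41))
    n_timepoints: int = 200
    n_rois: int = 116
    n_modules: int = 8
    module_partition: np.ndarray | None = None
    r_within: float = 0.6
    r_between: float = 0.1
    group_effect: dict = field(
        default_factory=lambda: {"T2DM-C": 1.25, "T2DM-NC": 1.1, "HC": 1.0}
    )
    noise_sd: float = 0.2
    subject_sigma: float = 0.1      # lognormal sd of per-subject connectivity scale
    spike_rate: float = 0.02
    spike_magnitude_mm: float = 0.5
    tr_s: float = 2.0
    age_mean: float = 54.0
    age_sd: float = 6.0
    covariate_model: dict = field(
        default_factory=lambda: {
            "HbA1c": CovariateSpec(mean=7.4, sd=1.8, partial_with="Eloc", target_r=0.5),
            "serum_creatinine": CovariateSpec(mean=57.5, sd=10.0),
        }
    )
    seed: int = 0

    def partition(self) -> np.ndarray:
        if self.module_partition is not None:
            p = np.asarray(self.module_partition)
            if p.size != self.n_rois:
                raise ParameterError("module_partition must cover every ROI exactly once")
            return p
        return default_partition(self.n_rois, self.n_modules)

    def validate(self) -> None:
        for name, v in (("r_within", self.r_within), ("r_between", self.r_between)):
            if not (0 <= v < 1):
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.r_within < self.r_between:
            raise ParameterError("r_within must be >= r_between")
        for label, n in self.groups:
            if n < 2:
                raise ParameterError(f"group {label!r} must have >= 2 subjects")
        for name, cs in self.covariate_model.items():
            if cs.partial_with is not None and cs.partial_with not in ANCHORABLE_METRICS:
                raise ConfigurationError(
                    f"covariate {name!r} targets unknown metric "
                    f"{cs.partial_with!r}; choose one of {ANCHORABLE_METRICS}"
                )
            if cs.partial_with is not None and not (-1 < cs.target_r < 1):
                raise ParameterError(f"target_r for {name!r} must be in (-1, 1)")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    timeseries: np.ndarray          # n_timepoints x n_rois
    motion: np.ndarray              # n_timepoints x 6
    wm_signal: np.ndarray
    csf_signal: np.ndarray
    covariates: dict


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]
    covariates: pd.DataFrame
    roi_labels: tuple[str, ...]


def _pilot_metric_auc(ts: np.ndarray, metric: str, grid=None) -> float:
    """AUC of a global metric computed directly on a raw simulated series.

    Used only to anchor clinical covariates; the real analysis recomputes
    metrics on preprocessed data.
    """
    from .metrics import auc, global_metrics_at
    from .network import build_stack, correlation_matrix, fisher_z, sparsity_grid

    if grid is None:
        grid = sparsity_grid()
    stack = build_stack(fisher_z(correlation_matrix(ts)), grid)
    vals = [global_metrics_at(adj)[metric] for _, adj in stack]
    return auc(vals, grid)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate every subject plus the cohort covariate table.

    Per-group covariance scales within-module correlation by
    ``group_effect[group]``; each subject additionally carries a lognormal
    connectivity jitter (sd ``subject_sigma``) that creates realistic
    between-subject metric variance. Metric-anchored clinical covariates are
    built in a pilot pass: the named metric AUC is computed on each raw
    series, standardized across the cohort, and the covariate is
    ``mean + sd * (r * z_metric + sqrt(1 - r^2) * noise)`` so the target
    (partial) correlation holds in expectation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    partition = spec.partition()
    labels = default_labels(spec.n_rois)

    subjects: list[SyntheticSubject] = []
    rows = []
    for g_label, g_n in spec.groups:
        scale = spec.group_effect.get(g_label, 1.0)  # absent group -> no effect
        for k in range(g_n):
            sid = f"sub-{g_label}-{k + 1:03d}"
            subj_scale = scale * float(
                np.exp(rng.normal(0.0, spec.subject_sigma))
            )
            rw = float(np.clip(spec.r_within * subj_scale, 0.0, 0.99))
            cov = make_module_covariance(partition, rw, spec.r_between)
            ts = simulate_subject_timeseries(cov, spec.n_timepoints, rng)
            ts = ts + rng.normal(0.0, spec.noise_sd, size=ts.shape)
            motion = simulate_motion(
                spec.n_timepoints, spec.spike_rate, spec.spike_magnitude_mm, rng
            )
            wm = rng.standard_normal(spec.n_timepoints)
            csf = rng.standard_normal(spec.n_timepoints)
            age = float(rng.normal(spec.age_mean, spec.age_sd))
            gender = "M" if rng.random() < 0.5 else "F"
            covs = {"age": age, "gender": gender}
            subjects.append(SyntheticSubject(sid, g_label, ts, motion, wm, csf, covs))
            rows.append({"subject_id": sid, "group": g_label, **covs})

    table = pd.DataFrame(rows)

    # pilot pass for metric-anchored clinical covariates
    anchored = {m for cs in spec.covariate_model.values()
                if (m := cs.partial_with) is not None}
    zscores = {}
    for m in anchored:
        vals = np.array([_pilot_metric_auc(s.timeseries, m) for s in subjects])
        zscores[m] = (vals - vals.mean()) / vals.std()
    for name, cs in spec.covariate_model.items():
        noise = rng.standard_normal(len(subjects))
        if cs.partial_with is None:
            vals = cs.mean + cs.sd * noise
        else:
            z = zscores[cs.partial_with]
            vals = cs.mean + cs.sd * (
                cs.target_r * z + np.sqrt(1 - cs.target_r**2) * noise
            )
        table[name] = vals
        for s, v in zip(subjects, vals):
            s.covariates[name] = float(v)

    return Cohort(spec=spec, subjects=subjects, covariates=table, roi_labels=labels)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write the cohort to disk and return the manifest (also saved as JSON).

    Per subject: ``<id>_timeseries.tsv`` (T x R, ROI-label header),
    ``<id>_motion.txt`` (T x 6, whitespace-separated, realignment-parameter
    dialect, no header), ``<id>_nuisance.tsv`` (wm, csf columns). Plus
    ``covariates.csv`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for s in cohort.subjects:
        ts_path = outdir / f"{s.subject_id}_timeseries.tsv"
        pd.DataFrame(s.timeseries, columns=list(cohort.roi_labels)).to_csv(
            ts_path, sep="\t", index=False, float_format="%.6f"
        )
        mot_path = outdir / f"{s.subject_id}_motion.txt"
        np.savetxt(mot_path, s.motion, fmt="%.8f")
        nui_path = outdir / f"{s.subject_id}_nuisance.tsv"
        pd.DataFrame({"wm": s.wm_signal, "csf": s.csf_signal}).to_csv(
            nui_path, sep="\t", index=False, float_format="%.6f"
        )
        files[s.subject_id] = {
            "group": s.group,
            "timeseries": ts_path.name,
            "motion": mot_path.name,
            "nuisance": nui_path.name,
        }
    cov_path = outdir / "covariates.csv"
    cohort.covariates.to_csv(cov_path, index=False)
    spec_dict = {
        "groups": [[label, n] for label, n in cohort.spec.groups],
        "n_timepoints": cohort.spec.n_timepoints,
        "n_rois": cohort.spec.n_rois,
        "n_modules": cohort.spec.n_modules,
        "r_within": cohort.spec.r_within,
        "r_between": cohort.spec.r_between,
        "group_effect": cohort.spec.group_effect,
        "noise_sd": cohort.spec.noise_sd,
        "subject_sigma": cohort.spec.subject_sigma,
        "spike_rate": cohort.spec.spike_rate,
        "spike_magnitude_mm": cohort.spec.spike_magnitude_mm,
        "tr_s": cohort.spec.tr_s,
        "seed": cohort.spec.seed,
    }
    manifest = {"spec": spec_dict, "covariates": cov_path.name, "subjects": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
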