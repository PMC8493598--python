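"""Time-series-level cleaning of regional BOLD signals.

The stage mirrors standard resting-state practice: drop the first volumes
acquired before signal equilibrium, quantify head motion as framewise
displacement (FD), flag high-motion volumes together with their temporal
neighbours ("scrubbing"), regress out a nuisance design (Friston-24 motion
expansion, per-volume spike indicators, linear trend, white-matter and CSF
signals, intercept), and finally band-pass filter the residuals. The fixed
order is: discard -> FD/scrub -> nuisance regression -> band-pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, SubjectExclusionError

logger = logging.getLogger(__name__)

#: rotations (radians) are converted to arc length on a sphere of this radius
HEAD_RADIUS_MM = 50.0


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise InputError(f"{name} must be a 2-D array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


def discard_initial_volumes(
    ts: np.ndarray, motion: np.ndarray, n_discard: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the first ``n_discard`` rows of the time series and motion trace.

    Both arrays must have the same number of rows; row counts stay equal.
    """
    ts = _as_2d(ts, "ts")
    motion = _as_2d(motion, "motion")
    if ts.shape[0] != motion.shape[0]:
        raise InputError(
            f"row mismatch: ts has {ts.shape[0]} volumes, motion {motion.shape[0]}"
        )
    if n_discard < 0:
        raise ParameterError("n_discard must be >= 0")
    if n_discard >= ts.shape[0]:
        raise InputError(
            f"cannot discard {n_discard} of {ts.shape[0]} volumes"
        )
    return ts[n_discard:], motion[n_discard:]


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Scalar framewise displacement per volume (mm).

    FD_t = sum of absolute backward differences of the three translations
    plus ``HEAD_RADIUS_MM`` times the summed absolute rotation differences
    (radians converted to displacement at the head surface). FD of the first
    volume is 0 by convention. Adding a constant offset to any motion column
    leaves FD unchanged.
    """
    motion = _as_2d(motion, "motion")
    if motion.shape[1] != 6:
        raise InputError(f"motion must have 6 columns, got {motion.shape[1]}")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return fd


def scrub_mask(
    fd: np.ndarray,
    threshold_mm: float = 0.2,
    n_before: int = 1,
    n_after: int = 2,
) -> np.ndarray:
    """Boolean mask of volumes to scrub (True = flagged).

    A volume is bad when its FD exceeds ``threshold_mm``; for every bad
    volume b the window {b - n_before, ..., b + n_after} is flagged as well,
    clipped to the series bounds.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1:
        raise InputError("fd must be 1-D")
    if np.any(fd < 0):
        raise InputError("fd values must be >= 0")
    if threshold_mm <= 0:
        raise ParameterError("threshold_mm must be > 0")
    if n_before < 0 or n_after < 0:
        raise ParameterError("scrub window sizes must be >= 0")
    mask = np.zeros(fd.size, dtype=bool)
    for b in np.flatnonzero(fd > threshold_mm):
        mask[max(0, b - n_before): min(fd.size, b + n_after + 1)] = True
    return mask


def friston24(motion: np.ndarray) -> pd.DataFrame:
    """Friston 24-parameter motion expansion.

    The 6 rigid-body parameters, their one-volume lags (first row zero),
    and the squares of both sets.
    """
    motion = _as_2d(motion, "motion")
    lag = np.vstack([np.zeros(6), motion[:-1]])
    names = [f"mot{i + 1}" for i in range(6)]
    cols = {}
    for i, n in enumerate(names):
        cols[n] = motion[:, i]
    for i, n in enumerate(names):
        cols[f"{n}_lag"] = lag[:, i]
    for i, n in enumerate(names):
        cols[f"{n}_sq"] = motion[:, i] ** 2
    for i, n in enumerate(names):
        cols[f"{n}_lag_sq"] = lag[:, i] ** 2
    return pd.DataFrame(cols)


def _drop_collinear(design: pd.DataFrame) -> pd.DataFrame:
    """Greedily keep columns that increase the design rank; log the rest.

    The intercept is always scanned first so degenerate (constant) motion
    columns collapse into it rather than the other way around.
    """
    x = design.to_numpy()
    keep: list[int] = []
    order = list(range(x.shape[1]))
    if "intercept" in design.columns:
        i0 = design.columns.get_loc("intercept")
        order.remove(i0)
        order.insert(0, i0)
    rank = 0
    for j in order:
        cand = x[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [design.columns[j] for j in range(x.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropped %d collinear design columns: %s",
                       len(dropped), ", ".join(dropped))
    keep_sorted = sorted(keep)
    return design.iloc[:, keep_sorted]


def build_nuisance_design(
    motion: np.ndarray,
    mask: np.ndarray,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> pd.DataFrame:
    """Nuisance regressor matrix with named columns.

    Columns: intercept, linear trend, Friston-24 motion expansion, one spike
    indicator per flagged volume, and (optionally) white-matter and CSF mean
    signals. Exactly collinear columns are dropped with a logged warning.
    """
    motion = _as_2d(motion, "motion")
    t = motion.shape[0]
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (t,):
        raise InputError("mask length must match motion rows")
    parts = [pd.DataFrame({"intercept": np.ones(t),
                           "trend": np.linspace(-0.5, 0.5, t)}),
             friston24(motion)]
    spikes = {}
    for v in np.flatnonzero(mask):
        col = np.zeros(t)
        col[v] = 1.0
        spikes[f"spike_t{v:04d}"] = col
    if spikes:
        parts.append(pd.DataFrame(spikes))
    for name, sig in (("wm", wm_signal), ("csf", csf_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float).ravel()
            if sig.size != t:
                raise InputError(f"{name} signal length {sig.size} != {t} volumes")
            parts.append(pd.DataFrame({name: sig}))
    design = pd.concat(parts, axis=1)
    return _drop_collinear(design)


def regress_nuisance(
    ts: np.ndarray, design: pd.DataFrame, min_dof: int = 10
) -> np.ndarray:
    """Per-region ordinary least-squares residuals against the design.

    Raises :class:`SubjectExclusionError` when fewer than ``min_dof``
    residual degrees of freedom remain — the analogue of dropping a subject
    whose scan is dominated by flagged volumes.
    """
    ts = _as_2d(ts, "ts")
    x = design.to_numpy() if isinstance(design, pd.DataFrame) else _as_2d(design, "design")
    if x.shape[0] != ts.shape[0]:
        raise InputError("design rows must match time-series rows")
    rank = np.linalg.matrix_rank(x)
    dof = ts.shape[0] - rank
    if dof < min_dof:
        raise SubjectExclusionError(
            f"only {dof} residual degrees of freedom (< {min_dof}); "
            "subject should be excluded"
        )
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)
    return ts - x @ beta


def bandpass_filter(
    ts: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_s: float = 2.0,
) -> np.ndarray:
    """Ideal (brick-wall) band-pass in the discrete Fourier domain.

    Frequency bins with ``low_hz <= f <= high_hz`` are retained, every other
    bin — including the DC component — is zeroed, so a constant series maps
    to zero. Output is real with the input's length.
    """
    ts = _as_2d(ts, "ts")
    nyquist = 0.5 / tr_s
    if not (0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist} Hz at TR = {tr_s} s"
        )
    t = ts.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_s)
    spec = np.fft.rfft(ts, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=0)


@dataclass
class PreprocessResult:
    """Cleaned time series plus the quality-control record for one subject."""

    timeseries: np.ndarray
    fd: np.ndarray
    mask: np.ndarray
    design_columns: list[str]
    mean_fd: float
    n_flagged: int
    excluded: bool
    exclusion_reasons: list[str] = field(default_factory=list)

    def qc_dict(self) -> dict:
        return {
            "mean_fd": self.mean_fd,
            "n_flagged": int(self.n_flagged),
            "excluded": bool(self.excluded),
            "exclusion_reasons": list(self.exclusion_reasons),
        }


def gross_motion_exceeded(
    motion: np.ndarray,
    max_translation_mm: float = 1.5,
    max_rotation_deg: float = 1.5,
) -> bool:
    """Peak-to-peak translation/rotation exclusion check (report, not a hard error)."""
    motion = _as_2d(motion, "motion")
    ptp_t = np.ptp(motion[:, :3], axis=0).max()
    ptp_r = np.degrees(np.ptp(motion[:, 3:], axis=0).max())
    return bool(ptp_t > max_translation_mm or ptp_r > max_rotation_deg)


def preprocess_subject(
    ts: np.ndarray,
    motion: np.ndarray,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
    *,
    n_discard: int = 10,
    fd_threshold_mm: float = 0.2,
    n_before: int = 1,
    n_after: int = 2,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_s: float = 2.0,
    min_dof: int = 10,
) -> PreprocessResult:
    """Run the full cleaning pipeline for one subject in the fixed order.

    Mean FD (the group-analysis covariate) is computed after the initial
    volumes are discarded. A subject is marked ``excluded`` — with the
    partial result retained for inspection — when gross motion exceeds the
    1.5 mm / 1.5 degree limits or too few degrees of freedom survive
    scrubbing; callers decide what to do with excluded subjects.
    """
    ts, motion = discard_initial_volumes(ts, motion, n_discard)
    if wm_signal is not None:
        wm_signal = np.asarray(wm_signal, dtype=float).ravel()[n_discard:]
    if csf_signal is not None:
        csf_signal = np.asarray(csf_signal, dtype=float).ravel()[n_discard:]
    fd = framewise_displacement(motion)
    mask = scrub_mask(fd, fd_threshold_mm, n_before, n_after)
    design = build_nuisance_design(motion, mask, wm_signal, csf_signal)
    reasons: list[str] = []
    if gross_motion_exceeded(motion):
        reasons.append("gross motion > 1.5 mm translation or 1.5 deg rotation")
    try:
        resid = regress_nuisance(ts, design, min_dof=min_dof)
        clean = bandpass_filter(resid, low_hz, high_hz, tr_s)
    except SubjectExclusionError as exc:
        reasons.append(str(exc))
        clean = np.full_like(ts, np.nan)
    return PreprocessResult(
        timeseries=clean,
        fd=fd,
        mask=mask,
        design_columns=list(design.columns),
        mean_fd=float(fd.mean()),
        n_flagged=int(mask.sum()),
        excluded=bool(reasons),
        exclusion_reasons=reasons,
    )
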