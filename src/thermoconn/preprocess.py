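"""Temporal cleaning and subject-level quality control.

The cleaning chain applied to every subject's series, in order:
discard initial volumes (T1-equilibration), remove the per-column
linear trend, ideal (frequency-mask) band-pass to the resting-state
band 0.01-0.08 Hz, and least-squares regression of nuisance
confounds.  Motion-based subject exclusion uses the classical rule:
more than 1 mm maximum displacement on any translation axis or more
than 1 degree on any rotation axis (strict inequalities).

All operations accept and return :class:`RegionalSeries`; the
underscore-free ``*_columns`` helpers operate on bare (T, N) arrays so
voxel data can reuse the identical numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RegionalSeries",
    "ConfoundSet",
    "MotionSummary",
    "discard_initial",
    "detrend_linear",
    "bandpass_ideal",
    "regress_confounds",
    "motion_flag",
    "clean_series",
    "detrend_columns",
    "bandpass_columns",
    "regress_columns",
]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class RegionalSeries:
    """Per-subject T x R matrix of region-mean BOLD values.

    ``values[t, r]`` is the mean signal of region ``region_ids[r]`` at
    volume t; ``tr_seconds`` is the sampling interval.
    """

    values: np.ndarray
    tr_seconds: float
    region_ids: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least two volumes")
        if self.values.shape[1] != self.region_ids.size:
            raise ValueError("region_ids length must match column count")
        if np.unique(self.region_ids).size != self.region_ids.size:
            raise ValueError("region_ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConfoundSet:
    """T x K matrix of nuisance regressors (motion, global mean, ...)."""

    columns: np.ndarray
    names: tuple = ()

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.ndim != 2 or self.columns.shape[1] < 1:
            raise ValueError("confounds must form a T x K matrix with K >= 1")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("confounds contain non-finite values")


@dataclass(frozen=True)
class MotionSummary:
    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    excluded: bool


def discard_initial(series: RegionalSeries, n_discard: int) -> RegionalSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    return replace(series, values=series.values[n_discard:].copy())


def detrend_columns(values: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend from each column."""
    v = np.asarray(values, dtype=float)
    t = np.arange(v.shape[0], dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def detrend_linear(series: RegionalSeries) -> RegionalSeries:
    """Per-region removal of the best-fitting line a + b*t.

    Output columns are orthogonal to both the constant and the ramp, so
    slow scanner drift no longer leaks into correlations.
    """
    if series.n_volumes < 3:
        raise ValueError("detrending needs at least 3 volumes")
    return replace(series, values=detrend_columns(series.values))


def bandpass_columns(
    values: np.ndarray, tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.08
) -> np.ndarray:
    """Ideal band-pass: keep FFT bins with low <= f <= high, zero the rest.

    DC is always removed (low > 0 excludes bin 0; at low = 0 the DC bin
    is kept).  The mask is applied to the real FFT of each column with
    no padding or tapering, matching the deterministic frequency-mask
    filters used by resting-state toolkits.
    """
    v = np.asarray(values, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds the Nyquist frequency {nyquist} Hz "
            f"for TR={tr_seconds}s"
        )
    T = v.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(v, axis=0)
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def bandpass_ideal(
    series: RegionalSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RegionalSeries:
    """Frequency-mask band-pass of every region to [low_hz, high_hz]."""
    return replace(
        series,
        values=bandpass_columns(series.values, series.tr_seconds, low_hz, high_hz),
    )


def regress_columns(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize columns of ``values`` against the confound matrix."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(confounds, dtype=float)
    if c.shape[0] != v.shape[0]:
        raise ValueError("confounds and series must share T")
    if v.shape[0] <= c.shape[1]:
        raise ValueError("underdetermined: T must exceed the confound count")
    coef, *_ = np.linalg.lstsq(c, v, rcond=None)
    return v - c @ coef


def regress_confounds(series: RegionalSeries, confounds: ConfoundSet) -> RegionalSeries:
    """Least-squares removal of nuisance signals.

    Residuals are orthogonal to every confound column.  The confound set
    should include an intercept column if mean removal is wanted here.
    """
    return replace(series, values=regress_columns(series.values, confounds.columns))


def motion_flag(
    motion_table: pd.DataFrame,
    trans_thr_mm: float = 1.0,
    rot_thr_deg: float = 1.0,
) -> MotionSummary:
    """Subject exclusion rule on realignment parameters.

    Excluded iff max |translation| > trans_thr_mm on any of x/y/z OR
    max |rotation| > rot_thr_deg on any axis.  Both comparisons are
    strict, so a subject sitting exactly at threshold is retained.
    """
    missing = [c for c in MOTION_COLUMNS if c not in motion_table.columns]
    if missing:
        raise ValueError(f"motion table missing columns: {missing}")
    trans = motion_table[list(MOTION_COLUMNS[:3])].to_numpy(dtype=float)
    rot = motion_table[list(MOTION_COLUMNS[3:])].to_numpy(dtype=float)
    max_t = float(np.max(np.abs(trans))) if trans.size else 0.0
    max_r = float(np.max(np.abs(rot))) if rot.size else 0.0
    return MotionSummary(max_t, max_r, max_t > trans_thr_mm or max_r > rot_thr_deg)


def clean_series(
    series: RegionalSeries,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    confounds: ConfoundSet | None = None,
) -> RegionalSeries:
    """Full temporal cleaning chain: discard, detrend, band-pass, regress.

    ``confounds`` (if given) must already match the post-discard length;
    regression runs after filtering by default.
    """
    out = discard_initial(series, n_discard)
    out = detrend_linear(out)
    out = bandpass_ideal(out, low_hz, high_hz)
    if confounds is not None:
        out = regress_confounds(out, confounds)
    return out
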