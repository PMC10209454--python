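"""Scan and time-course conditioning.

Voxel stage (applied to scans before network extraction): discard initial
volumes for magnetization equilibrium, truncate to a common length, z-score
each voxel series.  Time-course stage (applied to extracted network courses):
resample to a common TR, remove the linear trend, band-pass 0.01-0.15 Hz with
a zero-phase 5th-order Butterworth filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .io import BoldScan


@dataclass
class TimeCourseSet:
    """Network time courses (time x ICN) with TR and identity metadata."""

    data: np.ndarray
    tr: float
    icn_ids: list[str]
    orders: list[int | str]
    domains: list[str]
    subject_id: str = ""
    resampled: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time courses must be time x ICN")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite time-course values")
        if not (len(self.icn_ids) == len(self.orders) == len(self.domains) == self.data.shape[1]):
            raise ValueError("metadata length must match ICN count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_icns(self) -> int:
        return self.data.shape[1]


def discard_and_truncate(
    scan: BoldScan, n_discard: int = 5, target_len: int | None = 135
) -> BoldScan:
    """Drop the first ``n_discard`` volumes then keep the first ``target_len``."""
    if scan.n_volumes <= n_discard + 1:
        raise ValueError(
            f"scan {scan.subject_id}: {scan.n_volumes} volumes too short to "
            f"discard {n_discard}"
        )
    kept = scan.data[:, n_discard:]
    if target_len is not None:
        if target_len > kept.shape[1]:
            raise ValueError(
                f"scan {scan.subject_id}: only {kept.shape[1]} volumes after "
                f"discard, cannot truncate to {target_len}"
            )
        kept = kept[:, :target_len]
    return replace(scan, data=kept)


def zscore_voxels(scan: BoldScan) -> BoldScan:
    """Z-score every voxel time series (mean 0, sd 1).

    Zero-variance voxels cannot be normalized; they are zeroed out with a
    warning (an all-constant scan is fatal).
    """
    mu = scan.data.mean(axis=1, keepdims=True)
    sd = scan.data.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.all():
        raise ValueError(f"scan {scan.subject_id}: all voxels constant")
    if flat.any():
        warnings.warn(
            f"scan {scan.subject_id}: {int(flat.sum())} zero-variance voxels "
            "zeroed",
            stacklevel=2,
        )
    out = (scan.data - mu) / np.where(sd == 0, 1.0, sd)
    return replace(scan, data=out)


def resample_to_tr(tcs: TimeCourseSet, target_tr: float = 2.0) -> TimeCourseSet:
    """Interpolate courses onto a uniform ``target_tr`` grid (cubic spline).

    A no-op when the TR already matches.  Series with fewer than 4 points
    fall back to linear interpolation with a warning.
    """
    if tcs.tr <= 0 or target_tr <= 0:
        raise ValueError("TRs must be positive")
    if np.isclose(tcs.tr, target_tr):
        return tcs
    t_old = np.arange(tcs.n_timepoints) * tcs.tr
    t_new = np.arange(0.0, t_old[-1] + 1e-9, target_tr)
    if tcs.n_timepoints < 4:
        warnings.warn("fewer than 4 points; using linear interpolation", stacklevel=2)
        out = np.stack(
            [np.interp(t_new, t_old, col) for col in tcs.data.T], axis=1
        )
    else:
        out = CubicSpline(t_old, tcs.data, axis=0)(t_new)
    return replace(tcs, data=out, tr=target_tr, resampled=True)


def detrend_and_bandpass(
    tcs: TimeCourseSet,
    band: tuple[float, float] = (0.01, 0.15),
    filter_order: int = 5,
) -> TimeCourseSet:
    """Remove each column's linear trend, then zero-phase Butterworth band-pass."""
    nyq = 0.5 / tcs.tr
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= nyq:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist {nyq:.4f} Hz")
    detrended = signal.detrend(tcs.data, axis=0, type="linear")
    sos = signal.butter(filter_order, [lo / nyq, hi / nyq], "bandpass", output="sos")
    # even-reflection padding: odd reflection of oscillatory series injects
    # low-frequency edge energy into the passband
    out = signal.sosfiltfilt(sos, detrended, axis=0, padtype="even")
    out = out - out.mean(axis=0, keepdims=True)
    return replace(tcs, data=out, filtered=True)


def condition_timecourses(
    tcs: TimeCourseSet,
    target_tr: float = 2.0,
    band: tuple[float, float] = (0.01, 0.15),
    filter_order: int = 5,
) -> TimeCourseSet:
    """Full time-course stage: resample -> detrend -> band-pass."""
    return detrend_and_bandpass(
        resample_to_tr(tcs, target_tr), band=band, filter_order=filter_order
    )
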