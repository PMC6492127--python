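"""Breathing-field calibration from a phase-sensitive FLASH time series.

A sagittal spoiled gradient-echo time series acquired during free breathing
encodes the time-varying field offset in its phase: at echo time TE the
accrued phase of a voxel is 2π·f0(r,t)·TE on top of its static phase. The
calibration path unwraps the phase over time, converts it to a frequency
offset (Hz), averages it across the cord in each transverse plane, and fits
a per-slice coupling coefficient ΔBref(z) between the bellows trace R(t) and
the field, using the model

    f0(z, t) = R(t) · ΔBref(z).

ΔBref(z) carries units Hz per bellows-unit; any rescaling of the raw trace
is absorbed into the coupling, so the bellows never needs physical units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .correction import RespTrace, resample_trace

logger = logging.getLogger("breathfield")

#: gyromagnetic ratio of 1H over 2π, MHz/T — only for optional Tesla conversion;
#: all internal field bookkeeping is in Hz.
GAMMA_BAR_MHZ_PER_T = 42.5774785

__all__ = [
    "PhaseSeries",
    "FieldProfileSeries",
    "FieldCalibration",
    "unwrap_phase_temporal",
    "phase_to_field",
    "average_field_in_mask",
    "detect_outlier_frames",
    "fit_trace_coupling",
    "calibrate",
]


@dataclass
class PhaseSeries:
    """Voxelwise phase/magnitude time series from the calibration scan.

    ``phase``/``magnitude`` have shape (nz, nx, n_frames): rows index the
    superior–inferior axis (one row per transverse plane of the sagittal
    slice), columns the anterior–posterior axis.
    """

    phase: np.ndarray       # radians, (nz, nx, nt)
    magnitude: np.ndarray   # arbitrary units, same shape
    te_s: float
    frame_times: np.ndarray  # seconds, (nt,)
    z_mm: np.ndarray         # (nz,) slice position per row, increases inferiorly

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")
        if self.te_s <= 0:
            raise ValueError("TE must be positive")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[-1]


@dataclass
class FieldProfileSeries:
    """Cord-averaged field offset per transverse plane: f0(z, t) in Hz."""

    z_mm: np.ndarray        # (nz,)
    f0: np.ndarray          # Hz, (nz, nt)
    frame_times: np.ndarray  # (nt,)
    dropped_slices: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.all(np.isfinite(self.f0)):
            raise ValueError("field profile must be finite")
        if self.f0.shape != (self.z_mm.size, self.frame_times.size):
            raise ValueError("f0 must be (n_slices, n_frames)")


@dataclass
class FieldCalibration:
    """Per-slice trace-to-field coupling ΔBref(z) with fit diagnostics."""

    z_mm: np.ndarray        # (nz,)
    coupling: np.ndarray    # Hz per bellows-unit, (nz,)
    residual_rms: np.ndarray  # Hz, (nz,)
    fit_window: float       # seconds of calibration data used
    excluded_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("coupling must be finite")
        if np.any(self.residual_rms < 0):
            raise ValueError("residual_rms must be >= 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def unwrap_phase_temporal(series: PhaseSeries) -> PhaseSeries:
    """Unwrap each voxel's phase along the time axis.

    Frame-to-frame phase increments are corrected by the nearest multiple of
    2π so that no temporal jump exceeds π in magnitude; frame 0 is left
    unchanged. This is purely temporal — no spatial unwrapping is attempted,
    matching the acquisition regime where inter-frame phase changes from
    breathing are well below π.
    """
    if series.n_frames < 2:
        warnings.warn("single-frame series: temporal unwrap is a no-op")
        return series
    unwrapped = np.unwrap(series.phase, axis=-1)
    return PhaseSeries(
        phase=unwrapped,
        magnitude=series.magnitude,
        te_s=series.te_s,
        frame_times=series.frame_times,
        z_mm=series.z_mm,
    )


def phase_to_field(series: PhaseSeries) -> np.ndarray:
    """Convert an unwrapped phase series to a field-offset series in Hz.

    f0(r, t) = (ϕ(r,t) − mean_t ϕ(r,·)) / (2π·TE). Removing the temporal
    mean discards the static phase of each voxel, so the output has exactly
    zero time-average per voxel.
    """
    if series.te_s <= 0:
        raise ValueError("TE must be positive")
    dphi = series.phase - series.phase.mean(axis=-1, keepdims=True)
    return dphi / (2.0 * np.pi * series.te_s)


def average_field_in_mask(
    field_series: np.ndarray,
    cord_mask: np.ndarray,
    z_mm: np.ndarray,
    frame_times: np.ndarray,
) -> FieldProfileSeries:
    """Average the voxelwise field over the cord in each transverse plane.

    ``field_series`` is (nz, nx, nt); ``cord_mask`` is (nz, nx). Rows whose
    mask is empty are dropped (with a warning) and recorded in the output.
    """
    field_series = np.asarray(field_series, dtype=float)
    cord_mask = np.asarray(cord_mask, dtype=bool)
    z_mm = np.asarray(z_mm, dtype=float)
    nz = field_series.shape[0]
    keep, dropped, rows = [], [], []
    for iz in range(nz):
        m = cord_mask[iz]
        if not m.any():
            dropped.append(iz)
            continue
        keep.append(iz)
        rows.append(field_series[iz, m, :].mean(axis=0))
    if dropped:
        warnings.warn(f"slices with empty cord mask dropped: {dropped}")
    if not keep:
        raise ValueError("cord mask empty in every slice")
    return FieldProfileSeries(
        z_mm=z_mm[keep],
        f0=np.vstack(rows),
        frame_times=np.asarray(frame_times, dtype=float),
        dropped_slices=dropped,
    )


def _demeaned_lsq(r: np.ndarray, f0: np.ndarray) -> tuple[float, float]:
    """Scalar least-squares slope of f0 on r after demeaning both.

    Returns (coupling, residual_rms). Equivalent to fitting slope+intercept
    and discarding the intercept; the closed form is Σ r·f0 / Σ r².
    """
    r = r - r.mean()
    f0 = f0 - f0.mean()
    denom = float(np.sum(r * r))
    if denom == 0.0:
        raise ValueError("degenerate fit: trace has zero variance over the window")
    c = float(np.sum(r * f0)) / denom
    resid = f0 - c * r
    return c, float(np.sqrt(np.mean(resid**2)))


def detect_outlier_frames(
    profile: FieldProfileSeries,
    trace: RespTrace,
    k: float = 4.0,
) -> list[int]:
    """Flag frames whose field deviates from the linear trace model.

    Swallowing superimposes field bursts (tens of Hz) that are not driven by
    the bellows; such frames corrupt the coupling fit. A provisional
    per-slice fit is computed from all frames, then any frame whose residual
    exceeds ``k`` times the MAD-estimated residual SD in at least one slice
    is flagged. Returns a (possibly empty) sorted list of frame indices.
    """
    if profile.frame_times.size < 20:
        raise ValueError("outlier detection needs >= 20 frames")
    r = resample_trace(trace, profile.frame_times)
    flagged: set[int] = set()
    for iz in range(profile.z_mm.size):
        f0 = profile.f0[iz]
        c, _ = _demeaned_lsq(r, f0)
        resid = (f0 - f0.mean()) - c * (r - r.mean())
        mad = np.median(np.abs(resid - np.median(resid)))
        sigma = 1.4826 * mad
        if sigma == 0.0:
            continue
        flagged.update(np.flatnonzero(np.abs(resid) > k * sigma).tolist())
    return sorted(flagged)


def fit_trace_coupling(
    profile: FieldProfileSeries,
    trace: RespTrace,
    window_s: float = 30.0,
    excluded: list[int] | None = None,
) -> FieldCalibration:
    """Least-squares fit of the per-slice coupling ΔBref(z).

    Uses frames within ``window_s`` seconds from the start of the
    calibration record, minus ``excluded`` frames. The trace is linearly
    interpolated to the frame times; both trace and field are demeaned over
    the retained frames before the scalar normal-equation solve, so the fit
    is insensitive to residual baseline offsets of either signal.
    """
    t = profile.frame_times
    if window_s > (t[-1] - t[0]) + 1e-9:
        raise ValueError(
            f"fit window {window_s}s exceeds record length {t[-1] - t[0]:.2f}s"
        )
    in_window = t <= t[0] + window_s + 1e-12
    keep = np.flatnonzero(in_window)
    excluded = sorted(set(int(i) for i in (excluded or [])))
    keep = np.array([i for i in keep if i not in excluded], dtype=int)
    if keep.size == 0:
        raise ValueError("all frames excluded from the fit")
    if keep.size < 10:
        raise ValueError(f"fit needs >= 10 frames per slice, got {keep.size}")
    r = resample_trace(trace, t[keep])
    coupling = np.empty(profile.z_mm.size)
    resid_rms = np.empty(profile.z_mm.size)
    for iz in range(profile.z_mm.size):
        coupling[iz], resid_rms[iz] = _demeaned_lsq(r, profile.f0[iz, keep])
    return FieldCalibration(
        z_mm=profile.z_mm.copy(),
        coupling=coupling,
        residual_rms=resid_rms,
        fit_window=float(window_s),
        excluded_frames=excluded,
    )


def calibrate(
    series: PhaseSeries,
    cord_mask: np.ndarray,
    trace: RespTrace,
    window_s: float = 30.0,
    outlier_k: float = 4.0,
) -> FieldCalibration:
    """Full calibration path: unwrap → field → cord average → two-pass fit.

    The two-pass scheme fits provisionally, flags outlier frames (swallows)
    at threshold ``outlier_k`` MAD, then refits with those frames excluded.
    """
    unwrapped = unwrap_phase_temporal(series)
    f0_vox = phase_to_field(unwrapped)
    profile = average_field_in_mask(
        f0_vox, cord_mask, series.z_mm, series.frame_times
    )
    outliers = detect_outlier_frames(profile, trace, k=outlier_k)
    if outliers:
        logger.info("excluding %d outlier frames from calibration fit", len(outliers))
    return fit_trace_coupling(profile, trace, window_s=window_s, excluded=outliers)
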