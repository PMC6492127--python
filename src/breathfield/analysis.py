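"""Quantitative outputs: T2* maps, temporal SNR, ghosting metric, ROI stats.

T2* mapping fits the monoexponential decay S(TE) = S0·exp(−TE/T2*) to the
magnitude of each in-mask voxel across echoes, initialized from a
log-linear regression and refined by bounded nonlinear least squares. The
fit is performed on magnitudes with no constant offset — the noise-floor
bias of that model is accepted and measured, not corrected.

tSNR is the voxelwise ratio of the temporal mean to the temporal standard
deviation (sample SD, N−1) of an image time series. The ghost metric
quantifies signal scattered outside the imaged object by shot-to-shot
phase inconsistency: mean |signal| outside the 2-voxel-dilated object mask
divided by mean |signal| inside the cord mask (scale invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.optimize import least_squares

logger = logging.getLogger("breathfield")

__all__ = [
    "T2StarMap",
    "TSNRMap",
    "fit_t2star",
    "tsnr",
    "ghost_metric",
    "summarize_roi",
]

T2S_BOUNDS_MS = (0.1, 500.0)


@dataclass
class T2StarMap:
    t2star_ms: np.ndarray   # per voxel; NaN outside mask / invalid
    s0: np.ndarray
    rmse: np.ndarray
    valid: np.ndarray       # bool

    def __post_init__(self) -> None:
        if np.any(self.t2star_ms[self.valid] <= 0):
            raise ValueError("valid T2* must be positive")
        if np.any(self.rmse[self.valid] < 0):
            raise ValueError("fit RMSE must be >= 0")


@dataclass
class TSNRMap:
    tsnr: np.ndarray        # NaN where undefined
    mean: np.ndarray
    sd: np.ndarray
    defined: np.ndarray     # bool: SD > 0 inside mask


def _loglin_init(sig: np.ndarray, te_ms: np.ndarray) -> tuple[float, float]:
    """Log-linear (ordinary LSQ on log signal) estimate of (S0, T2*)."""
    logs = np.log(sig)
    slope, intercept = np.polyfit(te_ms, logs, 1)
    t2s = -1.0 / slope if slope < 0 else T2S_BOUNDS_MS[1]
    return float(np.exp(intercept)), float(np.clip(t2s, *T2S_BOUNDS_MS))


def fit_t2star(
    echo_mags: np.ndarray,
    te_ms: np.ndarray,
    mask: np.ndarray,
) -> T2StarMap:
    """Voxelwise monoexponential T2* fit across echoes.

    ``echo_mags`` has the echo axis first: (n_echo, ...spatial). Requires at
    least 3 echoes with strictly increasing TEs. Voxels with no positive
    echo signal are marked invalid.
    """
    echo_mags = np.asarray(echo_mags, dtype=float)
    te_ms = np.asarray(te_ms, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if te_ms.size < 3:
        raise ValueError("T2* fit needs >= 3 echoes")
    if not np.all(np.diff(te_ms) > 0):
        raise ValueError("TEs must be strictly increasing")
    if echo_mags.shape[0] != te_ms.size:
        raise ValueError("echo axis length must match TE list")
    spatial = echo_mags.shape[1:]
    if mask.shape != spatial:
        raise ValueError("mask shape must match spatial dimensions")

    t2s = np.full(spatial, np.nan)
    s0 = np.full(spatial, np.nan)
    rmse = np.full(spatial, np.nan)
    valid = np.zeros(spatial, dtype=bool)

    flat = echo_mags.reshape(te_ms.size, -1)
    mask_flat = mask.ravel()
    idx = np.flatnonzero(mask_flat)

    def model_resid(p, sig):
        return p[0] * np.exp(-te_ms / p[1]) - sig

    for vi in idx:
        sig = flat[:, vi]
        pos = sig > 0
        if not pos.any():
            continue  # invalid voxel: no usable signal
        if pos.sum() >= 2:
            p0 = _loglin_init(sig[pos], te_ms[pos])
        else:
            p0 = (float(sig[pos][0]), 20.0)
        s0_hi = max(10.0 * float(np.max(sig)), 1e-12)
        sol = least_squares(
            model_resid,
            x0=[np.clip(p0[0], 1e-12, s0_hi), p0[1]],
            bounds=([0.0, T2S_BOUNDS_MS[0]], [s0_hi, T2S_BOUNDS_MS[1]]),
            args=(sig,),
            method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        uvi = np.unravel_index(vi, spatial)
        s0[uvi], t2s[uvi] = sol.x
        rmse[uvi] = float(np.sqrt(np.mean(sol.fun**2)))
        valid[uvi] = True

    return T2StarMap(t2star_ms=t2s, s0=s0, rmse=rmse, valid=valid)


def tsnr(series: np.ndarray, mask: np.ndarray | None = None) -> TSNRMap:
    """Temporal SNR: mean / sample-SD over the time axis (axis 0).

    Needs >= 3 time points. Voxels with zero temporal SD are flagged
    undefined (NaN in the map), never infinite.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("tSNR needs >= 3 time points")
    mean = series.mean(axis=0)
    sd = series.std(axis=0, ddof=1)
    defined = sd > 0
    if mask is not None:
        defined = defined & np.asarray(mask, dtype=bool)
    out = np.full(mean.shape, np.nan)
    out[defined] = mean[defined] / sd[defined]
    return TSNRMap(tsnr=out, mean=mean, sd=sd, defined=defined)


def ghost_metric(
    image: np.ndarray,
    object_mask: np.ndarray,
    cord_mask: np.ndarray | None = None,
    dilate_vox: int = 2,
) -> float:
    """Ratio of mean |signal| outside the dilated object to inside the cord.

    The object mask is dilated by ``dilate_vox`` voxels before defining the
    outside region, to keep edge ringing out of the numerator. Scale
    invariant; near zero for a clean reconstruction of a compact object.
    """
    image = np.abs(np.asarray(image))
    object_mask = np.asarray(object_mask, dtype=bool)
    if cord_mask is None:
        cord_mask = object_mask
    cord_mask = np.asarray(cord_mask, dtype=bool)
    dilated = binary_dilation(object_mask, iterations=dilate_vox)
    outside = ~dilated
    if not outside.any():
        raise ValueError("no voxels outside the dilated object mask")
    if not cord_mask.any():
        raise ValueError("empty cord mask")
    denom = float(image[cord_mask].mean())
    if denom == 0:
        raise ValueError("zero mean signal inside cord mask")
    return float(image[outside].mean()) / denom


def summarize_roi(values: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Order statistics of in-mask voxels: median, P5/P25/P75/P95, mean.

    Percentiles use linear interpolation between order statistics. NaNs
    (e.g. invalid fit voxels) are excluded.
    """
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty ROI")
    p5, p25, p50, p75, p95 = np.percentile(values, [5, 25, 50, 75, 95])
    return {
        "n": int(values.size),
        "median": float(p50),
        "p5": float(p5),
        "p25": float(p25),
        "p75": float(p75),
        "p95": float(p95),
        "mean": float(values.mean()),
    }
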