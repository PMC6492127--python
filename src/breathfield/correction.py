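"""Field prediction from the respiratory trace and k-space phase demodulation.

During an imaging scan the breathing state R(t) recorded by the bellows is
converted, through the per-slice calibration coupling ΔBref(z), into a
predicted field offset

    f0_hat(z, t) = R(t) · ΔBref(z)            [Hz]

which, under the assumption that the field is static over one readout
train, imparts a phase

    Δϕ_hat(z, t, t_ro) = 2π · f0_hat(z, t) · t_ro     [rad]

on each k-space sample acquired t_ro seconds after the excitation.
Demodulation multiplies each complex sample by exp(−i·Δϕ_hat), removing the
breathing phase before reconstruction. Magnitudes are untouched exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import KSpaceContainer, TraceFile

logger = logging.getLogger("breathfield")

#: Sign of the phase the field imparts on the acquired signal: positive f0
#: accrues phase +2π·f0·t_ro. The simulator and the corrector both reference
#: this single constant; a demodulate-then-remodulate round trip pins it.
PHASE_SIGN = +1.0

__all__ = [
    "PHASE_SIGN",
    "RespTrace",
    "PredictedField",
    "sync_trace",
    "resample_trace",
    "predict_field",
    "predict_field_for_container",
    "phase_offset",
    "demodulate",
    "remodulate",
]


@dataclass
class RespTrace:
    """Synchronized, baseline-removed bellows trace.

    Time is rebased so that t = 0 coincides with the chosen sequence
    trigger; the per-scan mean has been subtracted from the value column to
    remove slow baseline drifts between scans.
    """

    time: np.ndarray
    value: np.ndarray
    sync_offset_s: float = 0.0  # applied shift between trace and sequence clocks

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time must be strictly increasing")
        rms = float(np.sqrt(np.mean(self.value**2)))
        if rms > 0 and abs(float(np.mean(self.value))) > 1e-9 * rms:
            raise ValueError("trace value must be mean-removed")


@dataclass
class PredictedField:
    """Predicted breathing field per (slice, excitation event), in Hz."""

    f0_hat: np.ndarray       # (n_slice, ...) Hz, trailing axes match event_times
    event_times: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.f0_hat = np.asarray(self.f0_hat, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        if not np.all(np.isfinite(self.f0_hat)):
            raise ValueError("predicted field must be finite")
        if self.f0_hat.shape[1:] != self.event_times.shape:
            raise ValueError("f0_hat trailing axes must match event_times")


# ---------------------------------------------------------------------------
# Trace handling
# ---------------------------------------------------------------------------

def sync_trace(trace_file: TraceFile, scan_start_trigger_index: int = 0) -> RespTrace:
    """Synchronize a raw trace to the sequence clock and remove its baseline.

    The time axis is rebased so that the sample carrying the
    ``scan_start_trigger_index``-th trigger mark sits at t = 0, and the mean
    of the value column over the record is subtracted.
    """
    trig = trace_file.trigger_indices
    if trig.size == 0:
        raise ValueError("trace has no trigger marks; cannot synchronize")
    if not 0 <= scan_start_trigger_index < trig.size:
        raise ValueError(
            f"trigger index {scan_start_trigger_index} out of range (0..{trig.size - 1})"
        )
    t0 = float(trace_file.time[trig[scan_start_trigger_index]])
    value = trace_file.value - float(np.mean(trace_file.value))
    return RespTrace(time=trace_file.time - t0, value=value, sync_offset_s=-t0)


def resample_trace(trace: RespTrace, times: np.ndarray) -> np.ndarray:
    """Linearly interpolate the trace at the given times (seconds).

    Beyond the recorded support the edge samples are held constant, with a
    logged warning — extrapolating a breathing signal is not meaningful.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < trace.time[0] or times.max() > trace.time[-1]):
        warnings.warn(
            "event times outside trace support; edge samples held constant"
        )
    return np.interp(times, trace.time, trace.value)


# ---------------------------------------------------------------------------
# Field prediction
# ---------------------------------------------------------------------------

def _nearest_coupling(calib, slices_z_mm: np.ndarray) -> np.ndarray:
    """Coupling per requested slice, nearest-neighbor along z.

    Nearest-neighbor substitution (rather than linear extrapolation) is used
    for slices outside the calibrated range: the breathing-field profile is
    strongly nonlinear near the thorax, so extrapolation is unsafe.
    """
    slices_z_mm = np.atleast_1d(np.asarray(slices_z_mm, dtype=float))
    calib_z = np.asarray(calib.z_mm, dtype=float)
    idx = np.abs(slices_z_mm[:, None] - calib_z[None, :]).argmin(axis=1)
    missing = ~np.isclose(slices_z_mm, calib_z[idx], atol=1e-6)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} slice(s) absent from calibration; "
            "nearest-z coupling substituted"
        )
    return np.asarray(calib.coupling, dtype=float)[idx]


def predict_field(calib, trace: RespTrace, event_times, slices_z_mm) -> PredictedField:
    """Predict f0_hat(z, event) = R(t_event) · ΔBref(z)."""
    event_times = np.asarray(event_times, dtype=float)
    r = resample_trace(trace, event_times.ravel()).reshape(event_times.shape)
    coupling = _nearest_coupling(calib, slices_z_mm)
    shape = (coupling.size,) + event_times.shape
    f0_hat = coupling.reshape((-1,) + (1,) * event_times.ndim) * r[None]
    return PredictedField(f0_hat=f0_hat.reshape(shape), event_times=event_times)


def field_evaluation_times(kset: KSpaceContainer) -> np.ndarray:
    """Per-excitation field evaluation time, (rep, exc), seconds.

    The field is treated as constant over each readout train. For a
    segmented EPI shot it is evaluated at excitation time + TE (the center
    of the echo train); for single-line multi-echo GRE it is evaluated once
    per excitation (at the RF pulse).
    """
    t_exc = kset.excitation_times()
    if str(kset.meta.get("seq_type", "")).upper().startswith("EPI"):
        te_s = float(np.asarray(kset.meta["te_ms"], dtype=float)[0]) * 1e-3
        return t_exc + te_s
    return t_exc


def predict_field_for_container(calib, trace: RespTrace, kset: KSpaceContainer) -> PredictedField:
    """Predict the breathing field at every excitation of an acquisition."""
    return predict_field(calib, trace, field_evaluation_times(kset), kset.slice_z_mm)


# ---------------------------------------------------------------------------
# Phase demodulation
# ---------------------------------------------------------------------------

def phase_offset(f0_hat, t_ro) -> np.ndarray:
    """Phase (rad) a field offset f0_hat (Hz) imparts after t_ro seconds.

    Δϕ = 2π · f0_hat · t_ro, signed per :data:`PHASE_SIGN`.
    """
    t_ro = np.asarray(t_ro, dtype=float)
    if np.any(t_ro < 0):
        raise ValueError("t_ro must be >= 0")
    return PHASE_SIGN * 2.0 * np.pi * np.asarray(f0_hat, dtype=float) * t_ro


def _apply_phase(kset: KSpaceContainer, field: PredictedField, sign: float) -> KSpaceContainer:
    nc, ns, nr, ne, nech, nl, nx = kset.data.shape
    if field.f0_hat.shape != (ns, nr, ne):
        raise ValueError(
            f"predicted field shape {field.f0_hat.shape} does not cover "
            f"(slice, rep, excitation) = {(ns, nr, ne)}"
        )
    if not np.all(np.isfinite(field.f0_hat)):
        raise ValueError("predicted field must be finite")
    # phase per (slice, rep, exc, echo, line); broadcast over coil and readout
    phi = phase_offset(
        field.f0_hat[:, :, :, None, None], kset.t_ro[None, None, :, :, :]
    )
    out = kset.copy()
    out.data *= np.exp(1j * sign * phi)[None, ..., None]
    return out


def demodulate(kset: KSpaceContainer, field: PredictedField) -> KSpaceContainer:
    """Remove the predicted breathing phase from every k-space sample.

    ŝ = s · exp(−i·Δϕ_hat). Per-sample magnitudes (and hence total k-space
    energy) are preserved exactly.
    """
    return _apply_phase(kset, field, sign=-1.0)


def remodulate(kset: KSpaceContainer, field: PredictedField) -> KSpaceContainer:
    """Inverse of :func:`demodulate` (re-applies the phase)."""
    return _apply_phase(kset, field, sign=+1.0)
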