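"""On-disk formats and in-memory containers.

Formats: CSV for the respiratory bellows trace, HDF5 for multi-coil k-space
with per-readout timing, NIfTI-1 magnitude/phase pairs for image volumes,
JSON for field-calibration results, YAML for pipeline configuration.
No science lives here.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("breathfield")

__all__ = [
    "TraceFile",
    "KSpaceContainer",
    "FormatError",
    "ConsistencyError",
    "InsufficientDataError",
    "read_trace",
    "write_trace",
    "read_kspace",
    "write_kspace",
    "read_nifti_pair",
    "write_nifti_pair",
    "read_mask",
    "write_mask",
    "read_calibration_json",
    "write_calibration_json",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(ValueError):
    """Arrays within a container disagree in shape or content."""


class InsufficientDataError(ValueError):
    """Too few samples/frames to perform the requested operation."""


# ---------------------------------------------------------------------------
# Respiratory trace
# ---------------------------------------------------------------------------

@dataclass
class TraceFile:
    """Raw bellows recording: time base, signal value and sequence triggers.

    ``time`` is in seconds and strictly increasing; ``value`` is in arbitrary
    bellows units; ``trigger`` marks samples at which the sequence emitted a
    synchronization pulse (used to rebase the clock at scan start).
    """

    time: np.ndarray
    value: np.ndarray
    trigger: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.trigger = np.asarray(self.trigger, dtype=bool)
        if self.time.ndim != 1 or self.time.size < 2:
            raise InsufficientDataError(
                f"trace needs >= 2 samples, got {self.time.size}"
            )
        if not (self.time.shape == self.value.shape == self.trigger.shape):
            raise ConsistencyError("time, value, trigger must have equal length")
        if not np.all(np.diff(self.time) > 0):
            raise FormatError("trace time column must be strictly increasing")

    @property
    def trigger_indices(self) -> np.ndarray:
        return np.flatnonzero(self.trigger)


def read_trace(path: str | Path) -> TraceFile:
    """Read a bellows trace CSV with header ``time,value,trigger``."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for required in ("time", "value", "trigger"):
            if required not in cols:
                raise FormatError(f"{path}: missing column '{required}'")
        rows = list(reader)
    if len(rows) < 2:
        raise InsufficientDataError(f"{path}: need >= 2 rows, got {len(rows)}")
    time = np.array([float(r["time"]) for r in rows])
    value = np.array([float(r["value"]) for r in rows])
    trigger = np.array([int(r["trigger"]) != 0 for r in rows])
    return TraceFile(time=time, value=value, trigger=trigger)


def write_trace(trace: TraceFile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "value", "trigger"])
        for t, v, g in zip(trace.time, trace.value, trace.trigger):
            # repr round-trips float64 exactly
            writer.writerow([repr(float(t)), repr(float(v)), int(g)])


# ---------------------------------------------------------------------------
# K-space container
# ---------------------------------------------------------------------------

#: meta keys serialized as HDF5 attributes
_META_SCALARS = (
    "seq_type", "tr_ms", "shot_tr_ms", "fov_mm", "bandwidth_hz_px",
    "n_shots", "sense_factor", "epi_ref_applied", "echo_spacing_ms",
)


@dataclass
class KSpaceContainer:
    """Multi-coil Cartesian k-space with per-readout timing.

    Axes of ``data``: (coil, slice, rep, excitation, echo, line, read).
    One "excitation" is a single RF shot; for a single-line-per-TR
    gradient-echo scan each excitation holds one line per echo, while a
    segmented EPI shot holds several lines of a single echo.

    ``k_index`` gives the 0-based phase-encode index of each acquired line
    (DC at floor(N/2)); ``t_abs`` is seconds since scan start at line
    acquisition; ``t_ro`` is seconds since the most recent RF excitation.
    """

    data: np.ndarray          # (coil, slice, rep, exc, echo, line, read) complex
    k_index: np.ndarray       # (exc, echo, line) int
    t_abs: np.ndarray         # (rep, exc, echo, line) float
    t_ro: np.ndarray          # (exc, echo, line) float
    line_reversed: np.ndarray  # (exc, echo, line) bool — EPI readout polarity
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.k_index = np.asarray(self.k_index, dtype=np.int64)
        self.t_abs = np.asarray(self.t_abs, dtype=float)
        self.t_ro = np.asarray(self.t_ro, dtype=float)
        self.line_reversed = np.asarray(self.line_reversed, dtype=bool)
        if self.data.ndim != 7:
            raise ConsistencyError(
                f"data must be 7-D (coil,slice,rep,exc,echo,line,read), got {self.data.ndim}-D"
            )
        nc, ns, nr, ne, nech, nl, nx = self.data.shape
        if self.k_index.shape != (ne, nech, nl):
            raise ConsistencyError("k_index shape does not match data")
        if self.t_abs.shape != (nr, ne, nech, nl):
            raise ConsistencyError("t_abs shape does not match data")
        if self.t_ro.shape != (ne, nech, nl):
            raise ConsistencyError("t_ro shape does not match data")
        if self.line_reversed.shape != (ne, nech, nl):
            raise ConsistencyError("line_reversed shape does not match data")
        if not np.all(np.isfinite(self.t_abs)):
            raise ConsistencyError("t_abs must be finite")
        if np.any(self.t_ro < 0):
            raise ConsistencyError("t_ro must be >= 0")
        ny = int(self.meta.get("matrix", (self.data.shape[-1], nx))[0])
        if np.any(self.k_index < 0) or np.any(self.k_index >= ny):
            raise ConsistencyError("k_index out of matrix bounds")
        te = np.asarray(self.meta.get("te_ms", []), dtype=float)
        if te.size > 1 and not np.all(np.diff(te) > 0):
            raise ConsistencyError("meta te_ms must be strictly increasing")

    # convenience accessors -------------------------------------------------
    @property
    def n_coil(self) -> int:
        return self.data.shape[0]

    @property
    def n_slice(self) -> int:
        return self.data.shape[1]

    @property
    def n_rep(self) -> int:
        return self.data.shape[2]

    @property
    def n_exc(self) -> int:
        return self.data.shape[3]

    @property
    def matrix(self) -> tuple[int, int]:
        ny, nx = self.meta["matrix"]
        return int(ny), int(nx)

    @property
    def slice_z_mm(self) -> np.ndarray:
        return np.asarray(self.meta["slice_z_mm"], dtype=float)

    def excitation_times(self) -> np.ndarray:
        """Time of each RF excitation, (rep, exc), seconds since scan start."""
        t_exc = self.t_abs - self.t_ro[None]
        # all lines of an excitation share the same excitation instant
        return t_exc[..., 0, 0]

    def copy(self) -> "KSpaceContainer":
        return KSpaceContainer(
            data=self.data.copy(),
            k_index=self.k_index.copy(),
            t_abs=self.t_abs.copy(),
            t_ro=self.t_ro.copy(),
            line_reversed=self.line_reversed.copy(),
            meta=dict(self.meta),
        )


def write_kspace(kset: KSpaceContainer, path: str | Path) -> None:
    """Write a :class:`KSpaceContainer` to a single HDF5 file (lossless)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=kset.data)
        fh.create_dataset("k_index", data=kset.k_index)
        fh.create_dataset("t_abs", data=kset.t_abs)
        fh.create_dataset("t_ro", data=kset.t_ro)
        fh.create_dataset("line_reversed", data=kset.line_reversed)
        grp = fh.create_group("meta")
        for key, val in kset.meta.items():
            if val is None:
                continue
            if isinstance(val, (list, tuple, np.ndarray)):
                grp.create_dataset(key, data=np.asarray(val))
            else:
                grp.attrs[key] = val


def read_kspace(path: str | Path) -> KSpaceContainer:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        for name in ("data", "k_index", "t_abs", "t_ro"):
            if name not in fh:
                raise FormatError(f"{path}: missing dataset '{name}'")
        if "meta" not in fh:
            raise FormatError(f"{path}: missing group 'meta'")
        meta: dict = {}
        grp = fh["meta"]
        for key, val in grp.attrs.items():
            meta[key] = val.item() if hasattr(val, "item") else val
        for key in grp:
            arr = np.asarray(grp[key])
            meta[key] = arr.tolist()
        data = np.asarray(fh["data"])
        if "line_reversed" in fh:
            rev = np.asarray(fh["line_reversed"], dtype=bool)
        else:
            rev = np.zeros(data.shape[3:6], dtype=bool)
        try:
            return KSpaceContainer(
                data=data,
                k_index=np.asarray(fh["k_index"]),
                t_abs=np.asarray(fh["t_abs"]),
                t_ro=np.asarray(fh["t_ro"]),
                line_reversed=rev,
                meta=meta,
            )
        except ConsistencyError:
            raise
        except ValueError as exc:  # pragma: no cover - defensive
            raise ConsistencyError(str(exc)) from exc


# ---------------------------------------------------------------------------
# NIfTI image volumes (magnitude/phase pairs) and masks
# ---------------------------------------------------------------------------

def write_nifti_pair(
    complex_data: np.ndarray,
    mag_path: str | Path,
    phase_path: str | Path,
    voxel_mm: tuple[float, ...] | None = None,
) -> None:
    """Store a complex array as magnitude + phase NIfTI files.

    Phase is stored in radians in (−π, π], matching scanner phase exports.
    """
    affine = np.eye(4)
    if voxel_mm is not None:
        for i, v in enumerate(voxel_mm[:3]):
            affine[i, i] = v
    mag = np.abs(complex_data).astype(np.float64)
    phs = np.angle(complex_data).astype(np.float64)
    nib.save(nib.Nifti1Image(mag, affine), str(mag_path))
    nib.save(nib.Nifti1Image(phs, affine), str(phase_path))


def read_nifti_pair(mag_path: str | Path, phase_path: str | Path) -> np.ndarray:
    """Load a magnitude/phase NIfTI pair back into a complex array."""
    mag = np.asarray(nib.load(str(mag_path)).dataobj, dtype=float)
    phs = np.asarray(nib.load(str(phase_path)).dataobj, dtype=float)
    if mag.shape != phs.shape:
        raise ConsistencyError("magnitude and phase volumes differ in shape")
    return mag * np.exp(1j * phs)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


# ---------------------------------------------------------------------------
# Calibration JSON, YAML config
# ---------------------------------------------------------------------------

def write_calibration_json(calib, path: str | Path) -> None:
    """Serialize a FieldCalibration (duck-typed) to JSON."""
    payload = {
        "z_mm": np.asarray(calib.z_mm, dtype=float).tolist(),
        "coupling_hz_per_unit": np.asarray(calib.coupling, dtype=float).tolist(),
        "residual_rms_hz": np.asarray(calib.residual_rms, dtype=float).tolist(),
        "fit_window_s": float(calib.fit_window),
        "excluded_frames": [int(i) for i in calib.excluded_frames],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_calibration_json(path: str | Path):
    from .calibration import FieldCalibration

    with open(path) as fh:
        payload = json.load(fh)
    return FieldCalibration(
        z_mm=np.asarray(payload["z_mm"], dtype=float),
        coupling=np.asarray(payload["coupling_hz_per_unit"], dtype=float),
        residual_rms=np.asarray(payload["residual_rms_hz"], dtype=float),
        fit_window=float(payload["fit_window_s"]),
        excluded_frames=list(payload["excluded_frames"]),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML config; the RNG seed is a top-level key and is logged."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    if "seed" in cfg:
        logger.info("config seed = %s", cfg["seed"])
    return cfg
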