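"""Cartesian multi-shot image reconstruction.

Encoding model per 2-D slice: the complex image x is weighted by each coil
sensitivity S_c, Fourier transformed (unitary, centered, DC at floor(N/2))
and sampled on the acquired phase-encode rows M:

    y_c = M F S_c x.

``cg_sense`` solves the least-squares problem min_x Σ_c ‖M F S_c x − y_c‖²
by conjugate gradients on the normal equations; with a full sampling mask
and a single unit-sensitivity coil this reduces to the inverse DFT, which
``fft_recon`` computes directly. ``epi_reference_correct`` removes the
odd/even readout-polarity phase discrepancy of segmented EPI using
phantom-derived reference coefficients, and ``rss_combine`` merges
multi-echo magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as spfft

from .io import ConsistencyError, KSpaceContainer

logger = logging.getLogger("breathfield")

__all__ = [
    "CoilSensitivities",
    "ImageVolume",
    "ReconDivergenceError",
    "fft2c",
    "ifft2c",
    "gather_kspace",
    "fft_recon",
    "cg_sense",
    "epi_reference_correct",
    "rss_combine",
]


class ReconDivergenceError(RuntimeError):
    """CG residual increased for several consecutive iterations."""


@dataclass
class CoilSensitivities:
    """Complex coil sensitivity maps, (coil, slice, ny, nx), with support mask."""

    maps: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 4:
            raise ValueError("sensitivity maps must be (coil, slice, ny, nx)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("sensitivities must be finite")
        rss = np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))
        if self.support is None:
            self.support = rss > 0
        else:
            self.support = np.asarray(self.support, dtype=bool)
            if np.any(self.support & (rss <= 0)):
                raise ValueError("zero coil RSS inside declared support")


@dataclass
class ImageVolume:
    """Reconstructed image stack with minimal geometry/echo annotation."""

    data: np.ndarray               # (slice, rep, echo, ny, nx) complex or float
    voxel_mm: tuple = (1.0, 1.0, 1.0)
    te_ms: Sequence[float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")


# ---------------------------------------------------------------------------
# Centered unitary DFT (DC at floor(N/2); Parseval holds exactly)
# ---------------------------------------------------------------------------

def fft2c(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


# ---------------------------------------------------------------------------
# Container → gridded k-space
# ---------------------------------------------------------------------------

def gather_kspace(
    kset: KSpaceContainer, slice_idx: int, rep: int, echo: int
) -> tuple[np.ndarray, np.ndarray]:
    """Grid the acquired lines of one (slice, rep, echo) onto the matrix.

    Returns (kgrid, row_mask): kgrid is (coil, ny, nx) with unacquired rows
    zero; row_mask marks acquired phase-encode rows.
    """
    ny, nx = kset.matrix
    nc = kset.n_coil
    kgrid = np.zeros((nc, ny, nx), dtype=np.complex128)
    row_mask = np.zeros(ny, dtype=bool)
    for exc in range(kset.n_exc):
        for line in range(kset.k_index.shape[2]):
            ky = int(kset.k_index[exc, echo, line])
            if row_mask[ky]:
                raise ConsistencyError(f"phase-encode row {ky} acquired twice")
            kgrid[:, ky, :] = kset.data[:, slice_idx, rep, exc, echo, line, :]
            row_mask[ky] = True
    return kgrid, row_mask


# ---------------------------------------------------------------------------
# Plain FFT reconstruction (fully sampled reference path)
# ---------------------------------------------------------------------------

def fft_recon(kset: KSpaceContainer, coil: int | None = None) -> ImageVolume:
    """Centered inverse 2-D DFT per slice/rep/echo (fully sampled data only).

    Returns complex coil images, (coil, slice, rep, echo, ny, nx); pass
    ``coil`` to restrict to one coil.
    """
    ny, nx = kset.matrix
    necho = kset.k_index.shape[1]
    coils = range(kset.n_coil) if coil is None else [coil]
    out = np.zeros(
        (len(coils), kset.n_slice, kset.n_rep, necho, ny, nx), dtype=np.complex128
    )
    for s in range(kset.n_slice):
        for r in range(kset.n_rep):
            for e in range(necho):
                kgrid, row_mask = gather_kspace(kset, s, r, e)
                if not row_mask.all():
                    raise ConsistencyError(
                        f"fft_recon requires full sampling; "
                        f"{int((~row_mask).sum())} rows missing"
                    )
                img = ifft2c(kgrid)
                for i, c in enumerate(coils):
                    out[i, s, r, e] = img[c]
    return ImageVolume(
        data=out,
        voxel_mm=tuple(kset.meta.get("voxel_mm", (1.0, 1.0, 1.0))),
        te_ms=list(np.atleast_1d(kset.meta.get("te_ms", []))),
    )


# ---------------------------------------------------------------------------
# CG-SENSE
# ---------------------------------------------------------------------------

def _normal_op(x: np.ndarray, sens: np.ndarray, row_mask: np.ndarray) -> np.ndarray:
    """E^H E x for the Cartesian SENSE encoding of one slice.

    ``x`` may carry a leading batch axis (several right-hand sides sharing
    the same sampling pattern and sensitivities). For even grid sizes the
    fftshift permutations commute with this circulant operator, so the
    plain (uncentered) DFT is used with the sampling mask unshifted — same
    operator, far fewer array rolls in the CG hot loop.
    """
    ny, nx = x.shape[-2:]
    coil_imgs = sens[None] * x[:, None]          # (B, coil, ny, nx)
    if ny % 2 == 0 and nx % 2 == 0:
        ksp = spfft.fft2(coil_imgs, norm="ortho", workers=1)
        ksp[:, :, np.fft.ifftshift(~row_mask), :] = 0.0
        back = spfft.ifft2(ksp, norm="ortho", overwrite_x=True, workers=1)
    else:  # pragma: no cover - odd matrices take the centered path
        ksp = fft2c(coil_imgs)
        ksp[:, :, ~row_mask, :] = 0.0
        back = ifft2c(ksp)
    return (np.conj(sens)[None] * back).sum(axis=1)


def _cg_solve(
    b: np.ndarray,
    sens: np.ndarray,
    row_mask: np.ndarray,
    n_iter: int,
    tol: float,
) -> np.ndarray:
    """Conjugate gradients on E^H E x = b from x = 0, batched over axis 0."""
    axes = tuple(range(1, b.ndim))
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.sum((r.conj() * r).real, axis=axes)      # (B,)
    b_norm = np.sqrt(rs.copy())
    active = b_norm > 0.0   # all-zero data → all-zero image at iteration 0
    n_rising = np.zeros(b.shape[0], dtype=int)
    prev = np.sqrt(rs)
    for _ in range(n_iter):
        active &= np.sqrt(rs) > tol * b_norm
        if not active.any():
            break
        ap = _normal_op(p, sens, row_mask)
        denom = np.sum((p.conj() * ap).real, axis=axes)
        if np.any(active & (denom <= 0.0)):
            raise ReconDivergenceError(
                "encoding normal operator not positive definite on search direction"
            )
        alpha = np.where(active, rs / np.where(denom > 0, denom, 1.0), 0.0)
        a = alpha.reshape((-1,) + (1,) * (b.ndim - 1))
        x = x + a * p
        r = r - a * ap
        rs_new = np.sum((r.conj() * r).real, axis=axes)
        res = np.sqrt(rs_new)
        n_rising = np.where(active & (res > prev), n_rising + 1, 0)
        if np.any(n_rising >= 3):
            raise ReconDivergenceError(
                "CG residual increased for 3 consecutive iterations"
            )
        prev = res
        beta = np.where(rs > 0, rs_new / np.where(rs > 0, rs, 1.0), 0.0)
        p = r + beta.reshape(a.shape) * p
        rs = rs_new
    return x


def cg_sense(
    kset: KSpaceContainer,
    sens: CoilSensitivities,
    n_iter: int = 30,
    tol: float = 1e-9,
) -> ImageVolume:
    """Iterative SENSE reconstruction by conjugate gradients.

    Solves E^H E x = E^H y per (slice, rep, echo), stopping at ``n_iter``
    iterations or relative residual below ``tol``. The sampling pattern plus
    sensitivities must make E^H E full rank (e.g. undersampling factor not
    exceeding the coil count).
    """
    ny, nx = kset.matrix
    necho = kset.k_index.shape[1]
    if sens.maps.shape != (kset.n_coil, kset.n_slice, ny, nx):
        raise ValueError(
            f"sensitivity maps {sens.maps.shape} do not match data "
            f"{(kset.n_coil, kset.n_slice, ny, nx)}"
        )
    out = np.zeros((kset.n_slice, kset.n_rep, necho, ny, nx), dtype=np.complex128)
    for s in range(kset.n_slice):
        smap = sens.maps[:, s]
        # all (rep, echo) problems of a slice share the sampling pattern and
        # sensitivities → solve them as one batched CG
        bs, masks = [], []
        for r in range(kset.n_rep):
            for e in range(necho):
                kgrid, row_mask = gather_kspace(kset, s, r, e)
                kgrid[:, ~row_mask, :] = 0.0
                bs.append((np.conj(smap) * ifft2c(kgrid)).sum(axis=0))
                masks.append(row_mask)
        if not all(np.array_equal(m, masks[0]) for m in masks):  # pragma: no cover
            raise ConsistencyError("sampling pattern differs across rep/echo")
        sol = _cg_solve(np.stack(bs), smap, masks[0], n_iter, tol)
        out[s] = sol.reshape(kset.n_rep, necho, ny, nx)
    return ImageVolume(
        data=out,
        voxel_mm=tuple(kset.meta.get("voxel_mm", (1.0, 1.0, 1.0))),
        te_ms=list(np.atleast_1d(kset.meta.get("te_ms", []))),
    )


# ---------------------------------------------------------------------------
# EPI reference-line (odd/even polarity) correction
# ---------------------------------------------------------------------------

def _hybrid_phase(nx: int, a0: float, a1: float) -> np.ndarray:
    """exp(i(a0 + a1·(x − floor(nx/2)))) along the readout axis."""
    x = np.arange(nx) - nx // 2
    return np.exp(1j * (a0 + a1 * x))


def epi_reference_correct(
    kset: KSpaceContainer, ref_lines: np.ndarray | None
) -> KSpaceContainer:
    """Remove the odd/even readout phase discrepancy of segmented EPI.

    ``ref_lines`` holds per-slice (constant, linear) phase coefficients
    [rad, rad/sample] measured from phantom phase-correction lines. Each
    reversed-polarity line is transformed to hybrid (x, k_y) space, the
    fitted constant + linear phase is removed, and the line transformed
    back. Non-idempotent: guarded by the ``epi_ref_applied`` meta flag.
    """
    if ref_lines is None:
        raise ValueError(
            "EPI data requires reference phase-correction coefficients"
        )
    if kset.meta.get("epi_ref_applied", False):
        raise ValueError("EPI reference correction already applied to this container")
    ref = np.atleast_2d(np.asarray(ref_lines, dtype=float))
    if ref.shape != (kset.n_slice, 2):
        raise ValueError(f"ref_lines must be (n_slice, 2), got {ref.shape}")
    out = kset.copy()
    nx = kset.data.shape[-1]
    rev = kset.line_reversed
    for s in range(kset.n_slice):
        corr = np.conj(_hybrid_phase(nx, ref[s, 0], ref[s, 1]))
        for exc, echo, line in zip(*np.nonzero(rev)):
            row = out.data[:, s, :, exc, echo, line, :]
            hyb = np.fft.fftshift(
                np.fft.ifft(np.fft.ifftshift(row, axes=-1), axis=-1, norm="ortho"),
                axes=-1,
            )
            hyb *= corr
            out.data[:, s, :, exc, echo, line, :] = np.fft.fftshift(
                np.fft.fft(np.fft.ifftshift(hyb, axes=-1), axis=-1, norm="ortho"),
                axes=-1,
            )
    out.meta["epi_ref_applied"] = True
    return out


# ---------------------------------------------------------------------------
# Echo combination
# ---------------------------------------------------------------------------

def rss_combine(echo_images: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Root-sum-of-squares combination over the echo axis.

    Accepts a sequence of same-shaped echo images or an array whose leading
    axis indexes echoes; returns sqrt(Σ_e |I_e|²). Invariant under a global
    phase on any echo.
    """
    if isinstance(echo_images, np.ndarray):
        stack = echo_images
    else:
        shapes = {np.asarray(e).shape for e in echo_images}
        if len(shapes) != 1:
            raise ConsistencyError(f"echo geometries differ: {shapes}")
        stack = np.stack([np.asarray(e) for e in echo_images], axis=0)
    if stack.shape[0] < 1:
        raise ValueError("need at least one echo")
    return np.sqrt((np.abs(stack) ** 2).sum(axis=0))
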