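"""CTF corrections and focal-series reconstructions.

The two halves of the CTF correspond to the two conjugate Ewald spheres.
Correcting every image transform with the unit-modulus factor i·exp(+iγ_j)
flattens the sphere at w = −(λ/2)s² (the "upper" sphere) while doubling the
curvature of the other; averaging the corrected transforms over the series is
the parabolic reconstruction — a complex image deliberately without Friedel
symmetry.  The conjugate factor −i·exp(−iγ_j) flattens the other sphere, and
the real factor 2 sin γ_j is the full (projection-approximation) CTF.

The constant quadrature factor i matches the weak-phase rendering convention:
after upper-sphere correction the structure lands on the real axis and the
unscattered mean at phase π/2 + χ.  No division by the CTF is performed
anywhere — corrections are unit-modulus (or the bounded 2 sin γ), so noise is
never amplified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .ctf_fit import CtfFitResult
from .fourier import friedel_mate, pad_with_mean
from .optics import FrequencyGrid, MicroscopeParams, SeriesGeometry, aberration_phase, ewald_offset
from .synthesize import FocalSeries

__all__ = [
    "ComplexReconstruction",
    "parabolic_reconstruct",
    "correct_stack",
    "ssb_reconstruct",
    "mask_shift_flatten",
    "extract_tile",
]


@dataclass
class ComplexReconstruction:
    """Complex 2D reconstruction, in real or frequency space.

    ``half`` records which CTF half produced it: ``upper``, ``lower``,
    ``full``, ``ssb-P`` or ``ssb-Q``.  Upper/lower reconstructions carry
    Ewald-sphere information and are *not* Friedel symmetric.
    """

    values: np.ndarray
    pixel: float
    space: str = "real"  # "real" | "freq"
    half: str = "upper"
    pad_factor: int = 1
    geometry: SeriesGeometry | None = None

    def __post_init__(self) -> None:
        if self.space not in ("real", "freq"):
            raise ValueError(f"unknown space {self.space!r}")

    def real_values(self) -> np.ndarray:
        return self.values if self.space == "real" else np.fft.ifft2(self.values)

    def freq_values(self) -> np.ndarray:
        """Frequency-space values in FFT (origin-at-corner) layout."""
        return np.fft.fft2(self.values) if self.space == "real" else self.values

    def amplitude(self) -> np.ndarray:
        return np.abs(self.real_values())

    def phase(self) -> np.ndarray:
        return np.angle(self.real_values())

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.values.shape[-1], self.pixel, "fft")


def _resolve(series: FocalSeries, fit) -> tuple[MicroscopeParams, SeriesGeometry]:
    """Microscope/geometry from a CtfFitResult or an explicit SeriesGeometry."""
    if isinstance(fit, CtfFitResult):
        mp = replace(series.microscope, cs=fit.cs)
        geom = fit.geometry(series.geometry.n_images)
    elif isinstance(fit, SeriesGeometry):
        mp, geom = series.microscope, fit
    else:
        raise TypeError(f"fit must be CtfFitResult or SeriesGeometry, got {type(fit)}")
    if geom.n_images != series.stack.shape[0]:
        raise ValueError("fit geometry does not cover the series")
    return mp, geom


def _correction(mode: str, gamma: np.ndarray) -> np.ndarray:
    if mode == "upper":
        return 1j * np.exp(1j * gamma)
    if mode == "lower":
        return -1j * np.exp(-1j * gamma)
    if mode == "full":
        return 2.0 * np.sin(gamma)
    if mode == "flip":  # pure phase flipping, kept as an option
        return np.sign(np.sin(gamma))
    raise ValueError(f"unknown correction mode {mode!r}")


def parabolic_reconstruct(
    series: FocalSeries,
    fit: CtfFitResult | SeriesGeometry,
    conjugate: bool = False,
    pad: bool = False,
) -> ComplexReconstruction:
    """Half-CTF (parabola-method) reconstruction of a focal series.

    Each image transform is multiplied by i·exp(+iγ_j) — or the conjugate
    factor when ``conjugate`` — and the corrected transforms are averaged;
    the back transform is the complex real-space reconstruction.  With
    ``pad`` each image is first embedded in a mean-filled frame of twice its
    size so delocalized signal can be recovered beyond tile edges.
    """
    mp, geom = _resolve(series, fit)
    n = series.n
    size = 2 * n if pad else n
    grid = FrequencyGrid(size, series.pixel, "fft")
    s, phi = grid.s, grid.phi
    mode = "lower" if conjugate else "upper"
    acc = np.zeros((size, size), dtype=complex)
    for j, ddf in enumerate(geom.offsets):
        img = series.stack[j]
        if pad:
            img = pad_with_mean(img, (size, size))
        gamma = aberration_phase(mp, geom, s, phi, extra_defocus=ddf)
        acc += np.fft.fft2(img) * _correction(mode, gamma)
    acc /= geom.n_images
    return ComplexReconstruction(
        np.fft.ifft2(acc),
        series.pixel,
        space="real",
        half=mode,
        pad_factor=2 if pad else 1,
        geometry=geom,
    )


def correct_stack(
    series: FocalSeries,
    fit: CtfFitResult | SeriesGeometry,
    mode: str = "upper",
) -> np.ndarray:
    """Per-image CTF correction, returning the complex real-space stack.

    ``upper`` and ``lower`` apply the unit-modulus half-CTF factors
    (±i·exp(±iγ_j)); ``full`` applies the real transfer factor 2 sin γ_j.
    The corrected stack can be inspected in 3D: upper/lower flatten one
    sphere onto w = 0 and double the curvature of the other, full yields the
    central plane plus both doubled spheres.
    """
    mp, geom = _resolve(series, fit)
    grid = FrequencyGrid(series.n, series.pixel, "fft")
    s, phi = grid.s, grid.phi
    out = np.empty(series.stack.shape, dtype=complex)
    for j, ddf in enumerate(geom.offsets):
        gamma = aberration_phase(mp, geom, s, phi, extra_defocus=ddf)
        out[j] = np.fft.ifft2(np.fft.fft2(series.stack[j]) * _correction(mode, gamma))
    return out


def _sector_signs(n: int, split_angle: float) -> np.ndarray:
    """±1 per pixel over eight azimuthal sectors, split at ``split_angle``."""
    grid = FrequencyGrid(n, 1.0, "fft")
    rel = np.mod(grid.phi - split_angle, 2.0 * np.pi)
    sector = np.floor(rel / (np.pi / 4.0)).astype(int) % 8
    return np.where(sector < 4, 1.0, -1.0)


def ssb_reconstruct(
    series: FocalSeries,
    fit: CtfFitResult | SeriesGeometry,
    split_angle: float = np.pi / 2.0,
) -> tuple[ComplexReconstruction, ComplexReconstruction, np.ndarray]:
    """Single-side-band (CTFP/CTFQ) focal-series reconstruction.

    Each image transform is corrected with exp(−iγ) on one side of the
    dividing line at ``split_angle`` and exp(+iγ) on the other, evaluated
    over eight azimuthal sectors, then Friedel symmetry is imposed so the
    outputs are real.  P and Q use opposite sign assignments; the per-pixel
    sign pattern (centered layout) is returned as ``sign_map``.
    """
    mp, geom = _resolve(series, fit)
    n = series.n
    grid = FrequencyGrid(n, series.pixel, "fft")
    s, phi = grid.s, grid.phi
    signs = _sector_signs(n, split_angle)
    acc_p = np.zeros((n, n), dtype=complex)
    acc_q = np.zeros((n, n), dtype=complex)
    for j, ddf in enumerate(geom.offsets):
        gamma = aberration_phase(mp, geom, s, phi, extra_defocus=ddf)
        G = np.fft.fft2(series.stack[j])
        cp = G * np.exp(-1j * signs * gamma)
        cq = G * np.exp(1j * signs * gamma)
        acc_p += 0.5 * (cp + friedel_mate(cp))
        acc_q += 0.5 * (cq + friedel_mate(cq))
    acc_p /= geom.n_images
    acc_q /= geom.n_images
    P = ComplexReconstruction(np.fft.ifft2(acc_p), series.pixel, "real", "ssb-P",
                              geometry=geom)
    Q = ComplexReconstruction(np.fft.ifft2(acc_q), series.pixel, "real", "ssb-Q",
                              geometry=geom)
    return P, Q, np.fft.fftshift(signs)


def mask_shift_flatten(
    series: FocalSeries,
    reflections: Sequence[tuple[float, float]],
    box: tuple[int, int, int] = (20, 20, 3),
    sphere: str = "upper",
    shift: bool = True,
    w_shift: str = "exact",
) -> np.ndarray:
    """Isolate reflections on one Ewald sphere of the 3D transform and flatten.

    The stack is 3D Fourier transformed; a box mask (``box`` = u, v, w voxels,
    extents rounded up to odd so the mask set is symmetric about each spot) is
    placed at every reflection's predicted w plane — w = −(λ/2)s² for the
    upper sphere, +(λ/2)s² for the lower — the masked transform is shifted
    along w to the central section, and back transformed.  The returned
    complex stack is constant along z when the shift compensates the focal
    gradient.

    ``w_shift="exact"`` shifts by the exact (generally fractional) Ewald
    offset via the Fourier shift theorem; ``"integer"`` rolls by the nearest
    whole number of w voxels, as in the original experiment.  The reflections
    are assumed to lie on a single ring (one radial frequency), so one shift
    serves all of them.
    """
    if sphere not in ("upper", "lower"):
        raise ValueError(f"sphere must be 'upper' or 'lower', got {sphere!r}")
    if w_shift not in ("exact", "integer"):
        raise ValueError(f"w_shift must be 'exact' or 'integer', got {w_shift!r}")
    lam = series.microscope.wavelength
    nz, ny, nx = series.stack.shape
    grid = series.grid
    w_step = grid.w_step
    fstep = grid.freq_step
    F3 = np.fft.fftn(series.stack)
    mask = np.zeros(F3.shape, dtype=bool)
    bu, bv, bw = box
    radii = []
    for u, v in reflections:
        s = float(np.hypot(u, v))
        if s >= grid.nyquist:
            raise ValueError(f"reflection ({u}, {v}) outside the grid (Nyquist {grid.nyquist})")
        radii.append(s)
        m = int(round(ewald_offset(lam, s) / w_step))
        wc = -m if sphere == "upper" else m
        iu = int(round(u / fstep))
        iv = int(round(v / fstep))
        du = np.arange(-(bu // 2), bu // 2 + 1)
        dv = np.arange(-(bv // 2), bv // 2 + 1)
        dw = np.arange(-(bw // 2), bw // 2 + 1)
        zi = (wc + dw) % nz
        yi = (iv + dv) % ny
        xi = (iu + du) % nx
        mask[np.ix_(zi, yi, xi)] = True
    masked = np.where(mask, F3, 0.0)
    if not (shift and radii):
        return np.fft.ifftn(masked)
    w0 = ewald_offset(lam, float(np.mean(radii)))
    if w_shift == "integer":
        m = int(round(w0 / w_step))
        roll = m if sphere == "upper" else -m
        return np.fft.ifftn(np.roll(masked, roll, axis=0))
    # exact fractional shift: phase ramp in the focus (z) domain
    out = np.fft.ifftn(masked)
    z = np.arange(nz)[:, None, None] * series.geometry.focal_step
    sign = 1.0 if sphere == "upper" else -1.0
    return out * np.exp(2j * np.pi * sign * w0 * z)


def extract_tile(
    data: FocalSeries | np.ndarray,
    origin: tuple[int, int],
    size: int,
    pad_to: int | None = None,
):
    """Extract a square tile (optionally from every image of a series) and pad.

    ``origin`` is the (row, col) of the tile's top-left corner.  With
    ``pad_to`` the tile is embedded centrally in a frame of that size filled
    with the tile mean.
    """
    if pad_to is None:
        pad_to = size
    if pad_to < size:
        raise ValueError("pad_to must be >= size")

    def one(img: np.ndarray) -> np.ndarray:
        oy, ox = origin
        if oy < 0 or ox < 0 or oy + size > img.shape[0] or ox + size > img.shape[1]:
            raise ValueError(f"tile {origin}+{size} out of bounds for image {img.shape}")
        return pad_with_mean(img[oy : oy + size, ox : ox + size], (pad_to, pad_to))

    if isinstance(data, FocalSeries):
        stack = np.stack([one(img) for img in data.stack])
        return FocalSeries(stack, data.pixel, data.geometry, data.microscope,
                           provenance={**data.provenance, "tile": (origin, size, pad_to)})
    if data.ndim == 3:
        return np.stack([one(img) for img in data])
    return one(data)
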