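"""Power-spectrum machinery for focal series.

Tiled 2D power spectra per micrograph, 3D power spectra of the stack (which
show the two Ewald-sphere ridges), orthogonal sections, azimuthally averaged
ridge profiles, and the "modified power spectra" rescaling that turns Thon
oscillations into a CTF-shaped signal in [−1, 1] for fitting.

All spectra use orthonormal FFTs so Parseval holds: the total power of a tile
spectrum equals the real-space sum of squares.  Spectra are stored in
centered (display) layout with the zero frequency at index n//2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import FrequencyGrid
from .synthesize import FocalSeries

__all__ = [
    "SpectraStack",
    "Power3D",
    "ModifiedSpectraStack",
    "tile_power_spectra",
    "power3d",
    "power3d_of_stack",
    "extract_section",
    "ridge_profile",
    "RidgeProfile",
    "modified_power_spectra",
]


@dataclass
class SpectraStack:
    """Stack of averaged 2D tile power spectra, one per micrograph (centered)."""

    spectra: np.ndarray  # (n_images, tile, tile), >= 0
    tile: int
    n_tiles: int
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        if np.any(self.spectra < 0):
            raise ValueError("power spectra must be non-negative")


@dataclass
class Power3D:
    """Averaged 3D power spectrum |FFT₃|² of tile stacks, centered layout.

    ``volume`` has shape (n_images, tile, tile) with the w axis first.
    """

    volume: np.ndarray
    grid: FrequencyGrid

    @property
    def w_step(self) -> float:
        return self.grid.w_step


@dataclass
class ModifiedSpectraStack:
    """CTF-shaped rescaled power spectra I_mps(s, φ) in [−1, 1] per image.

    ``signal_power`` and ``noise_power`` are the smooth per-image estimates
    produced by the same decomposition.
    """

    mps: np.ndarray  # (n_images, tile, tile) in [−1, 1]
    signal_power: np.ndarray
    noise_power: np.ndarray
    sigma: float
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        if np.any(np.abs(self.mps) > 1 + 1e-12):
            raise ValueError("modified power spectra must lie in [−1, 1]")

    @property
    def n_images(self) -> int:
        return self.mps.shape[0]


def _tiles(image: np.ndarray, tile: int):
    """Abutting non-overlapping tile origins covering the image."""
    ny, nx = image.shape
    if tile > min(ny, nx):
        raise ValueError(f"tile size {tile} exceeds image size {image.shape}")
    for oy in range(0, ny - tile + 1, tile):
        for ox in range(0, nx - tile + 1, tile):
            yield image[oy : oy + tile, ox : ox + tile]


def tile_power_spectra(series: FocalSeries, tile: int | None = None) -> SpectraStack:
    """Averaged 2D power spectrum of abutting tiles, per micrograph."""
    if tile is None:
        tile = series.n
    out = np.zeros((series.geometry.n_images, tile, tile))
    n_tiles = 0
    for j in range(series.geometry.n_images):
        n_tiles = 0
        for t in _tiles(series.stack[j], tile):
            out[j] += np.abs(np.fft.fft2(t, norm="ortho")) ** 2
            n_tiles += 1
        out[j] /= n_tiles
    grid = FrequencyGrid(tile, series.pixel, "centered",
                         n_images=series.geometry.n_images,
                         focal_step=series.geometry.focal_step)
    return SpectraStack(np.fft.fftshift(out, axes=(1, 2)), tile, n_tiles, grid)


def power3d_of_stack(stack: np.ndarray, pixel: float, focal_step: float,
                     tile: int | None = None) -> Power3D:
    """3D power spectrum of an (n_images, n, n) stack (real or complex).

    Abutting (tile × tile × n_images) sub-stacks are Fourier transformed in
    3D, converted to power and averaged; the result is centered on all axes.
    """
    n_images, ny, nx = stack.shape
    if tile is None:
        tile = min(ny, nx)
    if tile > min(ny, nx):
        raise ValueError(f"tile size {tile} exceeds image size {(ny, nx)}")
    out = np.zeros((n_images, tile, tile))
    n_tiles = 0
    for oy in range(0, ny - tile + 1, tile):
        for ox in range(0, nx - tile + 1, tile):
            sub = stack[:, oy : oy + tile, ox : ox + tile]
            out += np.abs(np.fft.fftn(sub, norm="ortho")) ** 2
            n_tiles += 1
    out /= n_tiles
    grid = FrequencyGrid(tile, pixel, "centered", n_images=n_images, focal_step=focal_step)
    return Power3D(np.fft.fftshift(out), grid)


def power3d(series: FocalSeries, tile: int | None = None) -> Power3D:
    """3D power spectrum of a focal series (see :func:`power3d_of_stack`)."""
    return power3d_of_stack(series.stack, series.pixel, series.geometry.focal_step, tile)


def extract_section(vol: Power3D, plane: str, index: int | None = None) -> np.ndarray:
    """Orthogonal section through a 3D power spectrum.

    ``plane`` is ``"xy"`` (axial, fixed w), ``"xz"`` (fixed v row) or ``"yz"``
    (fixed u column); ``index`` defaults to the central section.
    """
    nz, ny, nx = vol.volume.shape
    if plane == "xy":
        idx = nz // 2 if index is None else index
        if not 0 <= idx < nz:
            raise IndexError(f"section index {idx} out of range for axis of size {nz}")
        return vol.volume[idx]
    if plane == "xz":
        idx = ny // 2 if index is None else index
        if not 0 <= idx < ny:
            raise IndexError(f"section index {idx} out of range for axis of size {ny}")
        return vol.volume[:, idx, :]
    if plane == "yz":
        idx = nx // 2 if index is None else index
        if not 0 <= idx < nx:
            raise IndexError(f"section index {idx} out of range for axis of size {nx}")
        return vol.volume[:, :, idx]
    raise ValueError(f"unknown plane {plane!r}")


def _quadratic_peak(x: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Sub-sample extremum location by quadratic interpolation around idx."""
    if idx <= 0 or idx >= len(y) - 1:
        return float(x[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[idx])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[idx] + delta * (x[1] - x[0]))


@dataclass
class RidgeProfile:
    """Azimuthally averaged w-profile of a 3D power spectrum at fixed s."""

    w: np.ndarray  # Å⁻¹, centered and increasing
    intensity: np.ndarray
    s: float

    def peak_positions(self) -> tuple[float, float]:
        """(w⁻, w⁺) locations of the strongest negative-w and positive-w peaks,
        by quadratic interpolation."""
        centre = len(self.w) // 2
        neg = int(np.argmax(self.intensity[:centre]))
        pos = centre + int(np.argmax(self.intensity[centre:]))
        return (
            _quadratic_peak(self.w, self.intensity, neg),
            _quadratic_peak(self.w, self.intensity, pos),
        )

    def first_node(self, side: str = "outer") -> float:
        """w of the first minimum outward from the positive-w peak."""
        centre = len(self.w) // 2
        pos = centre + int(np.argmax(self.intensity[centre:]))
        for i in range(pos + 1, len(self.w) - 1):
            if self.intensity[i] <= self.intensity[i - 1] and self.intensity[i] <= self.intensity[i + 1]:
                return _quadratic_peak(self.w, self.intensity, i)
        return float(self.w[-1])


def ridge_profile(vol: Power3D, s: float) -> RidgeProfile:
    """Azimuthally averaged profile along w at radial frequency ``s``.

    Pixels within half a frequency step of the shell radius are averaged at
    each w plane.
    """
    grid = vol.grid
    if s >= grid.nyquist:
        raise ValueError(f"s = {s} exceeds Nyquist {grid.nyquist}")
    srad = grid.s  # centered layout
    shell = np.abs(srad - s) <= grid.freq_step / 2
    if not np.any(shell):
        raise ValueError(f"no grid points in shell at s = {s}")
    profile = vol.volume[:, shell].mean(axis=1)
    return RidgeProfile(grid.w_axis(), profile, s)


def modified_power_spectra(spectra: SpectraStack, sigma: float = 10.0,
                           eps: float = 1e-12) -> ModifiedSpectraStack:
    """Rescale power spectra into CTF-shaped images in [−1, 1].

    Per image: a Gaussian-smoothed copy (image 1) estimates noise power plus
    half the signal power; subtracting it leaves oscillations about zero
    (image 2); π times the smoothed |image 2| estimates the signal power
    (image 3, using mean(|cos|) = 2/π); image 2 divided by half of image 3
    and clamped to [−1, 1] approximates −cos 2γ.  The division is guarded
    where the signal estimate is below ``eps``.
    """
    if sigma <= 0:
        raise ValueError("smoothing sigma must be positive")
    P = spectra.spectra
    mps = np.empty_like(P)
    signal = np.empty_like(P)
    noise = np.empty_like(P)
    for j in range(P.shape[0]):
        im1 = gaussian_filter(P[j], sigma, mode="reflect")
        im2 = P[j] - im1
        im3 = np.pi * gaussian_filter(np.abs(im2), sigma, mode="reflect")
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(im3 > eps, im2 / (im3 / 2.0), 0.0)
        mps[j] = np.clip(m, -1.0, 1.0)
        signal[j] = im3
        noise[j] = im1 - im3 / 2.0
    return ModifiedSpectraStack(mps, signal, noise, sigma, spectra.grid)
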