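"""Quantitative assessment: spectral SNR, Fourier ring correlation,
Friedel asymmetry and real-space phase statistics.

SSNR is estimated per Fourier shell from repeated realizations of the same
signal: with n repeats, SSNR = max(0, (n·|F̄|² − σ̂²) / σ̂²), where F̄ is the
component-wise mean transform and σ̂² the unbiased per-component residual
variance — the SSNR of the summed (averaged) set, the convention used for
movie-frame and reconstruction quality curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import ComplexReconstruction, parabolic_reconstruct
from .synthesize import FocalSeries

__all__ = [
    "ShellCurve",
    "PhaseStats",
    "radial_shells",
    "ssnr",
    "snr_gain",
    "frc",
    "phase_stats",
    "friedel_asymmetry",
]

SSNR_CAP = 1e12


@dataclass
class ShellCurve:
    """Per-shell curve over radial frequency (Å⁻¹)."""

    shells: np.ndarray
    values: np.ndarray
    n_terms: np.ndarray
    capped: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.shells) <= 0):
            raise ValueError("shell centers must be strictly increasing")


@dataclass
class PhaseStats:
    """Histogram summary of real-space phases."""

    histogram: np.ndarray  # density over (−π, π]
    bin_edges: np.ndarray
    peak: float  # mode location, rad
    polar_summary: tuple[float, float]  # mean resultant (length, angle)


def radial_shells(n: int, pixel: float = 1.0):
    """Integer-radius shell labels for an n×n FFT-layout grid.

    Returns (labels, shell centers in Å⁻¹, counts); shells run 0 .. n//2.
    """
    k = np.fft.fftfreq(n) * n
    r = np.hypot(k[:, None], k[None, :])
    labels = np.rint(r).astype(int)
    nshell = n // 2 + 1
    valid = labels < nshell
    counts = np.bincount(labels[valid].ravel(), minlength=nshell)
    centers = np.arange(nshell) / (n * pixel)
    return labels, valid, centers, counts


def _shell_mean(values: np.ndarray, labels, valid, nshell: int) -> np.ndarray:
    sums = np.bincount(labels[valid].ravel(), weights=values[valid].ravel(),
                       minlength=nshell)
    counts = np.bincount(labels[valid].ravel(), minlength=nshell)
    return sums / np.maximum(counts, 1)


def ssnr(repeats: np.ndarray, pixel: float = 1.0) -> ShellCurve:
    """Shell SSNR of the summed set, from n ≥ 2 aligned repeats.

    ``repeats`` is an (n, ny, nx) stack, real (transformed internally) or
    complex frequency-space.  Negative estimates are clamped to zero; shells
    with zero residual variance are capped at ``SSNR_CAP`` and flagged.
    """
    repeats = np.asarray(repeats)
    if repeats.ndim != 3 or repeats.shape[0] < 2:
        raise ValueError("need a stack of at least 2 repeats")
    n_rep = repeats.shape[0]
    if np.isrealobj(repeats):
        F = np.fft.fft2(repeats, axes=(-2, -1), norm="ortho")
    else:
        F = repeats
    n = F.shape[-1]
    labels, valid, centers, counts = radial_shells(n, pixel)
    nshell = len(centers)
    Fbar = F.mean(axis=0)
    resid = np.sum(np.abs(F - Fbar) ** 2, axis=0) / (n_rep - 1)
    sig = _shell_mean(np.abs(Fbar) ** 2, labels, valid, nshell)
    var = _shell_mean(resid, labels, valid, nshell)
    capped = False
    values = np.empty(nshell)
    for i in range(nshell):
        if var[i] <= 0:
            values[i] = SSNR_CAP if sig[i] > 0 else 0.0
            capped = capped or sig[i] > 0
        else:
            values[i] = max(0.0, (n_rep * sig[i] - var[i]) / var[i])
    return ShellCurve(centers, values, counts, capped)


def snr_gain(
    series: FocalSeries,
    fit,
    noise_sd: float | None = None,
    repeats: int = 20,
    seed: int = 0,
    max_frequency: float | None = None,
    min_single_ssnr: float = 0.1,
) -> float:
    """SNR gain of the parabolic reconstruction over a single micrograph.

    ``series`` is a noiseless (signal) series; ``repeats`` noisy realizations
    are synthesized with i.i.d. Gaussian noise of sd ``noise_sd`` (default:
    the contrast RMS of the middle image).  The gain is the mean over shells
    of sqrt(SSNR_reconstruction / SSNR_micrograph), restricted to shells
    carrying signal and lying below the coherent-averaging frequency
    s = (1/(2πλΔf_r))^1/2, inside which both Ewald-sphere terms add
    coherently across the series and the expected gain is n^1/2.
    """
    mid = series.stack[series.geometry.n_images // 2]
    if noise_sd is None:
        noise_sd = float(np.std(mid - mid.mean()))
        if noise_sd == 0:
            noise_sd = 1.0
    lam = series.microscope.wavelength
    fr = series.geometry.focal_range
    if max_frequency is None:
        max_frequency = np.sqrt(1.0 / (2.0 * np.pi * lam * fr)) if fr > 0 else np.inf
    rng = np.random.default_rng(seed)
    recs = []
    mics = []
    for _ in range(repeats):
        noisy = FocalSeries(
            series.stack + rng.normal(0.0, noise_sd, series.stack.shape),
            series.pixel, series.geometry, series.microscope,
        )
        rec = parabolic_reconstruct(noisy, fit)
        recs.append(rec.freq_values())
        mics.append(noisy.stack[series.geometry.n_images // 2])
    curve_rec = ssnr(np.stack(recs), series.pixel)
    curve_mic = ssnr(np.stack(mics), series.pixel)
    single = curve_mic.values / repeats  # estimator measures the summed set
    sel = (
        (single > min_single_ssnr)
        & (curve_mic.shells <= max_frequency)
        & (curve_mic.shells > 0)
        & np.isfinite(curve_rec.values)
        & (curve_mic.values > 0)
    )
    if not np.any(sel):
        raise ValueError("no qualifying shells for the SNR gain estimate")
    ratio = curve_rec.values[sel] / curve_mic.values[sel]
    return float(np.mean(np.sqrt(ratio)))


def frc(a: np.ndarray, b: np.ndarray, pixel: float = 1.0) -> ShellCurve:
    """Fourier ring correlation between two images of equal shape."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    A = np.fft.fft2(a)
    B = np.fft.fft2(b)
    n = a.shape[-1]
    labels, valid, centers, counts = radial_shells(n, pixel)
    nshell = len(centers)
    cross = _shell_mean((A * np.conj(B)).real, labels, valid, nshell)
    pa = _shell_mean(np.abs(A) ** 2, labels, valid, nshell)
    pb = _shell_mean(np.abs(B) ** 2, labels, valid, nshell)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where((pa > 0) & (pb > 0), cross / np.sqrt(pa * pb), 0.0)
    return ShellCurve(centers, np.clip(vals, -1.0, 1.0), counts)


def phase_stats(
    rec: ComplexReconstruction | np.ndarray,
    band: tuple[float, float] | None = None,
    drop_dc: bool = False,
    bins: int = 360,
) -> PhaseStats:
    """Real-space phase histogram, mode and mean resultant vector.

    ``band`` = (d_min, d_max) in Å keeps frequencies 1/d_max ≤ s ≤ 1/d_min
    before phase extraction; ``drop_dc`` removes the zero frequency.  The
    mode is located by parabolic interpolation over the peak bin.
    """
    if isinstance(rec, ComplexReconstruction):
        vals = rec.real_values()
        pixel = rec.pixel
    else:
        vals = np.asarray(rec)
        pixel = 1.0
    if band is not None or drop_dc:
        F = np.fft.fft2(vals)
        if drop_dc:
            F[0, 0] = 0.0
        if band is not None:
            d_min, d_max = sorted(band)
            if d_min <= 0:
                raise ValueError(f"band resolutions must be positive, got {band}")
            n = vals.shape[-1]
            f = np.fft.fftfreq(n, d=pixel)
            s = np.hypot(f[:, None], f[None, :])
            keep = (s >= 1.0 / d_max) & (s <= 1.0 / d_min)
            if not np.any(keep):
                raise ValueError(f"band {band} Å is empty on this grid")
            F = np.where(keep, F, 0.0)
        vals = np.fft.ifft2(F)
    phases = np.angle(vals).ravel()
    hist, edges = np.histogram(phases, bins=bins, range=(-np.pi, np.pi), density=True)
    ipk = int(np.argmax(hist))
    # circular quadratic interpolation around the peak bin
    y0, y1, y2 = hist[(ipk - 1) % bins], hist[ipk], hist[(ipk + 1) % bins]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    width = edges[1] - edges[0]
    peak = float(edges[ipk] + width * (0.5 + delta))
    peak = (peak + np.pi) % (2 * np.pi) - np.pi
    resultant = np.mean(np.exp(1j * phases))
    return PhaseStats(hist, edges, peak, (float(np.abs(resultant)), float(np.angle(resultant))))


def friedel_asymmetry(rec: ComplexReconstruction | np.ndarray,
                      pixel: float = 1.0) -> ShellCurve:
    """Per-shell Friedel asymmetry mean|F(k) − F*(−k)| / mean|F(k)|.

    Zero for the transform of a real image; grows beyond the Ewald-sphere
    separation frequency for half-CTF-corrected data with 3D structure.
    """
    if isinstance(rec, ComplexReconstruction):
        F = rec.freq_values()
        pixel = rec.pixel
    else:
        F = np.asarray(rec)
    from .fourier import friedel_mate

    n = F.shape[-1]
    labels, valid, centers, counts = radial_shells(n, pixel)
    nshell = len(centers)
    asym = _shell_mean(np.abs(F - friedel_mate(F)), labels, valid, nshell)
    amp = _shell_mean(np.abs(F), labels, valid, nshell)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(amp > 0, asym / amp, 0.0)
    return ShellCurve(centers, vals, counts)
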