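"""Closed-form electron optics: wavelength, aberration phase, Fresnel propagation,
Ewald-sphere geometry and related analytic quantities.

Conventions (fixed once for the whole package):

* Lengths in ångström, spatial frequencies in Å⁻¹, angles in radians,
  accelerating voltage in kV.
* Positive defocus means underfocus; the aberration phase increases with
  defocus at fixed frequency:

      γ(s, φ) = χ + π λ Δf_eff s² − (π/2) C_s λ³ s⁴,
      Δf_eff  = Δf + extra_defocus + Δf_d cos 2(φ − α),

  where χ is the constant amplitude-contrast phase, Δf_d and α describe
  astigmatism and C_s is the spherical aberration coefficient.
* Free-space propagation by a distance z multiplies a structure factor by the
  Fresnel propagator exp(−iπ λ z s²); the "upper" Ewald sphere sits at
  w = −(λ/2) s² in the 3D frequency space of a focal series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    ELECTRON_MASS,
    ELEMENTARY_CHARGE,
    METERS_TO_ANGSTROM,
    PLANCK_H,
    SPEED_OF_LIGHT,
)

__all__ = [
    "MicroscopeParams",
    "SeriesGeometry",
    "FrequencyGrid",
    "electron_wavelength",
    "electron_beta",
    "aberration_phase",
    "fresnel_propagator",
    "ewald_offset",
    "separation_resolution",
    "delocalization",
    "tilt_from_astig",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength (Å) of an electron at ``voltage_kv`` kV.

    λ = h / sqrt(2 m e V (1 + eV / 2mc²))
    """
    if voltage_kv <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    volts = voltage_kv * 1e3
    rest = ELECTRON_MASS * SPEED_OF_LIGHT**2
    p2 = 2.0 * ELECTRON_MASS * ELEMENTARY_CHARGE * volts * (
        1.0 + ELEMENTARY_CHARGE * volts / (2.0 * rest)
    )
    return PLANCK_H / math.sqrt(p2) * METERS_TO_ANGSTROM


def electron_beta(voltage_kv: float) -> float:
    """Electron speed relative to light speed (dimensionless, 0 < β < 1)."""
    if voltage_kv <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    rest = ELECTRON_MASS * SPEED_OF_LIGHT**2
    gamma = 1.0 + ELEMENTARY_CHARGE * voltage_kv * 1e3 / rest
    return math.sqrt(1.0 - 1.0 / gamma**2)


@dataclass(frozen=True)
class MicroscopeParams:
    """Microscope state relevant to the contrast transfer function.

    Parameters
    ----------
    voltage : float
        Accelerating voltage in kV.
    cs : float
        Spherical aberration coefficient C_s in Å (e.g. 1.4e7 Å = 1.4 mm).
    amp_phase : float
        Constant amplitude-contrast phase shift χ in radians.
    """

    voltage: float
    cs: float = 0.0
    amp_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength λ in Å."""
        return electron_wavelength(self.voltage)

    @property
    def beta(self) -> float:
        """Electron speed relative to light speed."""
        return electron_beta(self.voltage)


@dataclass(frozen=True)
class SeriesGeometry:
    """Defocus geometry of a focal series.

    The per-image focal offsets form an arithmetic ramp with common
    difference ``focal_step`` centred on the reference (middle) image:
    zero at the middle index for odd ``n_images``, straddling zero for even.
    """

    n_images: int
    focal_step: float  # δf, Å
    mid_defocus: float  # Δf of the reference image, Å (positive = underfocus)
    astig_dev: float = 0.0  # Δf_d, Å
    astig_angle: float = 0.0  # α, rad

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")

    @property
    def offsets(self) -> np.ndarray:
        """Per-image focal offsets ΔΔf_j relative to the reference image (Å)."""
        j = np.arange(self.n_images, dtype=float)
        return (j - (self.n_images - 1) / 2.0) * self.focal_step

    @property
    def defoci(self) -> np.ndarray:
        """Absolute per-image defocus Δf + ΔΔf_j (Å)."""
        return self.mid_defocus + self.offsets

    @property
    def focal_range(self) -> float:
        """Δf_r = ΔΔf_max − ΔΔf_min (Å)."""
        return (self.n_images - 1) * self.focal_step

    @property
    def dft_range(self) -> float:
        """Focus extent sampled by the series DFT, n_images · δf (Å)."""
        return self.n_images * self.focal_step


@dataclass(frozen=True)
class FrequencyGrid:
    """Spatial-frequency coordinates of an n×n image with square pixels.

    Arrays are indexed ``[row, col]`` with u (the x frequency) varying along
    columns and v along rows.  ``layout`` is either ``"fft"`` (origin at the
    corner, numpy FFT order) or ``"centered"`` (origin at ``n//2``, display
    order); conversion between the two is a lossless ``fftshift``.
    """

    n: int
    pixel: float
    layout: str = "fft"
    n_images: int | None = None
    focal_step: float | None = None

    def __post_init__(self) -> None:
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")
        if self.layout not in ("fft", "centered"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel)

    @property
    def freq_step(self) -> float:
        return 1.0 / (self.n * self.pixel)

    @property
    def w_step(self) -> float:
        """w-axis sampling of the series' 3D transform, 1/(n_images·δf) (Å⁻¹)."""
        if self.n_images is None or self.focal_step is None:
            raise ValueError("grid carries no stack (w) axis")
        return 1.0 / (self.n_images * self.focal_step)

    def axis(self) -> np.ndarray:
        """1D frequency coordinate in the current layout (Å⁻¹)."""
        f = np.fft.fftfreq(self.n, d=self.pixel)
        return np.fft.fftshift(f) if self.layout == "centered" else f

    @property
    def u(self) -> np.ndarray:
        """2D x-frequency coordinate (Å⁻¹)."""
        return np.broadcast_to(self.axis()[None, :], (self.n, self.n))

    @property
    def v(self) -> np.ndarray:
        """2D y-frequency coordinate (Å⁻¹)."""
        return np.broadcast_to(self.axis()[:, None], (self.n, self.n))

    @property
    def s(self) -> np.ndarray:
        """Radial frequency (u² + v²)^1/2 (Å⁻¹)."""
        return np.hypot(self.u, self.v)

    @property
    def phi(self) -> np.ndarray:
        """Azimuth tan⁻¹(v/u) (rad)."""
        return np.arctan2(self.v, self.u)

    def w_axis(self) -> np.ndarray:
        """1D w coordinate of the stack axis in the current layout (Å⁻¹)."""
        if self.n_images is None or self.focal_step is None:
            raise ValueError("grid carries no stack (w) axis")
        f = np.fft.fftfreq(self.n_images, d=self.focal_step)
        return np.fft.fftshift(f) if self.layout == "centered" else f

    def with_layout(self, layout: str) -> "FrequencyGrid":
        return FrequencyGrid(self.n, self.pixel, layout, self.n_images, self.focal_step)


def aberration_phase(
    mp: MicroscopeParams,
    geom: SeriesGeometry | None,
    s,
    phi=0.0,
    extra_defocus=0.0,
):
    """Aberration phase γ (rad) at radial frequency ``s`` and azimuth ``phi``.

    ``extra_defocus`` folds any additional focus change — an atom's z
    coordinate or an image's focal offset ΔΔf_j — into the defocus term,
    since both enter γ identically.  ``geom=None`` means zero defocus and
    no astigmatism (only χ and the C_s term remain).
    """
    s = np.asarray(s, dtype=float)
    lam = mp.wavelength
    if geom is None:
        df_eff = np.asarray(extra_defocus, dtype=float)
    else:
        df_eff = geom.mid_defocus + np.asarray(extra_defocus, dtype=float)
        if geom.astig_dev != 0.0:
            df_eff = df_eff + geom.astig_dev * np.cos(2.0 * (np.asarray(phi) - geom.astig_angle))
    s2 = s * s
    gamma = mp.amp_phase + math.pi * lam * df_eff * s2 - 0.5 * math.pi * mp.cs * lam**3 * s2 * s2
    return gamma


def fresnel_propagator(lam: float, z, s):
    """Unit-modulus free-space propagation factor exp(−iπ λ z s²)."""
    s = np.asarray(s, dtype=float)
    return np.exp(-1j * np.pi * lam * np.asarray(z, dtype=float) * s * s)


def ewald_offset(lam: float, s) -> np.ndarray:
    """Magnitude of the Ewald-sphere w offset, (λ/2) s² (Å⁻¹).

    The upper sphere peaks at w = −(λ/2)s²; the caller chooses the sign.
    """
    s = np.asarray(s, dtype=float)
    return 0.5 * lam * s * s


def separation_resolution(lam: float, focal_range: float) -> float:
    """Real-space resolution (Å) below which the two Ewald spheres are resolved.

    d = (λ · Δf_r)^1/2: at frequencies beyond 1/d the spheres are separated by
    more than the w-resolution 1/Δf_r of the focal series.
    """
    if lam <= 0 or focal_range <= 0:
        raise ValueError("wavelength and focal range must be positive")
    return math.sqrt(lam * focal_range)


def delocalization(lam: float, defocus: float, s) -> np.ndarray:
    """First-order delocalization radius λ·|Δf|·s (Å), ignoring C_s."""
    s = np.asarray(s, dtype=float)
    return lam * abs(defocus) * s


def tilt_from_astig(astig_dev: float, cs: float) -> float:
    """Beam tilt (rad) inferred from tilt-induced astigmatism.

    A beam tilt t through a lens with spherical aberration C_s induces a
    focal deviation Δf_d = C_s t², hence t = (Δf_d / C_s)^1/2.
    """
    if cs <= 0:
        raise ValueError("cs must be positive")
    if astig_dev < 0:
        raise ValueError("astig_dev must be non-negative")
    return math.sqrt(astig_dev / cs)
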