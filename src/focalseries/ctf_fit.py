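"""Fitting the even-term CTF to a focal series' modified power spectra.

The modified power spectra approximate −cos 2γ_e, where γ_e is the even
aberration phase (χ, defocus, astigmatism, C_s).  The objective is the
Pearson correlation between the observed I_mps and that model over a
resolution annulus, for all images at once.  Fitting is stepwise: a linear
defocus search and three-parameter simplex on transverse (xz/yz) sections,
then a five-parameter downhill-simplex refinement on the full stack.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.optimize import minimize

from .optics import MicroscopeParams, SeriesGeometry, aberration_phase
from .spectra import ModifiedSpectraStack

__all__ = [
    "CtfFitResult",
    "SectionFit",
    "DEFAULT_LIMITS",
    "objective_cc",
    "fit_section",
    "fit_stack",
    "fit_focal_series",
    "render_fit_overlay",
]

#: default resolution range for fitting, (low, high) in Å
DEFAULT_LIMITS = (40.0, 2.5)

_SIMPLEX_STEPS = {"mid_defocus": 100.0, "focal_step": 1.0, "cs": 1e5,
                  "astig_dev": 50.0, "astig_angle": 0.1}


@dataclass
class SectionFit:
    """Three-parameter fit from a transverse section."""

    mid_defocus: float
    focal_step: float
    cs: float
    objective: float
    plane: str


@dataclass
class CtfFitResult:
    """Result of the five-parameter CTF fit to a focal series."""

    mid_defocus: float
    focal_step: float
    cs: float
    astig_dev: float
    astig_angle: float
    objective: float
    resolution_limits: tuple[float, float] = DEFAULT_LIMITS
    converged: bool = True
    trace: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        # canonicalize the α ≡ α + π degeneracy and the sign of Δf_d
        if self.astig_dev < 0:
            self.astig_dev = -self.astig_dev
            self.astig_angle += math.pi / 2.0
        self.astig_angle = self.astig_angle % math.pi

    def geometry(self, n_images: int) -> SeriesGeometry:
        return SeriesGeometry(n_images, self.focal_step, self.mid_defocus,
                              self.astig_dev, self.astig_angle)

    @classmethod
    def from_geometry(cls, geom: SeriesGeometry, cs: float,
                      objective: float = 1.0) -> "CtfFitResult":
        """Wrap known-truth geometry (e.g. from a simulation) as a fit result."""
        return cls(geom.mid_defocus, geom.focal_step, cs,
                   geom.astig_dev, geom.astig_angle, objective)


def _annulus(grid, limits: tuple[float, float]) -> np.ndarray:
    low, high = limits
    if not low > high > 0:
        raise ValueError(f"limits must satisfy low > high > 0 Å, got {limits}")
    s = grid.s
    mask = (s >= 1.0 / low) & (s <= 1.0 / high)
    if not np.any(mask):
        raise ValueError(f"resolution annulus {limits} Å is empty on this grid")
    return mask


def _model_stack(mp: MicroscopeParams, geom: SeriesGeometry,
                 s: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """−cos 2γ_e for each image of the series, on the given coordinates."""
    out = np.empty((geom.n_images,) + s.shape)
    for j, ddf in enumerate(geom.offsets):
        out[j] = -np.cos(2.0 * aberration_phase(mp, geom, s, phi, extra_defocus=ddf))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum()) / denom


def objective_cc(
    mps: ModifiedSpectraStack,
    mp: MicroscopeParams,
    geom: SeriesGeometry,
    limits: tuple[float, float] = DEFAULT_LIMITS,
) -> float:
    """Correlation between I_mps and −cos 2γ_e over the annulus, all images."""
    mask = _annulus(mps.grid, limits)
    s = mps.grid.s[mask]
    phi = mps.grid.phi[mask]
    model = _model_stack(mp, geom, s, phi)
    data = mps.mps[:, mask]
    return _pearson(data.ravel(), model.ravel())


def _section_data(mps: ModifiedSpectraStack, plane: str):
    """Transverse section (n_images, n) with its s and φ coordinates."""
    n = mps.mps.shape[1]
    c = n // 2
    axis = mps.grid.axis()
    if plane == "xz":
        data = mps.mps[:, c, :]
        phi = np.where(axis >= 0, 0.0, math.pi)
    elif plane == "yz":
        data = mps.mps[:, :, c]
        phi = np.where(axis >= 0, math.pi / 2.0, -math.pi / 2.0)
    else:
        raise ValueError(f"plane must be 'xz' or 'yz', got {plane!r}")
    return data, np.abs(axis), phi


def fit_section(
    mps: ModifiedSpectraStack,
    plane: str,
    mp: MicroscopeParams,
    init: SeriesGeometry,
    search: tuple[float, float] = (5000.0, 50.0),
    limits: tuple[float, float] = DEFAULT_LIMITS,
) -> SectionFit:
    """Determine defocus, focal step and C_s from one transverse section.

    Stage 1 is a linear search over the mid defocus within ``search`` =
    (half-range, step) Å around the nominal value; stage 2 refines
    (Δf₀, δf, C_s) with a downhill simplex on the section-restricted
    correlation objective.
    """
    half_range, step = search
    if half_range <= 0 or step <= 0 or step > 2 * half_range:
        raise ValueError(f"degenerate defocus search range {search}")
    s_hi = 1.0 / limits[1]
    half_period = 1.0 / (2.0 * mp.wavelength * s_hi * s_hi)
    if step > half_period:
        warnings.warn(
            f"linear-search step {step} Å is coarser than half a Thon period "
            f"({half_period:.0f} Å) at the resolution limit; the search may "
            "skip the global optimum",
            stacklevel=2,
        )
    data, s, phi = _section_data(mps, plane)
    low, high = limits
    sel = (s >= 1.0 / low) & (s <= 1.0 / high)
    if not np.any(sel):
        raise ValueError(f"resolution annulus {limits} Å is empty on this section")
    data = data[:, sel]
    s, phi = s[sel], phi[sel]
    n_images = mps.n_images

    def cc(df0: float, dstep: float, cs: float) -> float:
        geom = SeriesGeometry(n_images, dstep, df0)
        model = _model_stack(replace(mp, cs=cs), geom, s, phi)
        return _pearson(data.ravel(), model.ravel())

    # stage 1: linear defocus search at nominal step and cs
    cands = init.mid_defocus + np.arange(-half_range, half_range + step / 2, step)
    scores = [cc(d, init.focal_step, mp.cs) for d in cands]
    df0 = float(cands[int(np.argmax(scores))])

    # stage 2: simplex over (Δf0, δf, Cs)
    x0 = np.array([df0, init.focal_step, mp.cs])
    steps = np.array([_SIMPLEX_STEPS["mid_defocus"], _SIMPLEX_STEPS["focal_step"],
                      _SIMPLEX_STEPS["cs"]])
    simplex = np.vstack([x0, x0 + np.diag(steps)])
    res = minimize(
        lambda x: -cc(x[0], abs(x[1]), abs(x[2])),
        x0,
        method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": 1e-2, "fatol": 1e-8,
                 "maxiter": 2000},
    )
    return SectionFit(
        mid_defocus=float(res.x[0]),
        focal_step=float(abs(res.x[1])),
        cs=float(abs(res.x[2])),
        objective=float(-res.fun),
        plane=plane,
    )


def fit_stack(
    mps: ModifiedSpectraStack,
    mp: MicroscopeParams,
    init: SeriesGeometry,
    limits: tuple[float, float] = DEFAULT_LIMITS,
    init_cs: float | None = None,
    max_iter: int = 4000,
) -> CtfFitResult:
    """Five-parameter simplex fit (Δf₀, δf, C_s, Δf_d, α) to the whole stack."""
    mask = _annulus(mps.grid, limits)
    s = mps.grid.s[mask]
    phi = mps.grid.phi[mask]
    data = mps.mps[:, mask].ravel()
    n_images = mps.n_images
    cs0 = mp.cs if init_cs is None else init_cs

    def cc(x: np.ndarray) -> float:
        geom = SeriesGeometry(n_images, abs(x[1]), x[0], abs(x[3]), x[4])
        model = _model_stack(replace(mp, cs=abs(x[2])), geom, s, phi)
        return _pearson(data, model.ravel())

    x0 = np.array([init.mid_defocus, init.focal_step, cs0,
                   max(init.astig_dev, 1e-6), init.astig_angle])
    steps = np.array([_SIMPLEX_STEPS[k] for k in
                      ("mid_defocus", "focal_step", "cs", "astig_dev", "astig_angle")])
    simplex = np.vstack([x0, x0 + np.diag(steps)])
    res = minimize(
        lambda x: -cc(x),
        x0,
        method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": 1e-3, "fatol": 1e-6,
                 "maxiter": max_iter},
    )
    trace = [
        {"stage": "init", "params": x0.tolist()},
        {"stage": "stack_simplex", "params": res.x.tolist(),
         "objective": float(-res.fun), "iterations": int(res.nit)},
    ]
    return CtfFitResult(
        mid_defocus=float(res.x[0]),
        focal_step=float(abs(res.x[1])),
        cs=float(abs(res.x[2])),
        astig_dev=float(abs(res.x[3])),
        astig_angle=float(res.x[4]),
        objective=float(-res.fun),
        resolution_limits=limits,
        converged=bool(res.success),
        trace=trace,
    )


def fit_focal_series(
    mps: ModifiedSpectraStack,
    mp: MicroscopeParams,
    nominal: SeriesGeometry,
    search: tuple[float, float] = (5000.0, 50.0),
    limits: tuple[float, float] = DEFAULT_LIMITS,
) -> CtfFitResult:
    """Full stepwise fit: both transverse sections, then the 5-parameter stack fit."""
    sections = [fit_section(mps, p, mp, nominal, search, limits) for p in ("xz", "yz")]
    df0 = float(np.mean([f.mid_defocus for f in sections]))
    init_cs = float(np.mean([f.cs for f in sections]))
    mp_init = replace(mp, cs=init_cs)
    n_images = mps.n_images
    low, high = limits

    # combined-section objective: 1D data is insensitive to astigmatism
    sec_data = []
    for plane in ("xz", "yz"):
        data, s, phi = _section_data(mps, plane)
        sel = (s >= 1.0 / low) & (s <= 1.0 / high)
        sec_data.append((data[:, sel], s[sel], phi[sel]))

    def section_cc(step: float) -> float:
        vals, models = [], []
        for data, s, phi in sec_data:
            geom = SeriesGeometry(n_images, step, df0)
            vals.append(data.ravel())
            models.append(_model_stack(mp_init, geom, s, phi).ravel())
        return _pearson(np.concatenate(vals), np.concatenate(models))

    # the focal step is weakly determined by one section; refine it with a
    # linear search over both sections jointly
    step_sec = float(np.mean([f.focal_step for f in sections]))
    candidates = np.unique(np.concatenate([
        np.linspace(0.75, 1.25, 26) * step_sec,
        np.linspace(0.75, 1.25, 26) * nominal.focal_step,
    ]))
    scores = [section_cc(float(st)) for st in candidates]
    best_step = float(candidates[int(np.argmax(scores))])

    # initial astigmatism: the orthogonal sections see defocus shifts of
    # ±Δf_d cos 2α; a coarse grid on the full stack resolves the angle
    dev_hint = abs(sections[0].mid_defocus - sections[1].mid_defocus) / 2.0
    devs = sorted({0.0, dev_hint, 2.0 * dev_hint, 100.0, 300.0})
    angles = np.arange(8) * np.pi / 8.0
    best = (0.0, 0.0, -np.inf)
    for dev in devs:
        for ang in angles if dev > 0 else [0.0]:
            geom = SeriesGeometry(n_images, best_step, df0, dev, float(ang))
            cc = objective_cc(mps, mp_init, geom, limits)
            if cc > best[2]:
                best = (dev, float(ang), cc)

    init = SeriesGeometry(nominal.n_images, best_step, df0, best[0], best[1])
    result = fit_stack(mps, mp, init, limits, init_cs=init_cs)
    result.trace = (
        [{"stage": f"section_{f.plane}",
          "params": [f.mid_defocus, f.focal_step, f.cs],
          "objective": f.objective} for f in sections]
        + [{"stage": "step_search", "params": [df0, best_step, init_cs],
            "objective": float(np.max(scores))},
           {"stage": "astig_search", "params": [best[0], best[1]],
            "objective": best[2]}]
        + result.trace
    )
    return result


def render_fit_overlay(mps: ModifiedSpectraStack, mp: MicroscopeParams,
                       fit: CtfFitResult) -> np.ndarray:
    """Per image: left half observed I_mps, right half the fitted −cos 2γ_e."""
    n = mps.mps.shape[1]
    geom = fit.geometry(mps.n_images)
    model = _model_stack(replace(mp, cs=fit.cs), geom, mps.grid.s, mps.grid.phi)
    overlay = mps.mps.copy()
    overlay[:, :, n // 2 :] = model[:, :, n // 2 :]
    return overlay
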