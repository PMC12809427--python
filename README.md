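# focalseries

Simulation and analysis of **focal series of electron micrographs** under the
linear two-Ewald-sphere image-formation model: CTF estimation from the whole
series at once, Ewald-sphere-aware (half-CTF) exit-wave reconstruction,
single-side-band comparison, iterative refinement, and quantitative
assessment by spectral SNR and Fourier ring correlation.

## The problem

In bright-field electron microscopy every micrograph superimposes the
specimen information on two conjugate Ewald spheres — one from the spherical
scattering geometry, one from focusing — tied to the two halves of the
contrast transfer function.  In the 3D Fourier transform of a focal series
(images stacked along focus) the spheres appear as two ridges at
w = ∓(λ/2)s², each a sinc of width 1/Δf_r set by the focal range
Δf_r.  Beyond the real-space resolution d = (λ·Δf_r)^1/2 the spheres
separate, and correcting each micrograph with **one unit-modulus half of the
CTF**, i·exp(+iγ), flattens one sphere while doubling the curvature of the
other.  Averaging the corrected transforms over the series — the parabolic
reconstruction — recovers a complex image of one Ewald sphere with the SNR
enhanced by n^1/2, without ever dividing by the CTF (no noise amplification
at its zeros).  The aberration phase uses the convention

    γ(s, φ) = χ + πλ Δf_eff s² − (π/2) C_s λ³ s⁴,

with positive defocus = underfocus, χ the amplitude-contrast phase, and
astigmatism folded into Δf_eff.  The package is aimed at method developers
and microscopists who want a compact, fully testable reference
implementation of this processing chain on synthetic or recorded focal
series (MRC stacks with a JSON defocus sidecar).

## Worked example

```python
import numpy as np
import focalseries as fs

lam = fs.electron_wavelength(200.0)
print(f"electron wavelength at 200 kV: {lam:.5f} A")
print(f"Ewald offset of the 2.13 A reflection: {fs.ewald_offset(lam, 1/2.13):.5f} 1/A")
print(f"sphere separation for a 608 A focal range: {fs.separation_resolution(lam, 608.0):.2f} A")

# render a 20-image series of an amorphous film, 32 A focal steps,
# 8000 A underfocus, with noise — then fit the CTF starting from a
# wrong nominal step of 37 A
mp = fs.MicroscopeParams(200.0, cs=1.4e7, amp_phase=0.07)
geom = fs.SeriesGeometry(20, 32.0, 8000.0)
spec = fs.make_amorphous(0.08, 128.0, 20.0, seed=1)
series = fs.render_focal_series(spec, mp, geom, n=128, pixel=1.0,
                                noise_sd=0.3, seed=2)

mps = fs.modified_power_spectra(fs.tile_power_spectra(series), sigma=10.0)
nominal = fs.SeriesGeometry(20, 37.0, 7500.0)
fit = fs.fit_focal_series(mps, mp, nominal, search=(1500.0, 50.0))
print(f"fitted defocus:    {fit.mid_defocus:7.1f} A   (true 8000)")
print(f"fitted focal step: {fit.focal_step:7.2f} A   (true 32, nominal 37)")
print(f"fit correlation:   {fit.objective:7.3f}")

rec = fs.parabolic_reconstruct(series, fit)       # complex exit-wave image
noiseless = fs.render_focal_series(spec, mp, geom, n=128, pixel=1.0)
gain = fs.snr_gain(noiseless, fit, noise_sd=0.3, repeats=16, seed=3)
print(f"SNR gain of the 20-image reconstruction: {gain:.2f}  (n^1/2 = {np.sqrt(20):.2f})")
```

prints

```
electron wavelength at 200 kV: 0.02508 A
Ewald offset of the 2.13 A reflection: 0.00276 1/A
sphere separation for a 608 A focal range: 3.90 A
fitted defocus:     7992.4 A   (true 8000)
fitted focal step:   31.95 A   (true 32, nominal 37)
fit correlation:     0.240
SNR gain of the 20-image reconstruction: 4.25  (n^1/2 = 4.47)
```

The fit recovers the true defocus to 0.1% and discovers that the focal step
is 32 Å, not the nominal 37 Å.  The correlation objective is modest on noisy
data by construction (its absolute value has no meaning; the extrema carry
the signal).  The SNR gain of the reconstruction approaches √20 = 4.47, the
coherent-averaging limit for 20 images.  Phase statistics of the complex
reconstruction (`fs.phase_stats(rec)`) peak at π/2 + χ, e.g. ≈1.95 rad for
the heavy-metal amplitude contrast χ = 0.38.

The same workflow is available from the shell:

```sh
focalseries simulate --fixture amorphous --size 256 --seed 7 --out series.mrc
focalseries fit series.mrc --out fit.json --overlay overlay.mrc
focalseries reconstruct series.mrc --fit-json fit.json --out-prefix rec
focalseries refine series.mrc --fit-json fit.json --out-prefix refined
focalseries ssnr series.mrc --fit-json fit.json --out gain.json
```

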