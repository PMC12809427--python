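# Methods

## The image-formation model

`focalseries` implements the linear (single-elastic-scattering) model of
bright-field electron-microscope image formation in which every micrograph
carries the specimen information on **two conjugate Ewald spheres**, one from
the spherical scattering geometry and one from focusing.  In frequency space
the contrast of image *j* of a focal series is

    I_j(u, v) = F(u, v) e^{−iγ_j(u,v)} + F*(−u, −v) e^{+iγ_j(u,v)},

where the object spectrum of a set of point scatterers {x_a, y_a, z_a, f_a}
is

    F(u, v) = i Σ_a f_a exp[−2πi(u x_a + v y_a)] · exp[−iπλ z_a s²],

with s² = u² + v².  The leading factor *i* is the weak-phase convention: the
scattered amplitude is in quadrature with the unscattered beam, so a point
scatterer is transferred with the familiar contrast transfer function
2 sin γ.  The per-atom Fresnel factor exp(−iπλ z s²) is the free-space
propagator for the height z of the atom; it is what bends the information
onto the spheres w = ∓(λ/2)s².

The aberration phase uses one fixed sign convention throughout:

    γ(s, φ) = χ + πλ Δf_eff s² − (π/2) C_s λ³ s⁴,
    Δf_eff  = Δf + ΔΔf_j (+ z_a) + Δf_d cos 2(φ − α),

with positive defocus meaning underfocus, χ the constant amplitude-contrast
phase, Δf_d/α astigmatism and C_s the spherical aberration.  An atom's z and
an image's focal offset ΔΔf_j enter γ identically and are handled by one code
path.  Physical constants are CODATA 2018 values frozen in
`focalseries.constants`, so derived wavelengths are bit-reproducible
(λ = 0.02508 Å at 200 kV).

In the 3D Fourier transform of a focal series (stack transformed along the
focus direction, sample spacing δf) the two terms produce two spherical
ridges at w = ∓(λ/2)s², each convolved along w with the Dirichlet (periodic
sinc) kernel of the focal window: first node at 1/Δf_r, i.e. about one
w-voxel, with Δf_r = (n−1)δf the focal range.  The spheres are resolved from
each other below the real-space resolution d = (λ Δf_r)^1/2.

## Synthetic specimens

Three generators emulate the study's specimen types:

* `make_hex_lattice` — a planar triangular lattice whose six first-order
  reflections sit at 1/spacing (2.13 Å by default), a graphene-oxide-like
  single atomic layer;
* `make_nanocrystal_field` — randomly placed, randomly rotated small square
  lattice patches at random heights in a slab, giving rings of spots at
  1/spacing (2.25 Å and 1.39 Å defaults), a PtIr-like strong scatterer;
* `make_amorphous` — uniformly random atoms in a slab, the carbon-film-like
  background whose power spectra carry Thon rings following sin²γ.

Atoms are ideal points (flat scattering factor); an optional Gaussian form
factor is available.  Rendering is exact per atom: the separable phase
factors along u and v reduce the sum over atoms to one complex matrix product
per atom chunk, and the Friedel-paired construction makes each image real to
machine precision.  A constant positive baseline is added (the model fixes
only proportionality) and optional i.i.d. Gaussian noise is drawn per image
from a seeded generator recorded in the provenance.  A per-pixel Poisson
model is not included; at the dose regime emulated here the Gaussian
approximation is standard.

What the generator does **not** emulate: multiple/dynamical and inelastic
scattering, partial coherence envelopes, detector MTF, beam-induced motion
and radiation damage.  Passing tests therefore validate the linear model and
the processing chain, not detector- or dose-specific behavior of real data.

## Processing chain

**Power spectra.**  Abutting tiles are transformed with orthonormal FFTs
(Parseval holds exactly) and averaged; 3D power spectra use tile stacks
covering the whole series.  Azimuthal ridge profiles use one-voxel-wide
nearest shells.

**Modified power spectra.**  Each 2D power spectrum P is rescaled to a
CTF-shaped image in [−1, 1]: image1 = Gaussian-smooth(P) (σ = 10 px default,
reflective boundary) estimates noise plus half the signal power;
image2 = P − image1 oscillates about zero; image3 = π·smooth(|image2|)
estimates the signal power (mean |cos| = 2/π); I_mps = clamp(image2 /
(image3/2), −1, 1).  Dividing by image3/2 rather than image3 makes the
maxima/minima tend to ±1 on the ideal model P = N + S sin²γ, where image2 has
amplitude S/2 and image3 ≈ S.  The division is guarded below 1e−12.

**CTF fitting.**  The model for I_mps is −cos 2γ_e with γ_e the even terms
(χ, defocus, astigmatism, C_s); χ is fixed per specimen (0.07 default, 0.38
for heavy-metal fixtures).  The objective is the unweighted Pearson
correlation over a resolution annulus (2.5–40 Å default) across all images
at once.  Because the CTF oscillates rapidly, fitting is stepwise: (1) a
linear defocus search on a transverse (xz/yz) section (default ±5000 Å in
50 Å steps; a warning is emitted if the step exceeds half a Thon period at
the resolution limit); (2) a three-parameter Nelder–Mead refinement
(Δf₀, δf, C_s) per section; (3) a linear focal-step search on both sections
jointly, since one section determines δf weakly; (4) a coarse astigmatism
(Δf_d, α) grid on the full stack — the 2D annulus objective decorrelates
under unmodeled astigmatism, so the simplex needs a starting point inside
the basin; the grid is seeded with the defocus difference between the two
sections, which equals 2Δf_d cos 2α; (5) a five-parameter Nelder–Mead on the
full stack (standard coefficients; initial steps 100 Å, 1 Å, 1e5 Å, 50 Å,
0.1 rad; convergence on objective change < 1e−6, cap 4000 iterations;
non-convergence sets a flag rather than raising).  α is canonicalized to
[0, π).  Fitted values are working parameters for correction — defocus, C_s
and χ trade off and the individual numbers should not be over-interpreted.

**Reconstruction.**  The parabolic (half-CTF) reconstruction multiplies each
image transform by the unit-modulus factor **i·e^{+iγ_j}** and averages over
the series; the back transform is a complex image without Friedel symmetry.
The constant quadrature factor i is part of the correction convention: with
it, the corrected structure lands on the real axis and the unscattered mean
at phase π/2 + χ, which is where the real-space phase histogram of a
reconstruction peaks (≈1.95 rad for χ = 0.38).  The conjugate factor
−i·e^{−iγ_j} flattens the other sphere; the full (projection-approximation)
correction is the real factor 2 sin γ_j, which produces the central plane
plus both doubled-curvature spheres in 3D.  No division by the CTF is ever
performed — at CTF zeros both spheres cancel and the reconstruction honestly
carries no signal there rather than amplified noise.  Tiles may be padded to
twice their size with the tile mean before reconstruction so that signal
delocalized up to λ·Δf·s beyond the tile edge can be recovered.

**Single side band.**  The CTFP/CTFQ scheme corrects the two halves of
frequency space (split at a line through the origin, 90° default) with
conjugate factors e^{∓iγ}, evaluated over eight azimuthal sectors, and
imposes Friedel symmetry so the outputs are real; P and Q use opposite sign
assignments.  The sign map reproduces the qualitative eight-sector pattern
with a single discontinuity, not the bit-exact behavior of the original
external implementation.

**Mask-and-shift flattening.**  Lattice reflections are isolated in the 3D
transform with box masks (20×20×3 voxels by default, extents rounded up to
odd so the two sphere choices are exact Friedel images of each other) at
their predicted w planes, the masked transform is shifted along w to the
central section and back transformed.  The shift is applied exactly (a phase
ramp in the focus domain) by default because the ridge generally sits at a
fractional w-voxel — at the default geometry 1.77 voxels, where a whole-voxel
roll leaves a residual focal ramp; the integer-voxel roll used in the
original experiment is available as `w_shift="integer"`.

**IWFR.**  Iterative wavefunction reconstruction alternates parabolic
reconstruction with real-space amplitude replacement.  The default
replacement target is the original image values (`direct`); the square root
of the intensities (`sqrt`), as in the classic formulation, is provided as an
option — the two differ only in the fixed point's amplitude scale, and the
choice is documented rather than silently resolved.  Convergence is tested on
the *change* in RMS amplitude difference (tolerance 1e−6 of the mean target
amplitude; cap 1000 iterations).  Refinement reintroduces second-sphere
information below the separation frequency (1/λΔf_r)^1/2 — visible as a
low-frequency divergence from the unrefined reconstruction that grows with
iterations — and most of the RMS drop happens within the first few
iterations.

**SSNR and gain.**  SSNR is estimated per Fourier shell from n repeated
realizations as max(0, (n|F̄|² − σ̂²)/σ̂²) with σ̂² the unbiased per-component
residual variance — the SSNR of the summed/averaged set.  `snr_gain` renders
repeated noisy copies of a noiseless series (the noise sd defaults to the
contrast RMS), reconstructs each, and averages sqrt(SSNR ratio) over shells
with appreciable single-image SSNR (>0.1) below the coherent-averaging
frequency s = (1/(2πλΔf_r))^1/2.  Inside that band the focal-window kernel
keeps both Ewald-sphere terms coherent across the series and the expected
gain is n^1/2 (4.47 for 20 images); beyond it the conjugate term decoheres
and the per-shell gain falls toward (n/2)^1/2, which is why the band is part
of the measurement definition.

## Numerical conventions

* Arrays are indexed `[image, row=y, col=x]`; frequency grids are
  origin-at-corner (numpy FFT layout) internally and centered only for
  display/export.  Layout conversions are lossless shifts.
* Spectra use orthonormal FFTs; rendering/reconstruction use the default
  (unnormalized) transform pair, which is self-consistent.
* On even grids the aliased Nyquist row/column is self-conjugate; for atoms
  at off-lattice positions its value is convention-dependent and the renderer
  resolves it in favor of exactly real images.
* Shell curves use one-voxel integer-radius bins; histogram modes and ridge
  peaks are refined by quadratic interpolation.
* Degenerate inputs: empty annuli, out-of-range sections, non-positive
  tolerances and Nyquist-violating specimens raise `ValueError` with the
  offending quantity named; a non-converged fit returns a flagged result.

## Problem sizes

The default synthetic fixture mirrors the acquisition this model was built
around: 20 images, δf = 32 Å (focal range 608 Å), 512² pixels at 0.32 Å.
The test suite and the acceptance script run the same physics at desk scale —
128–256 px grids at 0.5–1 Å sampling, 10–20 images — where every anchored
quantity (Ewald offsets, ridge geometry, recovery tolerances, n^1/2 gain,
phase modes) is scale-independent or depends only on the preserved
geometry (λ, δf, n_images, defocus).

## Known limitations

* The linear model omits multiple and inelastic scattering; amplitudes are in
  arbitrary units (the relativistic interaction prefactor is absorbed into
  the atom amplitudes) and absolute contrast is not reproduced.
* Higher-order aberrations are not fitted; the aberration phase accepts only
  the even terms above.
* The focal series is constrained to an arithmetic focus ramp; per-image
  independent defocus is out of scope.
* The beam-tilt relation t = (Δf_d/C_s)^1/2 is the dimensionally consistent
  reading of the tilt-induced-astigmatism relation Δf_d = C_s t²; tilt is
  estimated, not corrected.
* Which exponent sign corresponds to the physical "upper" sphere is a fixed
  convention (exp(+iγ) flattens the sphere at w = −(λ/2)s²); the physical
  hand ambiguity is surfaced via the `conjugate` flag, not resolved.
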