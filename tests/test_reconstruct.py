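"""Half-CTF corrections, parabolic/single-side-band reconstructions,
mask-and-shift flattening and tile extraction."""

import numpy as np
import pytest

import focalseries as fs
from focalseries.fourier import friedel_mate
from focalseries.spectra import power3d_of_stack
from focalseries.synthesize import object_spectrum


class TestCorrectStack:
    def test_phase_only_correction_conserves_power(self, amorphous_series, truth_fit):
        corrected = fs.correct_stack(amorphous_series, truth_fit, "upper")
        orig = np.fft.fft2(amorphous_series.stack, axes=(1, 2))
        corr = np.fft.fft2(corrected, axes=(1, 2))
        assert np.allclose(np.abs(corr), np.abs(orig), rtol=1e-9, atol=1e-9)

    def test_upper_then_lower_restores_original(self, amorphous_series, truth_fit):
        """The lower factor is the exact conjugate of the upper factor."""
        up = fs.correct_stack(amorphous_series, truth_fit, "upper")
        mid = fs.FocalSeries(up.real, amorphous_series.pixel,
                             amorphous_series.geometry, amorphous_series.microscope)
        # apply the operators directly: (i e^{iγ})(−i e^{−iγ}) = 1
        from focalseries.optics import aberration_phase
        from focalseries.reconstruct import _correction, _resolve
        mp, geom = _resolve(amorphous_series, truth_fit)
        grid = amorphous_series.grid
        restored = np.empty_like(up)
        for j, ddf in enumerate(geom.offsets):
            g = aberration_phase(mp, geom, grid.s, grid.phi, extra_defocus=ddf)
            restored[j] = np.fft.ifft2(
                np.fft.fft2(up[j]) * _correction("lower", g))
        assert np.allclose(restored.real, amorphous_series.stack, atol=1e-9)
        assert np.abs(restored.imag).max() < 1e-9

    def test_upper_flattens_one_sphere_and_doubles_other(self, amorphous_series,
                                                         truth_fit):
        lam = amorphous_series.microscope.wavelength
        s0 = 0.35
        corrected = fs.correct_stack(amorphous_series, truth_fit, "upper")
        vol = power3d_of_stack(corrected, amorphous_series.pixel, 32.0)
        prof = fs.ridge_profile(vol, s0)
        c = len(prof.w) // 2
        assert np.argmax(prof.intensity) == c  # flattened onto w = 0
        rest = prof.intensity.copy()
        rest[c - 1 : c + 2] = 0
        w2 = prof.w[np.argmax(rest)]
        assert w2 == pytest.approx(2 * fs.ewald_offset(lam, s0), abs=vol.w_step)

    def test_full_correction_gives_plane_plus_doubled_spheres(self,
                                                              amorphous_series,
                                                              truth_fit):
        lam = amorphous_series.microscope.wavelength
        s0 = 0.35
        corrected = fs.correct_stack(amorphous_series, truth_fit, "full")
        vol = power3d_of_stack(corrected, amorphous_series.pixel, 32.0)
        prof = fs.ridge_profile(vol, s0)
        c = len(prof.w) // 2
        w2 = int(round(2 * fs.ewald_offset(lam, s0) / vol.w_step))
        single = int(round(fs.ewald_offset(lam, s0) / vol.w_step))
        assert prof.intensity[c] > 5 * prof.intensity[c + single]
        assert prof.intensity[c + w2] > 5 * prof.intensity[c + single]
        assert prof.intensity[c - w2] > 5 * prof.intensity[c + single]

    def test_upper_correction_concentrates_lattice_power_at_w0(self, hex_series):
        """Flattening in the per-reflection z spectrum: after upper correction
        the w = 0 term dominates; before it the power sits at ±(λ/2)s²."""
        spec, series = hex_series
        geom = series.geometry
        fit = fs.CtfFitResult.from_geometry(geom, series.microscope.cs)
        u, v = spec.metadata["reflections"][0]
        fstep = series.grid.freq_step
        n = series.n
        iu, iv = round(u / fstep) % n, round(v / fstep) % n

        def w_power(stack):
            vals = np.fft.fft2(stack, axes=(1, 2))[:, iv, iu]
            return np.abs(np.fft.fft(vals)) ** 2

        raw = w_power(series.stack.astype(complex))
        corr = w_power(fs.correct_stack(series, fit, "upper"))
        m = round(fs.ewald_offset(series.microscope.wavelength, 1 / 2.13)
                  / series.grid.w_step)
        assert raw[0] < 0.05 * raw.sum()  # no projection term before correction
        assert raw[m] + raw[-m] > 0.7 * raw.sum()  # power on the two spheres
        assert corr[0] > 0.4 * corr.sum()  # flattened term dominates after

    def test_full_mode_output_is_real(self, amorphous_series, truth_fit):
        corrected = fs.correct_stack(amorphous_series, truth_fit, "full")
        assert np.abs(corrected.imag).max() < 1e-9 * np.abs(corrected.real).max()


class TestParabolic:
    def test_weak_phase_truth_recovered_below_separation(self, mp200):
        """For a single-plane specimen the reconstruction phases carry the
        projected structure: FRC with the band-limited point map is high up
        to the sphere-separation frequency.  Shells at the CTF zeros are
        excluded — both spheres cancel there and no amplitude boosting is
        applied to compensate."""
        geom = fs.SeriesGeometry(20, 32.0, 1000.0)
        spec = fs.make_amorphous(0.08, 128.0, 1.0, seed=5)
        spec.z[:] = 0.0
        series = fs.render_focal_series(spec, mp200, geom, n=128, pixel=1.0)
        rec = fs.parabolic_reconstruct(series,
                                       fs.CtfFitResult.from_geometry(geom, mp200.cs))
        truth = np.fft.ifft2(object_spectrum(spec, mp200.wavelength, series.n,
                                             series.pixel) / 1j).real
        curve = fs.frc(rec.phase(), truth, series.pixel)
        s_sep = 1.0 / fs.separation_resolution(mp200.wavelength,
                                               series.geometry.focal_range)
        gamma = fs.aberration_phase(mp200, geom, curve.shells)
        sel = ((curve.shells > 0) & (curve.shells < s_sep)
               & (np.abs(np.sin(gamma)) > 0.3))
        vals = curve.values[sel]
        assert np.median(vals) > 0.95
        assert (vals > 0.95).mean() > 0.9

    def test_phase_mode_pi_half_plus_chi(self, mp200):
        """With χ = 0.38 the real-space phase histogram peaks at π/2 + 0.38."""
        mp = fs.MicroscopeParams(200.0, cs=1.4e7, amp_phase=0.38)
        geom = fs.SeriesGeometry(20, 32.0, 1660.0)
        spec = fs.make_nanocrystal_field(20, [2.25, 1.39], 96.0, 60.0, seed=3)
        series = fs.render_focal_series(spec, mp, geom, n=160, pixel=0.6)
        rec = fs.parabolic_reconstruct(series,
                                       fs.CtfFitResult.from_geometry(geom, mp.cs))
        stats = fs.phase_stats(rec)
        assert stats.peak == pytest.approx(np.pi / 2 + 0.38, abs=0.05)

    def test_conjugate_is_involutive(self, amorphous_series, truth_fit):
        """Correcting with the conjugate of the conjugate equals the original
        correction."""
        r1 = fs.parabolic_reconstruct(amorphous_series, truth_fit)
        up = fs.correct_stack(amorphous_series, truth_fit, "upper")
        down_up = np.empty_like(up)
        from focalseries.optics import aberration_phase
        from focalseries.reconstruct import _correction, _resolve
        mp, geom = _resolve(amorphous_series, truth_fit)
        grid = amorphous_series.grid
        for j, ddf in enumerate(geom.offsets):
            g = aberration_phase(mp, geom, grid.s, grid.phi, extra_defocus=ddf)
            op = _correction("upper", g) * _correction("lower", g)
            down_up[j] = np.fft.ifft2(np.fft.fft2(amorphous_series.stack[j]) * op)
        assert np.allclose(down_up.real, amorphous_series.stack, atol=1e-9)
        assert r1.half == "upper"
        r2 = fs.parabolic_reconstruct(amorphous_series, truth_fit, conjugate=True)
        assert r2.half == "lower"

    def test_identical_images_zero_aberrations_idempotent(self):
        """Averaging n identical images with γ = 0 equals one image (times the
        quadrature constant)."""
        mp = fs.MicroscopeParams(200.0, cs=0.0, amp_phase=0.0)
        geom = fs.SeriesGeometry(4, 0.0, 0.0)
        rng = np.random.default_rng(3)
        img = rng.uniform(1.0, 2.0, (32, 32))
        series = fs.FocalSeries(np.repeat(img[None], 4, axis=0), 1.0, geom, mp)
        rec = fs.parabolic_reconstruct(series,
                                       fs.CtfFitResult.from_geometry(geom, 0.0))
        assert np.allclose(rec.real_values(), 1j * img, atol=1e-12)

    def test_half_mode_breaks_friedel_symmetry_full_keeps_it(self,
                                                             amorphous_series,
                                                             truth_fit):
        rec = fs.parabolic_reconstruct(amorphous_series, truth_fit)
        F = rec.freq_values()
        asym = np.abs(F - friedel_mate(F)).mean() / np.abs(F).mean()
        assert asym > 0.05  # atoms spread in z: no Friedel symmetry
        full = fs.correct_stack(amorphous_series, truth_fit, "full").mean(axis=0)
        Ff = np.fft.fft2(full.real)
        asym_full = np.abs(Ff - friedel_mate(Ff)).mean() / np.abs(Ff).mean()
        assert asym_full < 1e-9

    def test_padded_reconstruction_doubles_grid(self, amorphous_series, truth_fit):
        rec = fs.parabolic_reconstruct(amorphous_series, truth_fit, pad=True)
        assert rec.values.shape == (256, 256)
        assert rec.pad_factor == 2

    def test_geometry_mismatch_raises(self, amorphous_series, mp200):
        wrong = fs.SeriesGeometry(7, 32.0, 8000.0)
        with pytest.raises(ValueError):
            fs.parabolic_reconstruct(amorphous_series, wrong)


class TestSingleSideBand:
    def test_outputs_are_real(self, amorphous_series, truth_fit):
        P, Q, signs = fs.ssb_reconstruct(amorphous_series, truth_fit)
        for rec in (P, Q):
            v = rec.real_values()
            assert np.abs(v.imag).max() < 1e-9 * np.abs(v).max()

    def test_sign_map_sectors_and_discontinuity(self, amorphous_series, truth_fit):
        _, _, signs = fs.ssb_reconstruct(amorphous_series, truth_fit,
                                         split_angle=np.pi / 2)
        assert set(np.unique(signs)) == {-1.0, 1.0}
        n = signs.shape[0]
        c = n // 2
        # split line is vertical: signs flip across it at matching radius
        assert signs[c + 10, c + 5] != signs[c + 10, c - 5]
        # antisymmetric under point inversion (opposite sectors, opposite sign)
        assert signs[c + 10, c + 5] == -signs[c - 10, c - 5]

    def test_partial_coherent_recovery(self, amorphous_series, truth_fit):
        """P correlates with the parabolic reconstruction amplitude at mid
        frequencies: the side-band images retain coherent information."""
        P, _, _ = fs.ssb_reconstruct(amorphous_series, truth_fit)
        rec = fs.parabolic_reconstruct(amorphous_series, truth_fit)
        curve = fs.frc(P.real_values().real, rec.amplitude(),
                       amorphous_series.pixel)
        sel = (curve.shells > 0.1) & (curve.shells < 0.35)
        assert curve.values[sel].mean() > 0.05


class TestMaskShiftFlatten:
    def test_flattening_reduces_z_variance(self, hex_series):
        spec, series = hex_series
        refl = spec.metadata["reflections"]
        flat = fs.mask_shift_flatten(series, refl)
        masked = fs.mask_shift_flatten(series, refl, shift=False)
        v_flat = np.var(flat.real, axis=0).mean()
        v_masked = np.var(masked.real, axis=0).mean()
        assert v_masked > 10 * v_flat

    def test_upper_and_lower_give_same_result(self, hex_series):
        spec, series = hex_series
        refl = spec.metadata["reflections"]
        up = fs.mask_shift_flatten(series, refl, sphere="upper")
        lo = fs.mask_shift_flatten(series, refl, sphere="lower")
        assert np.allclose(up.real, lo.real, atol=1e-12 * np.abs(up.real).max())
        assert np.allclose(np.abs(up), np.abs(lo), atol=1e-12 * np.abs(up).max())

    def test_no_shift_reproduces_masked_backtransform(self, hex_series):
        spec, series = hex_series
        refl = spec.metadata["reflections"]
        a = fs.mask_shift_flatten(series, refl, shift=False)
        b = fs.mask_shift_flatten(series, refl, shift=False, w_shift="integer")
        assert np.array_equal(a, b)

    def test_integer_shift_also_reduces_variance(self, hex_series):
        spec, series = hex_series
        refl = spec.metadata["reflections"]
        flat = fs.mask_shift_flatten(series, refl, w_shift="integer")
        masked = fs.mask_shift_flatten(series, refl, shift=False)
        assert np.var(masked.real, axis=0).mean() > 3 * np.var(flat.real, axis=0).mean()

    def test_reflection_outside_grid(self, hex_series):
        spec, series = hex_series
        with pytest.raises(ValueError):
            fs.mask_shift_flatten(series, [(1.0, 0.0)])


class TestExtractTile:
    def test_identity_without_padding(self, amorphous_series):
        tile = fs.extract_tile(amorphous_series.stack[0], (8, 16), 32)
        assert np.array_equal(tile, amorphous_series.stack[0][8:40, 16:48])

    def test_padding_uses_tile_mean(self, amorphous_series):
        img = amorphous_series.stack[0]
        tile = fs.extract_tile(img, (8, 16), 32, pad_to=64)
        inner = img[8:40, 16:48]
        assert tile.shape == (64, 64)
        assert tile[0, 0] == pytest.approx(inner.mean())
        assert tile.mean() == pytest.approx(inner.mean())

    def test_out_of_bounds(self, amorphous_series):
        with pytest.raises(ValueError):
            fs.extract_tile(amorphous_series.stack[0], (100, 100), 64)

    def test_series_tile_keeps_geometry(self, amorphous_series):
        sub = fs.extract_tile(amorphous_series, (0, 0), 64, pad_to=128)
        assert isinstance(sub, fs.FocalSeries)
        assert sub.geometry == amorphous_series.geometry
        assert sub.n == 128

    def test_delocalized_signal_recovered_beyond_tile_edge(self, mp200):
        """Padded-tile reconstruction recreates signal outside the original
        tile boundary (the delocalization halo)."""
        geom = fs.SeriesGeometry(20, 32.0, 1000.0)
        spec = fs.make_hex_lattice(2.13, 128.0)
        series = fs.render_focal_series(spec, mp200, geom, n=128, pixel=1.0)
        tile_series = fs.extract_tile(series, (32, 32), 64, pad_to=128)
        fit = fs.CtfFitResult.from_geometry(geom, mp200.cs)
        rec = fs.parabolic_reconstruct(tile_series, fit)
        amp = np.abs(rec.real_values() - rec.real_values().mean())
        deloc = fs.delocalization(mp200.wavelength, geom.mid_defocus, 1 / 2.13)
        assert 8.0 < deloc < 16.0  # halo extent in pixels at 1 Å sampling
        # band just outside the tile boundary (within the halo) vs a band
        # beyond the delocalization radius
        halo = amp[24:32, 40:88].std()
        far = amp[0:8, 40:88].std()
        assert halo > 5 * far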