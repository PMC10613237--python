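"""Plane transforms, Green's normalization, phase estimation and the loop."""

import numpy as np
import pytest

import mstrace as ms
from mstrace.mst import MSTConfig
from mstrace.optics import ValidationError


def make_single_plate(grid, depth=8.0, std=0.8, seed=7, spokes=6):
    med = ms.build_medium(grid, [depth], correlation_length=2.5,
                          phase_std=std, seed=seed)
    obj = ms.make_target_object("siemens_star", {"n_spokes": spokes}, grid)
    r = ms.reflection_from_medium(med, obj, reference_plane="z0")
    return med, obj, r


class TestTransformToLayer:
    def test_identity_when_planes_unchanged(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        out = ms.transform_to_layer(r, r.input_plane, r.output_plane)
        np.testing.assert_array_equal(out.values, r.values)

    def test_transform_then_inverse_restores(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        moved = ms.transform_to_layer(r, 8.0, 0.0)
        back = ms.transform_to_layer(moved, 0.0, 0.0)
        scale = np.max(np.abs(r.values))
        assert np.max(np.abs(back.values - r.values)) / scale < 1e-9

    def test_composition_of_partial_transforms(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        direct = ms.transform_to_layer(r, 8.0, 0.0)
        step = ms.transform_to_layer(ms.transform_to_layer(r, 3.0, 0.0),
                                     8.0, 0.0)
        scale = np.max(np.abs(direct.values))
        assert np.max(np.abs(direct.values - step.values)) / scale < 1e-9

    def test_single_plate_structural_form(self, grid16):
        """Output-corrected single-plate matrix factors as O * P * Phi."""
        depth = 6.0
        med = ms.build_medium(grid16, [depth], 2.0, 0.9, seed=3)
        obj = ms.make_target_object("siemens_star", {"n_spokes": 4}, grid16)
        r = ms.reflection_from_medium(med, obj, reference_plane="zN")
        # correcting the output path with the ground truth removes every
        # scattering event except the illumination-side pass of the plate;
        # (T^T)^-1 = conj(T) because T is unitary with symmetric factors
        t = ms.medium_transmission(med).values
        corrected = np.conj(t) @ r.values
        p = ms.propagation_matrix(grid16, 0.0, depth).as_matrix()
        phi = np.diag(med.plates[0].transmittance().ravel())
        o = np.diag(obj.amplitude_reflectance.ravel())
        expected = o @ p @ phi
        assert np.max(np.abs(corrected - expected)) < 1e-8


class TestNormalizeByGreens:
    def test_no_plate_delta_columns_are_flat(self, grid16):
        # with a point object every unmasked column of S carries the same
        # single spike: the object function, phase-flat across columns
        obj = ms.make_target_object("point_array", {"points": [(8, 8)]},
                                    grid16)
        med = ms.MediumModel(grid=grid16, plates=[])
        r = ms.reflection_from_medium(med, obj, reference_plane="z0")
        moved = ms.transform_to_layer(r, 5.0, 0.0)
        s = ms.normalize_by_greens(moved)
        row = s.values[8 * 16 + 8]
        good = s.validity_mask[8 * 16 + 8]
        phases = np.angle(row[good])
        if np.any(~good):
            assert np.max(np.abs(row[~good])) == 0.0
        assert np.std(np.abs(row[good])) / np.mean(np.abs(row[good])) < 1e-9
        assert np.max(np.abs(np.angle(np.exp(1j * (phases - phases[0]))))) \
            < 1e-9

    def test_zero_separation_rejected(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        with pytest.raises(ValidationError):
            ms.normalize_by_greens(r)

    def test_single_plate_is_nearly_rank_one(self, grid24):
        med, obj, r = make_single_plate(grid24)
        rn = ms.transform_to_layer(r, 8.0, 8.0)
        t = ms.medium_transmission(med).values
        out_corrected = rn.copy()
        out_corrected.values = np.conj(t) @ rn.values
        out_corrected.input_plane = 8.0
        out_corrected.output_plane = 0.0
        s = ms.normalize_by_greens(out_corrected)
        sv = np.linalg.svd(s.values, compute_uv=False)
        frac = sv[0] ** 2 / np.sum(sv ** 2)
        assert frac > 0.99

    def test_multi_plate_rank_one_fraction_is_lower(self, grid24):
        med1, obj, r1 = make_single_plate(grid24)
        med4 = ms.build_medium(grid24, [8.0, 14.0], 2.5, 0.8, seed=7)
        r4 = ms.reflection_from_medium(med4, obj, reference_plane="z0")

        def rank1_frac(r, med, depth):
            rn = ms.transform_to_layer(r, med.surface_depth,
                                       med.surface_depth)
            t = ms.medium_transmission(med).values
            w = rn.copy()
            w.values = np.conj(t) @ rn.values
            w.input_plane = med.surface_depth
            w.output_plane = 0.0
            w = ms.transform_to_layer(w, depth, 0.0)
            s = ms.normalize_by_greens(w)
            sv = np.linalg.svd(s.values, compute_uv=False)
            return sv[0] ** 2 / np.sum(sv ** 2)

        assert rank1_frac(r4, med4, 8.0) < rank1_frac(r1, med1, 8.0)


class TestEstimatePhase:
    def test_exact_rank_one_recovered(self, grid16):
        rng = np.random.default_rng(1)
        n = grid16.n
        phi = rng.uniform(-2, 2, (n, n))
        o = rng.uniform(0.2, 1.0, (n, n)).ravel()
        s_vals = np.outer(o, np.exp(1j * phi.ravel()))
        s = ms.NormalizedMatrix(values=s_vals, layer_index=0,
                                validity_mask=np.ones_like(s_vals, bool),
                                grid=grid16)
        cfg = MSTConfig(layer_depths=[5.0], band_limit_estimates=False)
        inc = ms.estimate_phase(s, cfg)
        ref = phi - phi[n // 2, n // 2]
        err = np.angle(np.exp(1j * (inc - ref)))
        assert np.sqrt(np.mean(err ** 2)) < 1e-6

    def test_perturbed_rank_one_recovered(self, grid16):
        rng = np.random.default_rng(2)
        n = grid16.n
        phi = rng.uniform(-2, 2, (n, n))
        o = rng.uniform(0.2, 1.0, (n, n)).ravel()
        s_vals = np.outer(o, np.exp(1j * phi.ravel()))
        noise = (rng.standard_normal(s_vals.shape)
                 + 1j * rng.standard_normal(s_vals.shape))
        noise *= 0.1 * np.linalg.norm(s_vals) / np.linalg.norm(noise)
        s = ms.NormalizedMatrix(values=s_vals + noise, layer_index=0,
                                validity_mask=np.ones_like(s_vals, bool),
                                grid=grid16)
        cfg = MSTConfig(layer_depths=[5.0], band_limit_estimates=False,
                        power_iteration_max_steps=30)
        inc = ms.estimate_phase(s, cfg)
        ref = phi - phi[n // 2, n // 2]
        err = np.angle(np.exp(1j * (inc - ref)))
        assert np.sqrt(np.mean(err ** 2)) < 0.1

    def test_pairwise_estimator_agrees_with_power_iteration(self, grid16):
        rng = np.random.default_rng(3)
        n = grid16.n
        phi = rng.uniform(-2, 2, (n, n))
        o = rng.uniform(0.4, 1.0, (n, n)).ravel()
        s_vals = np.outer(o, np.exp(1j * phi.ravel()))
        noise = (rng.standard_normal(s_vals.shape)
                 + 1j * rng.standard_normal(s_vals.shape))
        noise *= 0.05 * np.linalg.norm(s_vals) / np.linalg.norm(noise)
        s = ms.NormalizedMatrix(values=s_vals + noise, layer_index=0,
                                validity_mask=np.ones_like(s_vals, bool),
                                grid=grid16)
        cfg = MSTConfig(layer_depths=[5.0], band_limit_estimates=False,
                        power_iteration_max_steps=30)
        inc = ms.estimate_phase(s, cfg)
        pair = ms.pairwise_phase_estimate(s)
        pair = pair - pair[n // 2, n // 2]
        err = np.angle(np.exp(1j * (inc - pair)))
        assert np.sqrt(np.mean(err ** 2)) < 0.2

    def test_all_masked_rejected(self, grid16):
        s = ms.NormalizedMatrix(values=np.zeros((256, 256), complex),
                                layer_index=0,
                                validity_mask=np.zeros((256, 256), bool),
                                grid=grid16)
        with pytest.raises(ValidationError):
            ms.estimate_phase(s, MSTConfig(layer_depths=[5.0]))


class TestApplyPhaseCorrection:
    def test_zero_estimate_is_identity(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        out = ms.apply_phase_correction(r, np.zeros((24, 24)), "input")
        np.testing.assert_array_equal(out.values, r.values)

    def test_apply_then_negate_restores(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        rng = np.random.default_rng(4)
        est = rng.uniform(-3, 3, (24, 24))
        out = ms.apply_phase_correction(
            ms.apply_phase_correction(r, est, "output"), -est, "output")
        np.testing.assert_allclose(out.values, r.values, atol=1e-12)

    def test_unknown_side_rejected(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        with pytest.raises(ValidationError, match="side"):
            ms.apply_phase_correction(r, np.zeros((24, 24)), "both")


class TestCorrectedReflection:
    def test_identity_correction_is_noop(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        empty = ms.MediumModel(grid=r.grid, plates=[])
        out = ms.corrected_reflection(r, empty)
        np.testing.assert_allclose(out.values, r.values, atol=1e-10)

    def test_ground_truth_correction_recovers_object(self, grid32):
        """Exact-inversion identity of the roundtrip model."""
        med = ms.build_medium(grid32, [10.0, 17.0, 25.0], 2.5, 0.9, seed=11)
        rng = np.random.default_rng(5)
        amp = rng.uniform(0, 1, (32, 32)).astype(complex)
        obj = ms.ObjectMap(grid32, amp)
        r = ms.reflection_from_medium(med, obj, reference_plane="z0")
        r_c = ms.corrected_reflection(r, med)
        np.testing.assert_allclose(r_c.diagonal_image(), amp, atol=1e-8)
        off = r_c.values - np.diag(np.diagonal(r_c.values))
        assert np.max(np.abs(off)) < 1e-8

    def test_depth_mismatch_rejected(self, single_plate_phantom):
        med, _, r = single_plate_phantom
        shifted = ms.transform_to_layer(r, 3.0, 3.0)
        with pytest.raises(ValidationError):
            ms.corrected_reflection(shifted, med)

    def test_wrong_depth_correction_is_worse(self, grid24):
        med, obj, r = make_single_plate(grid24)
        right = ms.corrected_reflection(r, med)
        wrong_med = ms.correction_medium(
            grid24, [med.plates[0].phase_map], [med.plates[0].depth + 20.0])
        wrong = ms.corrected_reflection(r, wrong_med)
        truth = obj.intensity()
        c_right = ms.pearson_score(
            np.abs(right.diagonal_image()) ** 2, truth)
        c_wrong = ms.pearson_score(
            np.abs(wrong.diagonal_image()) ** 2, truth)
        assert c_right > c_wrong


class TestReconstructObject:
    def test_exact_correction_recovers_object_up_to_phase(self, grid16):
        med = ms.build_medium(grid16, [5.0], 2.0, 0.8, seed=8)
        rng = np.random.default_rng(6)
        amp = rng.uniform(0.1, 1.0, (16, 16)).astype(complex)
        obj = ms.ObjectMap(grid16, amp)
        r = ms.reflection_from_medium(med, obj, reference_plane="z0")
        est = ms.reconstruct_object(ms.corrected_reflection(r, med))
        ratio = est.values / amp
        np.testing.assert_allclose(np.abs(ratio), 1.0, atol=1e-8)
        assert np.std(np.angle(ratio)) < 1e-8

    def test_plane_mismatch_rejected(self, single_plate_phantom):
        _, _, r = single_plate_phantom
        moved = ms.transform_to_layer(r, 8.0, 0.0)
        with pytest.raises(ValidationError):
            ms.reconstruct_object(moved)


class TestMSTIterate:
    def test_empty_medium_trivially_converges(self, grid16):
        rng = np.random.default_rng(0)
        amp = rng.uniform(0.1, 1, (16, 16)).astype(complex)
        obj = ms.ObjectMap(grid16, amp)
        med = ms.MediumModel(grid=grid16, plates=[])
        r = ms.reflection_from_medium(med, obj, reference_plane="z0")
        res = ms.mst_iterate(r, MSTConfig(layer_depths=[]))
        assert res.converged and res.cycles_run == 1
        assert res.xi1_trace[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(res.object_estimate, amp, atol=1e-10)

    def test_single_plate_phase_recovery(self, grid24):
        med, obj, r = make_single_plate(grid24)
        cfg = MSTConfig(layer_depths=[8.0], max_cycles=10)
        res = ms.MSTModel(r, [8.0], cfg).fit()
        assert res.converged
        assert res.phase_correlations(med)[0] > 0.99
        assert res.image_correlation(obj) > 0.99

    def test_piston_gauge_invariance(self, grid24):
        """Adding a constant to the true phase changes no intensity image."""
        med, obj, r1 = make_single_plate(grid24)
        shifted_plates = [ms.PhasePlate(p.phase_map + 1.234, p.depth, p.pitch)
                          for p in med.plates]
        med2 = ms.MediumModel(grid=grid24, plates=shifted_plates)
        r2 = ms.reflection_from_medium(med2, obj, reference_plane="z0")
        cfg = MSTConfig(layer_depths=[8.0], max_cycles=6)
        img1 = ms.MSTModel(r1, [8.0], cfg).fit().mst_image
        img2 = ms.MSTModel(r2, [8.0], cfg).fit().mst_image
        np.testing.assert_allclose(img1, img2, rtol=1e-6, atol=1e-9)

    def test_clutter_robustness(self, grid24):
        """Recovery survives strong object-uncorrelated background."""
        med, obj, r = make_single_plate(grid24, std=0.7)
        noisy = ms.add_background_scattering(r, 3.0, 2.5, seed=9)
        cfg = MSTConfig(layer_depths=[8.0], max_cycles=10)
        res = ms.MSTModel(noisy, [8.0], cfg).fit()
        assert res.phase_correlations(med)[0] > 0.8

    def test_depth_selectivity_peak(self, grid24):
        """A single-plate xi2 depth scan peaks at the true plate depth."""
        true_depth = 12.0
        med = ms.build_medium(grid24, [true_depth], 2.5, 0.9, seed=13)
        obj = ms.make_target_object("siemens_star", {"n_spokes": 6}, grid24)
        r = ms.reflection_from_medium(med, obj, reference_plane="z0")
        scans = {}
        for z in (4.0, 12.0, 20.0):
            cfg = MSTConfig(layer_depths=[z], max_cycles=3)
            scans[z] = ms.MSTModel(r, [z], cfg).fit().xi2
        assert scans[12.0] == max(scans.values())

    def test_mst_image_not_worse_than_confocal(self, grid24):
        med, obj, r = make_single_plate(grid24)
        cfg = MSTConfig(layer_depths=[8.0], max_cycles=8)
        res = ms.MSTModel(r, [8.0], cfg).fit()
        conf_corr = ms.pearson_score(res.confocal_reference(),
                                     obj.intensity())
        assert res.image_correlation(obj) > conf_corr
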