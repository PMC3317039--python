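import dataclasses
import math

import numpy as np
import pytest

import subfrac as sf


def circle_contour(cy, cx, radius, n=256):
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return sf.Contour(np.stack([cy + radius * np.sin(ang),
                                cx + radius * np.cos(ang)], axis=1))


class TestPlaneSelection:
    def test_matches_brute_force_on_random_stacks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            receptor = rng.integers(0, 30, size=(6, 16, 16))
            marker = rng.integers(0, 30, size=(6, 16, 16))
            stack = sf.ConfocalStack(
                np.stack([receptor, marker]).astype(np.uint16),
                ["receptor", "marker"], 0.25, 0.5)
            spec = sf.ThresholdSpec(12, 14)
            per_plane = [
                int(((receptor[z] > 12) & (marker[z] > 14)).sum())
                for z in range(6)
            ]
            expected = int(np.argmax(per_plane))  # first maximum
            assert sf.select_max_coloc_plane(stack, spec) == expected

    def test_constructed_peak_plane_found(self, clean_scene):
        _, stack, truth = clean_scene
        spec = sf.ThresholdSpec(0, 0)
        assert sf.select_max_coloc_plane(stack, spec) == truth.peak_plane_true

    def test_single_plane_stack_returns_zero(self):
        voxels = np.ones((2, 1, 4, 4), dtype=np.uint16)
        stack = sf.ConfocalStack(voxels, ["receptor", "marker"], 0.25, 0.5)
        assert sf.select_max_coloc_plane(stack, sf.ThresholdSpec(0, 0)) == 0

    def test_all_zero_stack_tie_breaks_to_lowest_index(self):
        voxels = np.zeros((2, 5, 4, 4), dtype=np.uint16)
        stack = sf.ConfocalStack(voxels, ["receptor", "marker"], 0.25, 0.5)
        assert sf.select_max_coloc_plane(stack, sf.ThresholdSpec(0, 0)) == 0


class TestTraceMembrane:
    def test_annulus_traced_to_outer_radius(self, clean_scene):
        _, stack, truth = clean_scene
        contour = sf.trace_membrane(
            stack.channel("marker")[truth.peak_plane_true], 0.0)
        assert contour.source == "auto_traced"
        assert len(contour.vertices) <= 256
        cy, cx = contour.centroid
        assert math.hypot(cy - truth.center_px[0],
                          cx - truth.center_px[1]) < 1.0
        radii = np.hypot(contour.vertices[:, 0] - cy,
                         contour.vertices[:, 1] - cx)
        assert abs(radii.mean() - truth.ring_outer_radius_px) < 1.0

    def test_blank_plane_raises_trace_failure(self):
        with pytest.raises(sf.TraceFailureError):
            sf.trace_membrane(np.zeros((64, 64)), 0.0)

    def test_manual_contour_passes_through_unmodified(self, clean_scene):
        _, stack, _ = clean_scene
        manual = circle_contour(96, 96, 80)
        frac = sf.membrane_measures(stack, sf.ThresholdSpec(0, 0),
                                    contour=manual)
        assert frac.contour is manual
        assert frac.contour.source == "manual"

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [0, 10], [10, 0]], float)
        with pytest.raises(sf.ValidationError):
            sf.Contour(bowtie)


class TestBand:
    def test_band_area_matches_analytic_annulus(self):
        # 2 μm band at 0.2 μm/px around a 50 px circle: area 1000π px²
        contour = circle_contour(80, 80, 50)
        band = sf.band_from_contour(contour, 2.0, 0.2, (160, 160))
        analytic = 1000 * math.pi
        assert abs(band.sum() - analytic) / analytic < 0.03

    def test_one_pixel_band_is_the_rasterized_outline(self):
        contour = circle_contour(40, 40, 20)
        band = sf.band_from_contour(contour, 0.25, 0.25, (80, 80))
        # pixels within half a pixel of the circle: a thin ring
        yy, xx = np.mgrid[0:80, 0:80]
        dist = np.abs(np.hypot(yy - 40.0, xx - 40.0) - 20.0)
        # allow the polygonal approximation of the circle ±0.02 px
        assert band[dist < 0.45].all()
        assert not band[dist > 0.55].any()

    def test_doubling_thickness_nests_band(self):
        contour = circle_contour(60, 60, 30)
        thin = sf.band_from_contour(contour, 2.0, 0.25, (120, 120))
        thick = sf.band_from_contour(contour, 4.0, 0.25, (120, 120))
        assert (thin & ~thick).sum() == 0
        assert thick.sum() > thin.sum()

    def test_subpixel_thickness_rejected(self):
        contour = circle_contour(20, 20, 10)
        with pytest.raises(sf.ValidationError):
            sf.band_from_contour(contour, 0.1, 0.25, (40, 40))


class TestMembraneMeasures:
    def test_noiseless_pools_match_planted_footprints_exactly(
            self, clean_scene):
        _, stack, truth = clean_scene
        frac = sf.membrane_measures(stack, sf.ThresholdSpec(0, 0))
        z = truth.peak_plane_true
        syn_fp = truth.class_footprint("synaptic", 0.0)[z]
        ex_fp = truth.class_footprint("extrasynaptic", 0.0)[z]
        assert np.array_equal(frac.synaptic_mask, syn_fp & frac.band_mask)
        assert np.array_equal(frac.extrasynaptic_mask,
                              ex_fp & frac.band_mask)
        assert frac.synaptic_px == int((syn_fp & frac.band_mask).sum())
        assert frac.extrasynaptic_px == int((ex_fp & frac.band_mask).sum())
        assert frac.synaptic_px > 0 and frac.extrasynaptic_px > 0

    def test_scene_without_membrane_puncta_counts_zero(self):
        params = sf.SceneParams(n_synaptic=0, n_extrasynaptic=0,
                                n_intracellular=5, background_level=0.0,
                                noise_model="none", apply_psf=False, seed=2)
        stack, _ = sf.generate_scene(params)
        frac = sf.membrane_measures(stack, sf.ThresholdSpec(0, 0))
        assert frac.synaptic_px == 0 and frac.extrasynaptic_px == 0

    def test_partition_identity_on_random_stacks(self):
        rng = np.random.default_rng(7)
        contour = circle_contour(32, 32, 20)
        for _ in range(10):
            receptor = rng.integers(0, 30, size=(3, 64, 64))
            marker = rng.integers(0, 30, size=(3, 64, 64))
            stack = sf.ConfocalStack(
                np.stack([receptor, marker]).astype(np.uint16),
                ["receptor", "marker"], 0.25, 0.5)
            spec = sf.ThresholdSpec(10, 12)
            frac = sf.membrane_measures(stack, spec, contour=contour)
            band = frac.band_mask
            r_in_band = int(
                ((receptor[frac.plane_index] > 10) & band).sum())
            assert frac.synaptic_px + frac.extrasynaptic_px == r_in_band

    def test_counts_monotone_in_thickness(self, clean_scene):
        _, stack, _ = clean_scene
        spec = sf.ThresholdSpec(0, 0)
        thin = sf.membrane_measures(stack, spec, thickness_um=1.0)
        thick = sf.membrane_measures(stack, spec, thickness_um=3.0)
        assert thick.synaptic_px >= thin.synaptic_px
        assert thick.extrasynaptic_px >= thin.extrasynaptic_px

    def test_trace_failure_without_contour_names_manual_fallback(self):
        voxels = np.zeros((2, 3, 64, 64), dtype=np.uint16)
        stack = sf.ConfocalStack(voxels, ["receptor", "marker"], 0.25, 0.5)
        with pytest.raises(sf.TraceFailureError, match="manual"):
            sf.membrane_measures(stack, sf.ThresholdSpec(0, 0))

    def test_plane_override_is_respected(self, clean_scene):
        _, stack, truth = clean_scene
        spec = sf.ThresholdSpec(0, 0)
        other = truth.peak_plane_true - 1
        frac = sf.membrane_measures(stack, spec, plane_override=other)
        assert frac.plane_index == other


class TestRecovery:
    def test_exact_recovery_on_clean_scene(self, clean_scene):
        _, stack, truth = clean_scene
        rec = sf.recover_scene_counts(stack, sf.ThresholdSpec(0, 0))
        assert rec == truth.counts_true

    def test_recovery_under_default_noise(self, control_thresholds):
        params = sf.SceneParams(seed=77)
        stack, truth = sf.generate_scene(params)
        rec = sf.recover_scene_counts(stack, control_thresholds)
        for cls, true_n in truth.counts_true.items():
            assert abs(rec[cls] - true_n) <= max(2, 0.2 * true_n)
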