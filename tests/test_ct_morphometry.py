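"""μCT quantification: thresholds, segmentation, volumes, edge band, areas."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otokit import ct_morphometry as ct
from otokit import synthetic as syn
from otokit.types import CTVolume, DegenerateInputError, RoiPair, ThresholdResult, VolumeMeta

from conftest import random_volume


def brute_force_segment(vol, roi, threshold):
    """Exhaustive voxel-scan oracle for supra-threshold segmentation."""
    out = np.zeros(vol.voxels.shape, dtype=bool)
    nz, ny, nx = vol.voxels.shape
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if roi[i, j, k] and vol.voxels[i, j, k] >= threshold:
                    out[i, j, k] = True
    return out


class TestHistogram:
    def test_constant_roi_occupies_single_bin(self):
        vol = CTVolume(np.full((4, 4, 4), 5.0))
        edges, counts = ct.roi_histogram(vol, np.ones((4, 4, 4), bool), n_bins=16)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 64

    def test_counts_conserve_roi_size(self):
        rng = np.random.default_rng(0)
        vol, roi = random_volume(rng)
        _, counts = ct.roi_histogram(vol, roi, n_bins=32)
        assert counts.sum() == roi.sum()

    def test_phantom_histogram_modes_near_generator_means(self, default_phantom):
        vol, rois, _ = default_phantom
        for roi, mu in ((rois.otolith_roi, 200.0), (rois.tissue_roi, 50.0)):
            edges, counts = ct.roi_histogram(vol, roi, n_bins=64)
            mode = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2
            assert abs(mode - mu) < 10.0

    def test_empty_roi_rejected(self):
        vol = CTVolume(np.zeros((3, 3, 3)))
        with pytest.raises(DegenerateInputError):
            ct.roi_histogram(vol, np.zeros((3, 3, 3), bool))


class TestThreshold:
    def test_midpoint_and_edge_band_arithmetic(self):
        thr = ThresholdResult(alpha=100.0, beta=20.0)
        assert thr.threshold == 60.0
        assert thr.edge_lower == pytest.approx(54.0)

    def test_no_contrast_rejected(self):
        with pytest.raises(DegenerateInputError, match="contrast"):
            ThresholdResult(alpha=50.0, beta=50.0)

    def test_pure_roi_phantom_recovers_exact_means(self):
        # snug ROIs on a sharp noiseless phantom: alpha and beta are exact
        p = syn.PhantomParams(edge_blur_um=0.0, noise_sd=0.0, roi_margin_um=0.0)
        vol, rois, _ = syn.gen_ct_phantom(p)
        thr = ct.compute_threshold(vol, rois)
        assert thr.alpha == 200.0
        assert thr.beta == 50.0
        assert thr.threshold == 125.0

    def test_mode_summary_ignores_dilution(self):
        # with a dilated ROI the mean is diluted by background but the mode is not
        p = syn.PhantomParams(edge_blur_um=0.0, noise_sd=0.0, roi_margin_um=10.0)
        vol, rois, _ = syn.gen_ct_phantom(p)
        thr = ct.compute_threshold(vol, rois, summary="mode")
        assert abs(thr.alpha - 200.0) < 3.0

    def test_swapped_rois_rejected(self, default_phantom):
        vol, rois, _ = default_phantom
        swapped = RoiPair(rois.tissue_roi, rois.otolith_roi)
        with pytest.raises(DegenerateInputError):
            ct.compute_threshold(vol, swapped)


class TestSegmentation:
    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vol, roi = random_volume(rng)
            t = float(rng.normal(100, 30))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seg = ct.segment_otolith(vol, roi, t)
            assert np.array_equal(seg, brute_force_segment(vol, roi, t))

    def test_threshold_below_min_returns_roi(self):
        rng = np.random.default_rng(2)
        vol, roi = random_volume(rng)
        seg = ct.segment_otolith(vol, roi, vol.voxels.min() - 1)
        assert np.array_equal(seg, roi)

    def test_threshold_above_max_warns_and_returns_empty(self):
        rng = np.random.default_rng(3)
        vol, roi = random_volume(rng)
        with pytest.warns(UserWarning, match="empty"):
            seg = ct.segment_otolith(vol, roi, vol.voxels.max() + 1)
        assert not seg.any()

    def test_keep_largest_selects_biggest_component(self):
        vox = np.zeros((5, 5, 5))
        vox[0, 0, 0] = 10  # isolated corner voxel
        vox[2:5, 2:5, 2:5] = 10  # 27-voxel block
        vol = CTVolume(vox)
        seg = ct.segment_otolith(vol, np.ones_like(vox, bool), 5.0, keep_largest=True)
        assert seg.sum() == 27
        assert not seg[0, 0, 0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), t1=st.floats(0, 200), dt=st.floats(0, 100))
    def test_segmentation_monotone_in_threshold(self, seed, t1, dt):
        vol, roi = random_volume(np.random.default_rng(seed), max_side=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            low = ct.segment_otolith(vol, roi, t1)
            high = ct.segment_otolith(vol, roi, t1 + dt)
        assert np.all(high <= low)  # higher threshold => subset


class TestQuantify:
    def test_volume_arithmetic(self):
        vox = np.zeros((4, 4, 4))
        seg = np.zeros((4, 4, 4), bool)
        seg.flat[:10] = True
        meta = VolumeMeta(spacing_um=(10.0, 10.0, 10.0))
        res = ct.quantify(CTVolume(vox, meta), seg)
        assert res.volume_um3 == pytest.approx(10_000.0)

    def test_noiseless_phantom_mean_is_exact(self):
        p = syn.PhantomParams(edge_blur_um=0.0, noise_sd=0.0, roi_margin_um=0.0)
        vol, rois, _ = syn.gen_ct_phantom(p)
        thr = ct.compute_threshold(vol, rois)
        seg = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold)
        res = ct.quantify(vol, seg)
        assert res.mean_ct == 200.0

    def test_mean_over_segmented_voxels_at_least_threshold(self, default_phantom):
        vol, rois, _ = default_phantom
        thr = ct.compute_threshold(vol, rois)
        seg = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold)
        res = ct.quantify(vol, seg)
        assert res.mean_ct >= thr.threshold

    def test_empty_mask_reports_missing_mean(self):
        vol = CTVolume(np.zeros((3, 3, 3)))
        res = ct.quantify(vol, np.zeros((3, 3, 3), bool))
        assert res.volume_um3 == 0.0
        assert math.isnan(res.mean_ct)


class TestEdgeVolume:
    def test_matches_brute_force_set_difference(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vol, roi = random_volume(rng)
            thr = ThresholdResult(alpha=160.0, beta=40.0)
            res = ct.striola_edge_volume(vol, roi, thr)
            oracle = brute_force_segment(vol, roi, thr.edge_lower) & ~brute_force_segment(
                vol, roi, thr.threshold
            )
            assert np.array_equal(res.edge_mask, oracle)

    def test_edge_band_disjoint_from_core_and_union_is_wide_seg(self, default_phantom):
        vol, rois, _ = default_phantom
        thr = ct.compute_threshold(vol, rois)
        core = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold)
        res = ct.striola_edge_volume(vol, rois.otolith_roi, thr)
        wide = ct.segment_otolith(vol, rois.otolith_roi, thr.edge_lower)
        assert not np.any(res.edge_mask & core)
        assert np.array_equal(res.edge_mask | core, wide)

    def test_sharp_boundary_has_zero_edge_volume(self):
        p = syn.striola_preset(edge_blur_um=0.0, noise_sd=0.0)
        vol, rois, _ = syn.gen_ct_phantom(p)
        thr = ct.compute_threshold(vol, rois)
        res = ct.striola_edge_volume(vol, rois.otolith_roi, thr)
        assert res.edge_voxels == 0

    def test_striola_channel_excluded_from_supra_threshold_model(self):
        # the low-density channel should appear as a central gap, as it does
        # in reconstructed young-utricle models
        vol, rois, truth = syn.gen_ct_phantom(syn.striola_preset(seed=1))
        thr = ct.compute_threshold(vol, rois)
        seg = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold)
        inside = seg & truth.striola_mask
        assert inside.sum() / truth.striola_mask.sum() < 0.01


class TestSliceAreas:
    @pytest.mark.parametrize("axis", ["z", "y", "x"])
    def test_slice_sum_recovers_volume(self, axis, default_phantom):
        vol, rois, _ = default_phantom
        thr = ct.compute_threshold(vol, rois)
        seg = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold)
        table = ct.slice_areas(seg, vol.meta, axis=axis)
        thickness = vol.meta.spacing_um[{"z": 0, "y": 1, "x": 2}[axis]]
        total = (table["area_um2"] * thickness).sum()
        assert total == pytest.approx(ct.quantify(vol, seg).volume_um3)

    def test_sphere_slices_match_analytic_circles(self):
        r = 50.0
        p = syn.PhantomParams(
            grid=(60, 60, 60), spacing_um=(2.0, 2.0, 2.0), semi_axes_um=(r, r, r),
            edge_blur_um=0.0, noise_sd=0.0,
        )
        _, _, truth = syn.gen_ct_phantom(p)
        table = ct.slice_areas(truth.otolith_mask, VolumeMeta((2.0, 2.0, 2.0)), axis="z")
        center = (60 - 1) / 2.0 * 2.0
        for k, area in zip(table["slice"], table["area_um2"]):
            z = k * 2.0 - center
            if abs(z) < 0.8 * r:  # compare away from the poles
                analytic = math.pi * (r**2 - z**2)
                assert abs(area - analytic) / analytic < 0.05

    def test_empty_slice_has_zero_area(self):
        seg = np.zeros((4, 4, 4), bool)
        seg[2, :, :] = True
        table = ct.slice_areas(seg, VolumeMeta((10.0, 10.0, 10.0)), axis="z")
        assert table["area_um2"][0] == 0.0
        assert table["area_um2"][2] == 1600.0
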