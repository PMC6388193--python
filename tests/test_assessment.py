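"""Fit assessment: margin measurement, indirect gap segmentation, thickness
maps, summary statistics, and ANOVA, each against independent oracles."""

import numpy as np
import pytest
from scipy import ndimage, stats

from veneerfit.assessment import (
    DetectionError,
    GapModel,
    aggregate_per_sample_medians,
    compute_thickness_map,
    measure_marginal_gap,
    one_way_anova,
    reconstruct_gap_model,
    segment_gap_indirect,
    summarize_gap,
)
from veneerfit.imaging import ParameterError, VoxelVolume
from veneerfit.phantoms import render_synthetic_margin
from veneerfit.segmentation import BinaryMask
from veneerfit.thickness import local_thickness

UM = 12.8  # µCT voxel size in µm
SP = UM / 1000.0


class TestMeasureMarginalGap:
    def test_parallel_edges_constant_gap(self):
        img = render_synthetic_margin(lambda y: np.full_like(np.asarray(y, float), 50.0),
                                      pixel_size=5.0, tooth_edge_col=100)
        m = measure_marginal_gap(img, pixel_size=5.0)
        assert len(m.readings) == 6
        np.testing.assert_allclose(m.readings, 50.0, atol=5.0)

    def test_closed_margin_near_zero(self):
        img = render_synthetic_margin(lambda y: np.zeros_like(np.asarray(y, float)),
                                      pixel_size=5.0, tooth_edge_col=100)
        m = measure_marginal_gap(img, pixel_size=5.0)
        assert np.all(m.readings <= 5.0 + 1e-9)  # within one pixel of zero

    def test_sinusoidal_profile_within_one_pixel(self):
        px = 5.0
        prof = lambda y_um: 100 + 40 * np.sin(2 * np.pi * np.asarray(y_um, float) / 600.0)
        img = render_synthetic_margin(prof, pixel_size=px, shape=(300, 300),
                                      tooth_edge_col=80, veneer_width_px=120)
        m = measure_marginal_gap(img, px)
        truth = prof(m.stations[:, 0] * px)
        assert np.all(np.abs(m.readings - truth) <= px)

    def test_station_count_configurable(self):
        img = render_synthetic_margin(lambda y: np.full_like(np.asarray(y, float), 60.0),
                                      pixel_size=5.0)
        m = measure_marginal_gap(img, 5.0, n_stations=10)
        assert len(m.readings) == 10

    def test_uniform_image_detection_error(self):
        with pytest.raises(DetectionError):
            measure_marginal_gap(np.full((64, 64), 3.0), 5.0)

    def test_single_region_detection_error(self):
        img = np.full((64, 64), 0.05)
        img[10:50, 10:50] = 0.9
        with pytest.raises(DetectionError):
            measure_marginal_gap(img, 5.0)

    def test_noise_tolerance(self):
        prof = lambda y: np.full_like(np.asarray(y, float), 80.0)
        img = render_synthetic_margin(prof, pixel_size=4.0, noise_sd=0.05, seed=3)
        m = measure_marginal_gap(img, 4.0)
        np.testing.assert_allclose(m.readings, 80.0, atol=8.0)


def _phases_volume(labels: np.ndarray, intensities=(0.0, 100.0, 60.0)) -> VoxelVolume:
    data = np.asarray(intensities)[labels]
    return VoxelVolume(data, [SP] * 3)


class TestSegmentGapIndirect:
    @staticmethod
    def _sandwich_labels(gap_vox: int, n=40):
        """Flat sandwich: tooth slab | air gap | veneer slab."""
        lab = np.zeros((n, n, 30 + gap_vox), np.uint8)
        lab[:, :, :12] = 1  # tooth
        lab[:, :, 12 + gap_vox : 24 + gap_vox] = 2  # veneer
        return lab

    def test_gap_mask_matches_truth(self):
        lab = self._sandwich_labels(8)
        vol = _phases_volume(lab)
        combined, enamel, gap = segment_gap_indirect(vol, (30, 200), (30, 200),
                                                     expected_gap_um=100)
        truth = lab == 0
        truth[:, :, :12] = False
        truth[:, :, 24 + 8 :] = False
        # evaluate away from the lateral scan borders, where a sliced-open
        # gap cannot be closed by any morphological protocol
        core = (slice(10, 30), slice(10, 30), slice(None))
        g, t = gap.data[core], truth[core]
        dice = 2 * (g & t).sum() / (g.sum() + t.sum())
        assert dice >= 0.95

    def test_enamel_equals_combined_gives_empty_gap(self):
        lab = self._sandwich_labels(4)
        vol = _phases_volume(lab)
        combined, enamel, gap = segment_gap_indirect(vol, (30, 200), (30, 200),
                                                     closing_radius=0)
        # no closing: combined == enamel -> empty difference
        np.testing.assert_array_equal(combined.data, enamel.data)
        assert not gap.data.any()

    def test_subset_mask_logic(self):
        a = np.zeros((8, 8, 8), bool)
        a[2:6, 2:6, 2:6] = True
        b = np.zeros_like(a)
        b[3:5, 3:5, 3:5] = True
        combined = BinaryMask(a, [SP] * 3)
        enamel = BinaryMask(b, [SP] * 3)
        model = reconstruct_gap_model(combined, enamel, min_component_voxels=1,
                                      mesh_booleans=False)
        np.testing.assert_array_equal(model.mask.data, a & ~b)

    def test_gap_set_identity_exact(self):
        rng = np.random.default_rng(0)
        lab = self._sandwich_labels(6)
        vol = _phases_volume(lab)
        vol.data += rng.normal(0, 2.0, vol.shape)
        combined, enamel, gap = segment_gap_indirect(vol, (30, 200), (30, 200),
                                                     expected_gap_um=80)
        np.testing.assert_array_equal(gap.data, combined.data & ~enamel.data)


class TestReconstructGapModel:
    @staticmethod
    def _concentric_masks(r_out=0.5, r_in=0.35, n=96):
        g = (np.arange(n) - n / 2) * SP
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        R = np.sqrt(X**2 + Y**2 + Z**2)
        combined = BinaryMask(R <= r_out, [SP] * 3, origin=[-n / 2 * SP] * 3)
        enamel = BinaryMask(R <= r_in, [SP] * 3, origin=[-n / 2 * SP] * 3)
        return combined, enamel

    def test_shell_volume(self):
        combined, enamel = self._concentric_masks()
        model = reconstruct_gap_model(combined, enamel, mesh_booleans=False)
        analytic = 4 / 3 * np.pi * (0.5**3 - 0.35**3)
        assert model.mask.volume_mm3() == pytest.approx(analytic, rel=0.03)

    def test_zero_gap_empty_model(self):
        combined, enamel = self._concentric_masks(r_out=0.5, r_in=0.5)
        model = reconstruct_gap_model(combined, enamel)
        assert model.empty

    def test_mesh_and_voxel_routes_agree(self):
        combined, enamel = self._concentric_masks()
        model = reconstruct_gap_model(combined, enamel, mesh_booleans=True)
        assert model.mesh is not None
        assert model.mesh.volume() == pytest.approx(model.mask.volume_mm3(), rel=0.05)

    def test_speck_noise_discarded(self):
        combined, enamel = self._concentric_masks()
        combined.data[2, 2, 2] = True  # isolated speck far from the shell
        model = reconstruct_gap_model(combined, enamel, mesh_booleans=False)
        assert not model.mask.data[2, 2, 2]


class TestThicknessMap:
    def test_slab_100um(self):
        n = int(round(100.0 / UM))
        mask = np.zeros((40, 40, n + 12), bool)
        mask[:, :, 6 : 6 + n] = True
        th = local_thickness(mask, UM)
        assert abs(np.median(th[mask]) - 100.0) <= UM

    @pytest.mark.parametrize("gap_um", [50.0, 100.0, 150.0, 200.0])
    def test_slab_parameter_recovery(self, gap_um):
        n = int(round(gap_um / UM))
        mask = np.zeros((30, 30, n + 12), bool)
        mask[:, :, 6 : 6 + n] = True
        th = local_thickness(mask, UM)
        assert abs(np.median(th[mask]) - gap_um) <= UM

    def test_shell_150um(self):
        g = (np.arange(121) - 60) * SP
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        R = np.sqrt(X**2 + Y**2 + Z**2)
        mask = (R >= 0.5) & (R < 0.65)
        th = local_thickness(mask, UM)
        assert abs(np.median(th[mask]) - 150.0) <= UM

    def test_single_voxel(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        th = local_thickness(mask, UM)
        assert th[4, 4, 4] == pytest.approx(UM)

    def test_axis_rotation_invariance(self):
        n = 7
        mask = np.zeros((30, 30, 30), bool)
        mask[:, :, 10 : 10 + n] = True
        th_z = local_thickness(mask, UM)
        th_x = local_thickness(mask.transpose(2, 1, 0), UM)
        assert np.median(th_z[mask]) == pytest.approx(
            np.median(th_x[mask.transpose(2, 1, 0)])
        )

    def test_compute_thickness_map_empty(self):
        model = GapModel(BinaryMask(np.zeros((4, 4, 4), bool), [SP] * 3), None)
        out = compute_thickness_map(model)
        assert out.thickness_um is not None
        assert not out.thickness_um.any()


class TestSummarizeGap:
    def test_symmetric_triple(self):
        s = summarize_gap([50.0, 100.0, 150.0])
        assert s.mean == 100.0
        assert s.median == 100.0

    def test_all_below_cutoff(self):
        s = summarize_gap([10, 20, 30], cutoff=200)
        assert s.fraction_below_cutoff == 1.0

    def test_truncated_normal_oracle(self):
        mu, sigma = 100.0, 50.0
        a = (0 - mu) / sigma
        rvs = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=1000,
                                  random_state=np.random.default_rng(9))
        s = summarize_gap(rvs)
        # closed-form truncated-normal mean
        expected = mu + sigma * stats.norm.pdf(a) / (1 - stats.norm.cdf(a))
        se = rvs.std(ddof=1) / np.sqrt(len(rvs))
        assert abs(s.mean - expected) <= 3 * se

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            summarize_gap([])

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(10, 300, 50)
        k = 2.5
        s1 = summarize_gap(v, cutoff=150.0)
        s2 = summarize_gap(v * k, cutoff=150.0 * k)
        assert s2.mean == pytest.approx(k * s1.mean)
        assert s2.sd == pytest.approx(k * s1.sd)
        assert s2.median == pytest.approx(k * s1.median)
        assert s2.fraction_below_cutoff == s1.fraction_below_cutoff

    def test_sd_is_sample_form(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert summarize_gap(v).sd == pytest.approx(np.std(v, ddof=1))


class TestAggregateMedians:
    def test_single_sample(self):
        mean, sd, iqr, med = aggregate_per_sample_medians([[1.0, 2.0, 3.0]])
        assert mean == 2.0
        assert sd == 0.0

    def test_known_medians(self):
        mean, sd, _, med = aggregate_per_sample_medians(
            [[100.0, 100.0], [150.0, 150.0], [200.0, 200.0]]
        )
        assert mean == 150.0
        np.testing.assert_array_equal(med, [100, 150, 200])

    def test_brute_force_two_stage(self):
        rng = np.random.default_rng(12)
        samples = [rng.uniform(50, 250, rng.integers(5, 30)) for _ in range(10)]
        mean, sd, (q1, q3), _ = aggregate_per_sample_medians(samples)
        meds = np.array([np.median(s) for s in samples])
        assert mean == pytest.approx(meds.mean())
        assert sd == pytest.approx(meds.std(ddof=1))
        assert (q1, q3) == pytest.approx(tuple(np.percentile(meds, [25, 75])))

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_per_sample_medians([])


class TestAnova:
    def test_identical_groups(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        # {1,2},{2,3},{3,4}: SSB = 4 (df 2), SSW = 1.5 (df 3) -> F = 4.0
        r = one_way_anova([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        assert r.df_between == 2
        assert r.df_within == 3
        assert r.f_statistic == pytest.approx(4.0)
        f_scipy, p_scipy = stats.f_oneway([1.0, 2.0], [2.0, 3.0], [3.0, 4.0])
        assert r.f_statistic == pytest.approx(f_scipy)
        assert r.p_value == pytest.approx(p_scipy)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        r = one_way_anova([a, b])
        t, p = stats.ttest_ind(a, b)
        assert r.f_statistic == pytest.approx(t**2, rel=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_seeded(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 12))
                  for _ in range(int(rng.integers(2, 6)))]
        r = one_way_anova(groups)
        f, p = stats.f_oneway(*groups)
        assert r.f_statistic == pytest.approx(f, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-8)

    def test_degenerate_variance(self):
        with pytest.raises(ParameterError):
            one_way_anova([[5.0, 5.0], [5.0, 5.0]])

    def test_too_few_groups(self):
        with pytest.raises(ParameterError):
            one_way_anova([[1, 2, 3]])
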