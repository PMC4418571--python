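"""Lagged cross-correlation best-frequency mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tonorep import (
    FrequencyProgression,
    HemodynamicModel,
    SheetSpec,
    VolumeSeries,
    best_frequency_map,
    build_reference_cycle,
    combine_directions,
    make_tonotopic_sheet,
    r_to_p,
    simulate_tonotopy_run,
    threshold_map,
)


@pytest.fixture(scope="module")
def noiseless_maps(default_gt, progression):
    asc_run = simulate_tonotopy_run(default_gt, progression, noise_sd=0.0, seed=0,
                                    global_noise_sd=0.0)
    desc_run = simulate_tonotopy_run(default_gt, progression.reversed(), noise_sd=0.0,
                                     seed=0, global_noise_sd=0.0)
    return (
        best_frequency_map(asc_run, progression),
        best_frequency_map(desc_run, progression.reversed()),
    )


class TestReferenceCycle:
    def test_32s_cycle_at_tr2_gives_16_samples(self, progression):
        ref = build_reference_cycle(progression, tr=2.0)
        assert ref.size == 16

    def test_reference_peaks_near_hrf_peak_delay(self, progression):
        hrf = HemodynamicModel()
        ref = build_reference_cycle(progression, hrf, tr=2.0)
        peak_time = np.argmax(ref) * 2.0
        assert abs(peak_time - hrf.peak_delay) <= 2.0

    def test_reference_integral_positive(self, progression):
        assert build_reference_cycle(progression, tr=2.0).sum() > 0

    def test_tr_must_divide_cycle(self, progression):
        with pytest.raises(ValueError, match="does not divide"):
            build_reference_cycle(progression, tr=3.0)


class TestBestFrequencyMap:
    def test_noiseless_run_recovers_all_best_frequencies(self, default_gt, noiseless_maps):
        for tmap in noiseless_maps:
            resp = default_gt.responsive
            assert np.all(
                np.isclose(tmap.best_frequency[resp], default_gt.best_frequency[resp])
            )

    def test_constant_voxel_excluded_with_reason(self, default_gt, progression):
        run = simulate_tonotopy_run(default_gt, progression, noise_sd=0.0, seed=0,
                                    global_noise_sd=0.0)
        tmap = best_frequency_map(run, progression)
        background = ~default_gt.responsive
        assert not tmap.mask[background].any()
        assert tmap.excluded["constant"][background].all()
        assert np.all(np.isnan(tmap.r[background]))

    def test_time_courses_shifted_by_one_step_differ_by_half_octave(self, progression):
        ref = build_reference_cycle(progression, tr=2.0)
        base = np.tile(ref, 15)
        data = np.stack([base, np.roll(base, 1)]).reshape(2, 1, 1, 240).astype(float)
        run = VolumeSeries(data=data, tr=2.0)
        tmap = best_frequency_map(run, progression)
        f0, f1 = tmap.best_frequency[0, 0, 0], tmap.best_frequency[1, 0, 0]
        assert np.isclose(f1 / f0, 2 ** 0.5, rtol=0.02)

    def test_null_voxel_suprathreshold_rate_matches_independent_monte_carlo(self, progression):
        """P(max-lag r > 0.13) for pure-noise voxels agrees with a direct null."""
        rng = np.random.default_rng(0)
        n_vox, n_frames = 4000, 240
        data = rng.standard_normal((n_vox, 1, 1, n_frames))
        run = VolumeSeries(data=data, tr=2.0)
        tmap = best_frequency_map(run, progression)
        observed = (tmap.r > 0.13).mean()

        # independent oracle: correlate fresh noise against the 16 shifted
        # references with plain corrcoef arithmetic
        ref = build_reference_cycle(progression, tr=2.0)
        refs = np.stack([np.roll(np.tile(ref, 15), lag) for lag in range(16)])
        refs = (refs - refs.mean(1, keepdims=True)) / refs.std(1, keepdims=True)
        noise = rng.standard_normal((4000, n_frames))
        noise = (noise - noise.mean(1, keepdims=True)) / noise.std(1, keepdims=True)
        null_max_r = (noise @ refs.T / n_frames).max(axis=1)
        expected = (null_max_r > 0.13).mean()
        assert abs(observed - expected) < 0.03

    def test_frequency_estimates_equivariant_under_axis_relabelling(
        self, default_gt, progression
    ):
        run = simulate_tonotopy_run(default_gt, progression, seed=3)
        tmap = best_frequency_map(run, progression)
        swapped = VolumeSeries(data=run.data.transpose(1, 0, 2, 3), tr=run.tr)
        tmap_swapped = best_frequency_map(swapped, progression)
        assert np.array_equal(
            tmap.best_frequency.transpose(1, 0, 2),
            tmap_swapped.best_frequency,
            equal_nan=True,
        )


class TestCombineDirections:
    def test_combining_identical_maps_is_identity(self, noiseless_maps):
        asc, _ = noiseless_maps
        combined = combine_directions(asc, asc)
        assert np.array_equal(combined.best_frequency, asc.best_frequency, equal_nan=True)

    def test_hemodynamic_delay_bias_cancels_exactly(self, default_gt, progression):
        """Analyzing with an HRF 2 s too slow biases each direction by one
        step in opposite senses; the combination recovers the truth everywhere."""
        asc_run = simulate_tonotopy_run(default_gt, progression, noise_sd=0.0, seed=0,
                                        global_noise_sd=0.0)
        desc_run = simulate_tonotopy_run(default_gt, progression.reversed(), noise_sd=0.0,
                                         seed=0, global_noise_sd=0.0)
        wrong = HemodynamicModel(peak_delay=6.2, peak_dispersion=0.7)
        asc_map = best_frequency_map(asc_run, progression, hrf=wrong)
        desc_map = best_frequency_map(desc_run, progression.reversed(), hrf=wrong)
        resp = default_gt.responsive
        # each single-direction map is biased for most voxels
        assert np.isclose(asc_map.best_frequency[resp], default_gt.best_frequency[resp]).mean() < 0.2
        combined = combine_directions(asc_map, desc_map)
        assert np.all(
            np.isclose(combined.best_frequency[resp], default_gt.best_frequency[resp])
        )

    def test_disagreeing_voxels_flagged_unreliable(self, noiseless_maps):
        import copy

        asc, desc = noiseless_maps
        shifted = copy.deepcopy(desc)
        vox = tuple(np.argwhere(asc.mask)[0])
        shifted.ascending_index[vox] += 5
        combined = combine_directions(asc, shifted)
        assert not combined.mask[vox]
        assert combined.excluded["disagreement"][vox]

    def test_different_grids_rejected(self, noiseless_maps, progression):
        asc, _ = noiseless_maps
        small = VolumeSeries(data=np.random.default_rng(0).standard_normal((2, 2, 1, 240)),
                             tr=2.0)
        other = best_frequency_map(small, progression)
        with pytest.raises(ValueError, match="grids"):
            combine_directions(asc, other)


class TestRToP:
    def test_zero_correlation_gives_p_one(self):
        assert r_to_p(0.0, 240) == pytest.approx(1.0)

    def test_paper_threshold_equivalence(self):
        """r = 0.13 at n = 240 frames is significant at the 5% level."""
        assert r_to_p(0.13, 240) <= 0.05
        assert r_to_p(0.13, 240) > 0.01

    def test_unit_correlation_gives_p_zero(self):
        assert r_to_p(1.0, 10) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            r_to_p(0.5, 2)

    def test_matches_permutation_null(self):
        """p(r=0.5, n=10) agrees with a 10,000-draw permutation null within 0.02."""
        rng = np.random.default_rng(1)
        n = 10
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        perms = np.stack([rng.permutation(y) for _ in range(10_000)])
        perms = (perms - perms.mean(1, keepdims=True)) / perms.std(1, keepdims=True)
        null_r = perms @ x / n
        p_perm = (np.abs(null_r) >= 0.5).mean()
        assert abs(r_to_p(0.5, n) - p_perm) < 0.02


class TestThresholdMap:
    def test_rmin_minus_one_keeps_every_valid_voxel(self, noiseless_maps):
        asc, _ = noiseless_maps
        thr = threshold_map(asc, -1.0)
        assert np.array_equal(thr.mask, asc.mask)

    def test_rmin_one_empties_mask(self, noiseless_maps):
        asc, _ = noiseless_maps
        assert not threshold_map(asc, 1.0).mask.any()

    def test_default_threshold_covers_most_responsive_voxels(self, default_gt, progression):
        run_a = simulate_tonotopy_run(default_gt, progression, seed=21)
        run_d = simulate_tonotopy_run(default_gt, progression.reversed(), seed=22)
        combined = combine_directions(
            best_frequency_map(run_a, progression),
            best_frequency_map(run_d, progression.reversed()),
        )
        thr = threshold_map(combined, 0.13)
        assert thr.mask[default_gt.responsive].mean() >= 0.95

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=-1.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_raising_threshold_never_adds_voxels(self, noiseless_maps, r_min, delta):
        asc, _ = noiseless_maps
        low = threshold_map(asc, r_min)
        high = threshold_map(asc, min(r_min + delta, 1.0))
        assert not (high.mask & ~low.mask).any()
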