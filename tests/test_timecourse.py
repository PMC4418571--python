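"""Block time-course extraction, segmentation and repetition statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.anova import AnovaRM

from tonorep import (
    VolumeSeries,
    anova_2x2_timepoint,
    contrast_conditions,
    extract_block_timecourses,
    extrema_stats,
    glm_sound_vs_rest,
    make_block_design,
    segment_phases,
    simulate_repetition_run,
)
from tonorep.timecourse import FRAMES_PER_BLOCK, SegmentLabels


def make_segments(windows):
    return SegmentLabels(
        slope_t=np.zeros(14), slope_p=np.ones(14),
        labels=["plateau"] * 14, windows=windows, tr=2.0, alpha=0.05,
    )


class TestExtraction:
    def test_constant_run_gives_all_zero_timecourses(self, gt_rois, block_design):
        data = np.full(gt_rois.labels.shape + (block_design.n_frames,), 100.0)
        run = VolumeSeries(data=data, tr=2.0)
        tcs = extract_block_timecourses(run, gt_rois, block_design)
        for tc in tcs:
            assert np.allclose(tc.values, 0.0)

    def test_thirty_second_blocks_give_fifteen_frames(self, default_gt, gt_rois, block_design):
        run = simulate_repetition_run(default_gt, block_design, seed=0)
        tcs = extract_block_timecourses(run, gt_rois, block_design)
        assert all(tc.values.size == 15 for tc in tcs)
        assert all(tc.values[0] == 0.0 for tc in tcs)
        assert {tc.condition for tc in tcs} == {"REP", "CTRL"}

    def test_averaging_identical_runs_changes_nothing(self, default_gt, gt_rois, block_design):
        run = simulate_repetition_run(default_gt, block_design, seed=5)
        one = extract_block_timecourses(run, gt_rois, block_design)
        two = extract_block_timecourses([run, run], gt_rois, block_design)
        for a, b in zip(one, two):
            assert np.allclose(a.values, b.values)
            assert b.n_blocks == 2 * a.n_blocks

    def test_block_past_run_end_dropped_with_warning(self, gt_rois):
        design = make_block_design(2, tr=2.0)
        data = 100.0 + np.zeros(gt_rois.labels.shape + (design.n_frames - 5,))
        run = VolumeSeries(data=data, tr=2.0)
        with pytest.warns(UserWarning, match="past the run end"):
            tcs = extract_block_timecourses(run, gt_rois, design)
        # only the final (CTRL) block is truncated
        counts = {tc.condition: tc.n_blocks for tc in tcs}
        assert counts == {"REP": 2, "CTRL": 1}


class TestSegmentation:
    def test_flat_timecourses_are_all_plateau(self):
        rng = np.random.default_rng(0)
        values = 1e-6 * rng.standard_normal((9, FRAMES_PER_BLOCK))
        values[:, 0] = 0
        seg = segment_phases(values)
        assert all(lab == "plateau" for lab in seg.labels)
        assert seg.windows["rise"] is None and seg.windows["decay"] is None

    def test_piecewise_linear_truth_recovered(self):
        """Up 4 frames, flat 6, down 4 at high SNR gives the built-in windows."""
        rng = np.random.default_rng(1)
        template = np.concatenate([
            np.linspace(0, 1, 5),              # rise over frames 0-4
            np.ones(6),                        # plateau frames 5-10
            np.linspace(0.8, 0.2, 4),          # decay frames 11-14
        ])
        values = template + 0.01 * rng.standard_normal((9, 15))
        values -= values[:, :1]
        seg = segment_phases(values)
        assert seg.windows["rise"] == (0.0, 8.0)
        assert seg.windows["plateau"] == (8.0, 20.0)
        assert seg.windows["decay"] == (20.0, 28.0)

    def test_phase_windows_are_ordered(self):
        rng = np.random.default_rng(2)
        template = np.concatenate([np.linspace(0, 1, 4), np.ones(7), np.linspace(1, 0, 4)])
        values = template + 0.02 * rng.standard_normal((9, 15))
        seg = segment_phases(values - values[:, :1])
        w = seg.windows
        assert w["rise"][1] <= w["plateau"][0] <= w["plateau"][1] <= w["decay"][0]

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            segment_phases(np.zeros((2, 15)))

    def test_offset_invariance_across_subjects(self):
        """Adding a per-subject constant never changes the segmentation."""
        rng = np.random.default_rng(3)
        values = rng.standard_normal((9, 15))
        seg1 = segment_phases(values)
        seg2 = segment_phases(values + rng.standard_normal((9, 1)) * 100)
        assert seg1.labels == seg2.labels
        assert seg1.windows == seg2.windows


class TestContrast:
    def test_identical_conditions_give_no_effect(self):
        rng = np.random.default_rng(4)
        rep = rng.standard_normal((9, 15))
        seg = make_segments({"rise": (2.0, 6.0), "plateau": (6.0, 18.0), "decay": (18.0, 22.0)})
        res = contrast_conditions(rep, rep.copy(), seg)
        assert not res.significant.any()
        assert not res.repetition_effect

    def test_suppressed_plateau_detected(self):
        rng = np.random.default_rng(5)
        ctrl = np.ones((9, 15)) + 0.05 * rng.standard_normal((9, 15))
        rep = ctrl.copy()
        rep[:, 3:9] -= 0.5                     # CTRL > REP inside the plateau
        seg = make_segments({"rise": (2.0, 6.0), "plateau": (6.0, 18.0), "decay": (18.0, 22.0)})
        res = contrast_conditions(rep, ctrl, seg)
        assert res.repetition_effect

    def test_difference_outside_plateau_does_not_count(self):
        rng = np.random.default_rng(6)
        ctrl = np.ones((9, 15)) + 0.05 * rng.standard_normal((9, 15))
        rep = ctrl.copy()
        rep[:, 12:] -= 0.5                     # only during frames at 24-28 s
        seg = make_segments({"rise": (2.0, 6.0), "plateau": (6.0, 18.0), "decay": (18.0, 22.0)})
        res = contrast_conditions(rep, ctrl, seg)
        assert not res.repetition_effect
        assert res.significant[12:].all()

    def test_unpaired_shapes_rejected(self):
        seg = make_segments({"plateau": (6.0, 18.0)})
        with pytest.raises(ValueError, match="paired"):
            contrast_conditions(np.zeros((9, 15)), np.zeros((8, 15)), seg)


class TestAnova:
    def test_identical_cells_give_zero_f(self):
        cells = np.ones((9, 2, 2, 15))
        res = anova_2x2_timepoint(cells)
        assert np.all(res.f_condition == 0) and np.all(res.p_condition == 1)

    def test_pure_condition_offset_detected(self):
        rng = np.random.default_rng(7)
        cells = rng.standard_normal((9, 2, 2, 15)) * 0.1
        cells[:, :, 1, :] += 2.0               # REP vs CTRL offset, no hemisphere effect
        res = anova_2x2_timepoint(cells)
        assert np.all(res.p_condition < 0.01)
        assert np.mean(res.p_hemisphere < 0.05) < 0.3
        assert np.mean(res.p_interaction < 0.05) < 0.3

    def test_f_values_match_independent_rm_anova_to_six_decimals(self):
        rng = np.random.default_rng(8)
        cells = rng.standard_normal((9, 2, 2, 3))
        res = anova_2x2_timepoint(cells)
        for j in range(3):
            rows = [
                {"s": s, "h": h, "c": c, "y": cells[s, h, c, j]}
                for s in range(9) for h in range(2) for c in range(2)
            ]
            table = AnovaRM(pd.DataFrame(rows), "y", "s", within=["h", "c"]).fit().anova_table
            assert np.isclose(res.f_condition[j], table.loc["c", "F Value"], atol=1e-6)
            assert np.isclose(res.f_hemisphere[j], table.loc["h", "F Value"], atol=1e-6)
            assert np.isclose(res.f_interaction[j], table.loc["h:c", "F Value"], atol=1e-6)

    def test_condition_effect_equals_squared_paired_t(self):
        """With hemispheres collapsed to equal copies, F = t^2 to 4 decimals."""
        from scipy import stats

        rng = np.random.default_rng(9)
        rep = rng.standard_normal((9, 15))
        ctrl = rng.standard_normal((9, 15))
        cells = np.stack(
            [np.stack([ctrl, rep], axis=1), np.stack([ctrl, rep], axis=1)], axis=1
        )
        res = anova_2x2_timepoint(cells)
        t = stats.ttest_rel(ctrl, rep, axis=0).statistic
        assert np.allclose(res.f_condition, t**2, atol=1e-4)

    def test_missing_cells_rejected(self):
        cells = np.ones((9, 2, 2, 15))
        cells[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            anova_2x2_timepoint(cells)


class TestExtrema:
    def test_monotone_timecourse_extrema_at_ends(self):
        tc = np.tile(np.linspace(0, 1, 15), (5, 1))
        res = extrema_stats(tc, tc.copy())
        assert np.all(res.rep_max == 1.0) and np.all(res.rep_min == 0.0)

    def test_constant_shift_moves_extrema_not_amplitude(self):
        rng = np.random.default_rng(10)
        ctrl = rng.standard_normal((12, 15))
        rep = ctrl - 0.5                       # uniform downward shift
        res = extrema_stats(rep, ctrl)
        assert res.p_maxima < 0.01
        assert res.p_minima < 0.01
        # amplitudes are unchanged up to rounding; their test stays null
        assert np.allclose(res.rep_amplitude, res.ctrl_amplitude)
        assert res.p_amplitude > 0.05

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=-50, max_value=50))
    def test_amplitude_invariant_to_constant_offsets(self, shift):
        rng = np.random.default_rng(11)
        rep = rng.standard_normal((6, 15))
        ctrl = rng.standard_normal((6, 15))
        a = extrema_stats(rep, ctrl)
        b = extrema_stats(rep + shift, ctrl)
        assert np.allclose(a.rep_amplitude, b.rep_amplitude)


class TestGlm:
    def test_responsive_voxels_have_large_t_nonresponsive_small(
        self, default_gt, block_design
    ):
        run = simulate_repetition_run(
            default_gt, block_design, noise_sd=0.01, seed=0, global_noise_sd=0.0
        )
        tmap = glm_sound_vs_rest(run, block_design)
        assert np.median(tmap[default_gt.responsive]) > 50
        assert np.median(np.abs(tmap[~default_gt.responsive])) < 3

    def test_t_matches_closed_form_regression_oracle(self, default_gt, block_design):
        import statsmodels.api as sm
        from tonorep.hrf import DEFAULT_HRF

        run = simulate_repetition_run(default_gt, block_design, seed=1)
        tmap = glm_sound_vs_rest(run, block_design)
        t_fine = np.arange(0.0, block_design.run_duration, 0.1)
        boxcar = np.zeros_like(t_fine)
        for b in block_design.blocks:
            boxcar[(t_fine >= b.onset) & (t_fine < b.onset + b.stimulation_duration)] = 1.0
        reg = DEFAULT_HRF.convolve(boxcar, 0.1)[
            np.round(np.arange(block_design.n_frames) * 2.0 / 0.1).astype(int)
        ]
        X = sm.add_constant(reg)
        for vox in [(10, 10, 0), (20, 5, 1), (0, 0, 0)]:
            fit = sm.OLS(run.data[vox], X).fit()
            assert np.isclose(tmap[vox], fit.tvalues[1], atol=1e-6)

    def test_all_rest_design_rejected(self, default_gt):
        design = make_block_design(1, tr=2.0)
        object.__setattr__(design.blocks[0], "stimulation_duration", 0.0)
        object.__setattr__(design.blocks[1], "stimulation_duration", 0.0)
        data = np.ones(default_gt.shape + (design.n_frames,))
        run = VolumeSeries(data=data, tr=2.0)
        with pytest.raises(ValueError, match="degenerate"):
            glm_sound_vs_rest(run, design)

    def test_null_simulation_controls_familywise_error(self):
        """Bonferroni over all voxels keeps the familywise error at or below 5%."""
        from scipy import stats

        design = make_block_design(4, tr=2.0)
        rng = np.random.default_rng(12)
        n_vox = 2000
        fw_hits = 0
        n_reps = 60
        for _ in range(n_reps):
            data = rng.standard_normal((n_vox, 1, 1, design.n_frames))
            run = VolumeSeries(data=data, tr=2.0)
            tmap = glm_sound_vs_rest(run, design)
            p = 2 * stats.t.sf(np.abs(tmap.ravel()), df=design.n_frames - 2)
            fw_hits += int((p < 0.05 / n_vox).any())
        # nominal familywise rate is ~0.05; allow Monte-Carlo slack
        assert fw_hits / n_reps <= 0.12
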