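"""Acoustic profiles and iterative REP/CTRL set matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tonorep import (
    AcousticProfile,
    SoundStimulus,
    acoustic_profile,
    compare_mean_spectra,
    compare_sets,
    make_sound_pool,
    select_matched_sets,
)
from tonorep.matching import N_ENVELOPE_POINTS, N_SAMPLES, N_SPECTRUM_BINS, CandidatePool
from tonorep.soundgen import SoundClassParams


def _tone(freq=1000.0, amp=0.9):
    t = np.arange(N_SAMPLES) / 44100.0
    return SoundStimulus(waveform=amp * np.sin(2 * np.pi * freq * t), identifier="tone")


class TestAcousticProfile:
    def test_generated_sounds_have_correct_length_and_ramps(self):
        pool = make_sound_pool(4, seed=0)
        for s in pool.sounds:
            assert s.waveform.size == 22050
            assert np.max(np.abs(s.waveform)) <= 0.9 + 1e-9
            # 50-ms ramps: the extreme samples are attenuated
            assert np.max(np.abs(s.waveform[:20])) < 0.1
            assert np.max(np.abs(s.waveform[-20:])) < 0.1

    def test_profile_dimensions(self):
        p = acoustic_profile(_tone())
        assert p.envelope.size == N_ENVELOPE_POINTS
        assert p.spectrum.size == N_SPECTRUM_BINS == 11025

    def test_pure_tone_concentrates_in_one_spectral_bin(self):
        p = acoustic_profile(_tone(1000.0))
        # bin k covers k * (44100/22050) = 2k Hz -> 1000 Hz near bin 500
        peak_bin = int(np.argmax(p.spectrum)) + 1  # +1: DC bin dropped
        assert abs(peak_bin * 2.0 - 1000.0) <= 4.0
        assert p.spectrum.max() > 100 * np.median(p.spectrum)

    def test_silence_gives_zero_envelope_and_spectrum(self):
        p = acoustic_profile(SoundStimulus(waveform=np.zeros(N_SAMPLES), identifier="sil"))
        assert np.all(p.envelope == 0) and np.all(p.spectrum == 0)

    def test_white_noise_spectrum_flat_across_bands(self):
        """Mean white-noise bin magnitudes vary by <20% across frequency bands."""
        rng = np.random.default_rng(0)
        spectra = []
        for _ in range(100):
            x = rng.standard_normal(N_SAMPLES)
            x = 0.9 * x / np.max(np.abs(x))
            spectra.append(acoustic_profile(SoundStimulus(x, "n")).spectrum)
        band_means = np.mean(spectra, axis=0).reshape(25, 441).mean(axis=1)
        cv = band_means.std() / band_means.mean()
        assert cv < 0.2


class TestCompareSets:
    def test_identical_sets_have_zero_significant_fraction(self):
        pool = make_sound_pool(8, seed=1)
        profs = [acoustic_profile(s) for s in pool.sounds]
        res = compare_sets(profs, list(profs))
        assert res.fraction == 0.0

    def test_comparison_is_symmetric(self):
        pool = make_sound_pool(12, seed=2)
        profs = [acoustic_profile(s) for s in pool.sounds]
        a, b = profs[:6], profs[6:]
        r1, r2 = compare_sets(a, b), compare_sets(b, a)
        assert np.allclose(r1.envelope_p, r2.envelope_p)
        assert np.allclose(r1.spectrum_p, r2.spectrum_p)

    def test_large_envelope_shift_flags_most_envelope_points(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.standard_normal((8, N_ENVELOPE_POINTS))) + 1.0
        spec = np.abs(rng.standard_normal((8, N_SPECTRUM_BINS)))
        a = [AcousticProfile(e, s) for e, s in zip(base, spec)]
        pooled_sd = base.std(axis=0).mean()
        b = [AcousticProfile(e + 10 * pooled_sd, s) for e, s in zip(base, spec)]
        res = compare_sets(a, b)
        assert res.envelope_fraction > 0.9

    def test_null_rejection_rate_is_calibrated(self):
        """Per-point type-I error at alpha=0.05 in [0.03, 0.07] over 200 draws."""
        rng = np.random.default_rng(4)
        rates = []
        for _ in range(200):
            env = 1.0 + 0.1 * rng.standard_normal((16, 50))
            spec = 1.0 + 0.1 * rng.standard_normal((16, N_SPECTRUM_BINS))
            a = [AcousticProfile(e, s) for e, s in zip(env[:8], spec[:8])]
            b = [AcousticProfile(e, s) for e, s in zip(env[8:], spec[8:])]
            res = compare_sets(a, b)
            rates.append(
                ((res.envelope_p < 0.05).sum() + (res.spectrum_p < 0.05).sum())
                / (res.envelope_p.size + res.spectrum_p.size)
            )
        assert 0.03 < np.mean(rates) < 0.07

    def test_both_sets_constant_at_a_point_gives_p_one(self):
        env = np.ones((4, N_ENVELOPE_POINTS))
        spec = np.ones((4, N_SPECTRUM_BINS))
        a = [AcousticProfile(e, s) for e, s in zip(env, spec)]
        res = compare_sets(a, a)
        assert np.all(res.envelope_p == 1.0)


class TestSelectMatchedSets:
    def test_accepted_sets_satisfy_their_own_predicate(self, small_pool):
        ms = select_matched_sets(small_pool, n_rep=16, n_ctrl=32, max_iter=200,
                                 threshold=0.02, seed=0)
        if ms.accepted:
            assert ms.result.fraction < 0.02
            assert not set(ms.rep_ids) & set(ms.ctrl_ids)
        else:
            assert ms.best_fraction >= 0.02

    def test_same_pool_and_seed_reproduce_selection(self, small_pool):
        a = select_matched_sets(small_pool, 8, 16, max_iter=50, seed=7)
        b = select_matched_sets(small_pool, 8, 16, max_iter=50, seed=7)
        assert a.rep_ids == b.rep_ids and a.ctrl_ids == b.ctrl_ids

    def test_disjoint_band_populations_cannot_be_matched(self):
        low = make_sound_pool(20, SoundClassParams(freq_range=(150.0, 300.0)),
                              seed=0, categories=None)
        high = make_sound_pool(20, SoundClassParams(freq_range=(4000.0, 8000.0)),
                               seed=1, categories=None)
        for i, s in enumerate(high.sounds):
            s.identifier = f"hi{i:03d}"
        profs_low = [acoustic_profile(s) for s in low.sounds]
        profs_high = [acoustic_profile(s) for s in high.sounds]
        # forcing opposite sets: the spectral difference alone exceeds the 1% bar
        res = compare_sets(profs_low, profs_high)
        assert res.fraction > 0.01
        pool = CandidatePool(sounds=low.sounds + high.sounds)
        ms = select_matched_sets(pool, n_rep=20, n_ctrl=20, max_iter=20,
                                 threshold=1e-4, seed=0)
        assert ms.status == "failed"
        assert ms.best_fraction >= 1e-4

    def test_pool_too_small_rejected(self, small_pool):
        with pytest.raises(ValueError, match="pool too small"):
            select_matched_sets(small_pool, n_rep=40, n_ctrl=40)


class TestCompareMeanSpectra:
    def test_identical_conditions_give_no_significant_bins(self):
        pool = make_sound_pool(6, seed=6)
        profs = [acoustic_profile(s) for s in pool.sounds]
        res = compare_mean_spectra(profs, list(profs))
        assert res.n_significant == 0
        assert res.fraction == 0.0

    def test_reported_fraction_is_count_over_bins(self):
        rng = np.random.default_rng(7)
        spec = 1.0 + 0.05 * rng.standard_normal((12, N_SPECTRUM_BINS))
        env = np.ones((12, N_ENVELOPE_POINTS))
        a = [AcousticProfile(env[i], spec[i]) for i in range(6)]
        b = [AcousticProfile(env[i], spec[i]) for i in range(6, 12)]
        res = compare_mean_spectra(a, b)
        assert np.isclose(res.fraction, res.n_significant / 11025)

    def test_single_band_difference_confined_to_that_band(self):
        rng = np.random.default_rng(8)
        spec = 1.0 + 0.05 * rng.standard_normal((16, N_SPECTRUM_BINS))
        env = np.ones((16, N_ENVELOPE_POINTS))
        band = slice(2000, 2100)
        spec[8:, band] += 5.0
        a = [AcousticProfile(env[i], spec[i]) for i in range(8)]
        b = [AcousticProfile(env[i], spec[i]) for i in range(8, 16)]
        res = compare_mean_spectra(a, b)
        sig = res.p_values < 0.05
        assert sig[band].all()
        outside_rate = sig[~np.isin(np.arange(N_SPECTRUM_BINS), np.arange(2000, 2100))].mean()
        assert outside_rate < 0.08

    def test_unequal_spectral_lengths_rejected(self):
        from types import SimpleNamespace

        a = [AcousticProfile(np.ones(10), np.ones(N_SPECTRUM_BINS))] * 2
        short = [SimpleNamespace(spectrum=np.ones(100))] * 2
        with pytest.raises(ValueError, match="lengths"):
            compare_mean_spectra(a, short)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_matched_output_never_mixes_rep_into_ctrl(seed):
    pool = make_sound_pool(20, seed=99)
    ms = select_matched_sets(pool, 4, 8, max_iter=5, threshold=0.5, seed=seed)
    assert not set(ms.rep_ids) & set(ms.ctrl_ids)
    assert len(ms.rep_ids) == 4 and len(ms.ctrl_ids) == 8
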