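"""Profile engine: directional passes, min-combination, smoothing, sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from infoprofile import (
    InformationProfile,
    ProfileConfig,
    blackman_taps,
    combine_min,
    conditional_profile,
    profile,
    profile_one_direction,
    smooth,
    subsample,
    train_models,
)
from _reference import naive_profile, random_dna

SMALL = ProfileConfig(depths=(1, 2, 4), window=1)


def make_profile(values, mask=None, seq_id="s"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isnan(values)
    return InformationProfile(seq_id, values, np.asarray(mask, bool))


class TestSinglePass:
    def test_acgt_fresh_models_all_uniform(self):
        p = profile_one_direction("ACGT", ProfileConfig())
        np.testing.assert_allclose(p.values, 2.0, atol=1e-12)

    def test_homopolymer_becomes_predictable(self):
        p = profile_one_direction("A" * 10_000, ProfileConfig())
        assert p.values[-1000:].mean() < 0.1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            profile_one_direction("", ProfileConfig())

    @pytest.mark.parametrize("gamma", [1.0, 0.9])
    def test_streaming_matches_naive_reference(self, gamma):
        """Engine output equals the explicit-loop reference to 1e-9 bits."""
        cfg = ProfileConfig(depths=(1, 2, 3, 6), alphas={6: 1 / 16},
                            gamma=gamma, window=1)
        seq = random_dna(1000, seed=3)
        got = profile_one_direction(seq, cfg).values
        want = naive_profile(seq, cfg.depths,
                             [cfg.alphas[d] for d in cfg.depths], gamma)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_masked_positions_and_context_reset(self):
        """Ns are NaN in the output and the reference treats them the same."""
        seq = random_dna(300, seed=5) + "NNNN" + random_dna(300, seed=6)
        cfg = ProfileConfig(depths=(2, 4), gamma=0.95, window=1)
        got = profile_one_direction(seq, cfg)
        want = naive_profile(seq, cfg.depths,
                             [cfg.alphas[d] for d in cfg.depths], 0.95)
        assert not got.mask[300:304].any()
        assert np.isnan(got.values[300:304]).all()
        np.testing.assert_allclose(got.values, want, atol=1e-9)

    def test_reversal_consistency(self):
        """Reversed-direction profile of S = direct profile of reverse(S), flipped."""
        seq = random_dna(800, seed=11)
        cfg = ProfileConfig(depths=(2, 4, 8), window=1)
        rev_pass = profile_one_direction(seq, cfg, reverse=True)
        oracle = profile_one_direction(seq[::-1], cfg)
        np.testing.assert_array_equal(rev_pass.values, oracle.values[::-1])

    def test_revcomp_policy(self):
        comp = str.maketrans("ACGT", "TGCA")
        seq = random_dna(500, seed=13)
        cfg = ProfileConfig(depths=(2, 4), window=1, revcomp=True)
        rev_pass = profile_one_direction(seq, cfg, reverse=True)
        oracle = profile_one_direction(seq.translate(comp)[::-1], cfg)
        np.testing.assert_array_equal(rev_pass.values, oracle.values[::-1])

    def test_self_trained_statistics_no_worse_than_fresh(self):
        seq = random_dna(50_000, seed=17)
        cfg = ProfileConfig(window=1)
        fresh = profile_one_direction(seq, cfg)
        trained = train_models(seq, cfg)
        pretrained = profile_one_direction(seq, cfg, pretrained=trained)
        assert pretrained.mean() <= fresh.mean()

    def test_pretrained_depth_mismatch_rejected(self):
        models = train_models("ACGTACGTAC", SMALL)
        with pytest.raises(ValueError):
            profile_one_direction("ACGT", ProfileConfig(depths=(2, 4)),
                                  pretrained=models)


class TestCombineMin:
    def test_elementwise_minimum(self):
        out = combine_min(make_profile([1.0, 2.0]), make_profile([1.5, 0.5]))
        assert list(out.values) == [1.0, 0.5]

    def test_idempotent_on_identical_inputs(self):
        p = make_profile([0.3, 1.7, 2.0])
        out = combine_min(p, make_profile([0.3, 1.7, 2.0]))
        assert np.array_equal(out.values, p.values)

    def test_never_exceeds_either_input(self, rng):
        a = make_profile(rng.uniform(0, 2, 100_000))
        b = make_profile(rng.uniform(0, 2, 100_000))
        out = combine_min(a, b)
        assert (out.values <= a.values).all() and (out.values <= b.values).all()

    def test_mask_is_conjunction(self):
        a = make_profile([1.0, np.nan, 2.0], mask=[True, False, True])
        b = make_profile([1.0, 1.0, np.nan], mask=[True, True, False])
        out = combine_min(a, b)
        assert list(out.mask) == [True, False, False]
        assert np.isnan(out.values[1]) and np.isnan(out.values[2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_min(make_profile([1.0]), make_profile([1.0, 2.0]))


class TestSmoothing:
    def test_constant_preserved(self):
        p = make_profile(np.full(500, 1.37))
        out = smooth(p, 101)
        np.testing.assert_allclose(out.values, 1.37, rtol=1e-12)

    def test_window_one_is_identity(self, rng):
        p = make_profile(rng.uniform(0, 2, 200))
        assert np.array_equal(smooth(p, 1).values, p.values)

    def test_impulse_response_is_normalized_blackman(self):
        sig = np.zeros(11)
        sig[5] = 1.0
        out = smooth(make_profile(sig), 5)
        taps = blackman_taps(5)
        # interior placements see all 5 taps, each normalized by the tap sum
        np.testing.assert_allclose(out.values[3:8], taps / taps.sum(), atol=1e-15)

    def test_blackman_endpoints_are_zero(self):
        for m in (5, 51, 1001):
            taps = blackman_taps(m)
            assert taps[0] == 0.0 and taps[-1] == 0.0
            assert (taps[1:-1] > 0).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(make_profile([1.0, 2.0]), 4)
        with pytest.raises(ValueError):
            ProfileConfig(window=100)

    @given(seed=st.integers(0, 50))
    def test_output_within_input_range(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 2, 400)
        out = smooth(make_profile(vals), 31).values
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12

    def test_masked_positions_excluded_and_preserved(self):
        vals = np.full(300, 0.8)
        mask = np.ones(300, bool)
        vals[100:120] = np.nan
        mask[100:120] = False
        out = smooth(make_profile(vals, mask), 41)
        assert np.isnan(out.values[100:120]).all()
        # constant input stays constant even next to the gap
        np.testing.assert_allclose(out.values[out.mask], 0.8, rtol=1e-12)


class TestSubsample:
    def test_fixed_grid(self):
        p = make_profile(np.arange(100, dtype=float))
        s = subsample(p, 20)
        assert list(s.positions) == [1, 21, 41, 61, 81]
        assert list(s.values) == [0.0, 20.0, 40.0, 60.0, 80.0]

    def test_step_one_round_trips(self, rng):
        vals = rng.uniform(0, 2, 57)
        s = subsample(make_profile(vals), 1)
        assert np.array_equal(s.values, vals)
        assert s.positions[0] == 1 and s.positions[-1] == 57

    def test_masked_samples_are_nan(self):
        vals = np.array([1.0, np.nan, 2.0, 0.5])
        s = subsample(make_profile(vals), 2)
        assert list(s.positions) == [1, 3]
        assert s.values[0] == 1.0 and s.values[1] == 2.0
        s1 = subsample(make_profile(vals), 1)
        assert np.isnan(s1.values[1])


class TestFullPipeline:
    def test_min_combined_bounded_by_directional_passes(self):
        seq = random_dna(3000, seed=23)
        cfg = ProfileConfig(depths=(2, 4, 8), window=1)
        combined = profile(seq, cfg)
        direct = profile_one_direction(seq, cfg)
        rev = profile_one_direction(seq, cfg, reverse=True)
        assert (combined.values <= direct.values + 1e-15).all()
        assert (combined.values <= rev.values + 1e-15).all()

    def test_direction_policies(self):
        seq = random_dna(500, seed=29)
        cfg = ProfileConfig(depths=(2, 4), window=1, direction="direct")
        only_direct = profile(seq, cfg)
        oracle = profile_one_direction(seq, cfg)
        assert np.array_equal(only_direct.values, oracle.values)

    def test_duplicated_segment_is_low_information(self):
        """A planted duplication drops below the background mean."""
        rng = np.random.default_rng(31)
        bg = "".join("ACGT"[c] for c in rng.integers(0, 4, 30_000))
        seq = bg[:20_000] + bg[5_000:10_000] + bg[20_000:25_000]
        prof = profile(seq, ProfileConfig(window=501))
        inside = prof.values[20_000:25_000].mean()
        outside = np.concatenate(
            [prof.values[:20_000], prof.values[25_000:]]).mean()
        assert inside < outside

    def test_total_stored_contexts_bounded(self):
        L = 20_000
        cfg = ProfileConfig()
        models = train_models(random_dna(L, seed=37), cfg)
        for m in models:
            assert m.n_contexts <= min(L, 4**m.order)
        total = sum(m.n_contexts for m in models)
        assert total <= sum(min(L, 4**d) for d in cfg.depths)


class TestConditionalProfile:
    def test_divergent_symbol_in_trained_context_is_surprising(self):
        """A base contradicting heavily trained statistics costs far more
        than 2 bits; once the context itself is unseen the estimate falls
        back to uniform (exactly 2 bits)."""
        cfg = ProfileConfig(depths=(2, 4), window=1, direction="direct")
        cond = conditional_profile("A" * 2000, "A" * 20 + "C" * 30, cfg)
        first_c = 20
        assert cond.values[first_c] > 10.0  # trained context, wrong symbol
        assert np.allclose(cond.values[-10:], 2.0)  # unseen contexts

    def test_training_on_itself_beats_fresh_statistics(self):
        seq = random_dna(50_000, seed=41)
        cfg = ProfileConfig(window=1)
        cond = conditional_profile(seq, seq, cfg)
        fresh = profile(seq, cfg)
        assert cond.mean() < fresh.mean()

    def test_planted_substitution_is_the_global_peak(self):
        rng = np.random.default_rng(43)
        ref = "".join("ACGT"[c] for c in rng.integers(0, 4, 20_000))
        sub = "".join("ACGT"[c] for c in rng.integers(0, 4, 2_000))
        target = ref[:9_000] + sub + ref[11_000:]
        cond = conditional_profile(ref, target, ProfileConfig(window=501))
        peak = int(np.nanargmax(cond.values))
        assert 9_000 <= peak < 11_000

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            conditional_profile("", "ACGT", SMALL)


class TestConfig:
    def test_default_parameter_set(self):
        cfg = ProfileConfig()
        assert cfg.depths == (2, 4, 6, 8, 10, 12, 14, 16)
        assert cfg.alphas[12] == 1.0 and cfg.alphas[14] == 1 / 16
        assert cfg.window == 1001 and cfg.sample_step == 20
        assert cfg.direction == "min"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"depths": (4, 2)},
            {"depths": ()},
            {"gamma": 0.0},
            {"gamma": 1.2},
            {"window": 10},
            {"sample_step": 0},
            {"direction": "sideways"},
            {"alphas": {3: 1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProfileConfig(**kwargs)
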