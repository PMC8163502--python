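"""Permutation entropy and Lempel-Ziv complexity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from anesrecov.complexity import (
    LZCConfig,
    PEConfig,
    binarize_multichannel,
    lz76_word_count,
    lz76_word_count_slow,
    lzc_by_epoch,
    lzc_window,
    ordinal_pattern_distribution,
    pe_by_epoch,
    permutation_entropy_window,
    regional_pe,
)
from anesrecov.eeg_preprocess import FRONTAL_CHANNELS, STANDARD_21
from anesrecov.errors import LengthError, MontageError

TOY = (4, 7, 9, 10, 6, 11, 3)


class TestOrdinalPatterns:
    def test_toy_series_pair_distribution(self):
        # 6 consecutive pairs: 4 ascending, 2 descending (hand enumeration)
        p = ordinal_pattern_distribution(TOY, dE=2, tau=1)
        np.testing.assert_allclose(p, [4 / 6, 2 / 6])

    def test_monotone_series_single_pattern(self):
        p = ordinal_pattern_distribution(np.arange(100.0), dE=4, tau=3)
        assert p.max() == 1.0 and p.sum() == 1.0

    def test_at_most_factorial_patterns(self, rng):
        p = ordinal_pattern_distribution(rng.standard_normal(500), dE=3, tau=2)
        assert p.size == math.factorial(3)
        assert (p > 0).sum() <= math.factorial(3)
        assert p.sum() == pytest.approx(1.0)

    def test_too_short_input_rejected(self):
        with pytest.raises(LengthError):
            ordinal_pattern_distribution([1.0, 2.0], dE=5, tau=4)

    def test_tie_break_is_first_occurrence(self):
        # equal values rank by order of occurrence -> ascending pattern
        p = ordinal_pattern_distribution([1.0, 1.0, 1.0], dE=2, tau=1)
        np.testing.assert_allclose(p, [1.0, 0.0])


class TestPermutationEntropy:
    def test_monotone_series_zero_entropy(self):
        assert permutation_entropy_window(np.arange(100.0), PEConfig()) == 0.0

    def test_toy_series_entropy_bits(self):
        cfg = PEConfig(dE=2, tau=1, normalize=False)
        h = permutation_entropy_window(TOY, cfg)
        assert h == pytest.approx(0.9182958340544896, abs=1e-12)

    def test_iid_noise_near_maximal(self):
        for seed in (0, 1, 2):
            x = np.random.default_rng(seed).random(100_000)
            assert permutation_entropy_window(x, PEConfig()) >= 0.99

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_increasing_transform(self, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        cfg = PEConfig(dE=3, tau=2)
        a = permutation_entropy_window(x, cfg)
        b = permutation_entropy_window(np.exp(x), cfg)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0


class TestEpochPE:
    def test_two_minute_epoch_gives_twelve_windows(self, make_epoch, rng):
        ep = make_epoch(rng.standard_normal((2, 30000)))
        w = 2500
        manual = np.mean(
            [
                permutation_entropy_window(ep.data[0, i * w : (i + 1) * w], PEConfig())
                for i in range(12)
            ]
        )
        assert pe_by_epoch(ep, PEConfig()).iloc[0] == pytest.approx(manual, abs=1e-12)

    def test_stationary_epoch_matches_single_window(self, make_epoch, rng):
        ep = make_epoch(rng.standard_normal((1, 30000)))
        whole = permutation_entropy_window(ep.data[0, :2500], PEConfig())
        assert pe_by_epoch(ep, PEConfig()).iloc[0] == pytest.approx(whole, abs=0.01)

    def test_narrowband_lower_than_broadband(self, make_epoch):
        fs = 250.0
        sos_lo = signal.butter(4, (0.5, 4.0), "bandpass", fs=fs, output="sos")
        sos_hi = signal.butter(4, (0.5, 30.0), "bandpass", fs=fs, output="sos")
        lo, hi = [], []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(6000)[None, :]
            lo.append(pe_by_epoch(make_epoch(signal.sosfilt(sos_lo, x)), PEConfig()).iloc[0])
            hi.append(pe_by_epoch(make_epoch(signal.sosfilt(sos_hi, x)), PEConfig()).iloc[0])
        assert np.mean(lo) < np.mean(hi)


class TestRegionalPE:
    def test_default_frontal_set(self):
        assert set(FRONTAL_CHANNELS) == {"Fp1", "Fp2", "Fpz", "F3", "F4", "Fz"}

    def test_constant_field(self):
        per_ch = {ch: 0.7 for ch in STANDARD_21}
        assert regional_pe(per_ch) == (pytest.approx(0.7), pytest.approx(0.7))

    def test_frontal_mean(self):
        per_ch = {ch: 0.9 for ch in STANDARD_21}
        for ch, v in zip(("Fp1", "Fp2", "Fpz"), (0.6, 0.6, 0.6)):
            per_ch[ch] = v
        f, _ = regional_pe(per_ch)
        assert f == pytest.approx(0.75)

    def test_missing_channel_named(self):
        per_ch = {ch: 0.7 for ch in STANDARD_21 if ch != "Oz"}
        with pytest.raises(MontageError, match="Oz"):
            regional_pe(per_ch)


class TestLZ76:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("0001101001000101", 6),  # exhaustive history 0|001|10|100|1000|101
            ("0000000000", 2),  # first '0', then one reproducible run
            ("01", 2),
            ("0", 1),
        ],
    )
    def test_known_parsings(self, s, expected):
        bits = [int(c) for c in s]
        assert lz76_word_count(bits) == expected
        assert lz76_word_count_slow(bits) == expected

    def test_fast_route_matches_bruteforce_on_random_strings(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            bits = rng.integers(0, 2, n)
            assert lz76_word_count(bits) == lz76_word_count_slow(bits)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lz76_word_count([])


class TestBinarize:
    def test_shape_and_alphabet(self, rng):
        b = binarize_multichannel(rng.standard_normal((21, 1000)))
        assert b.shape == (21, 1000)
        assert set(np.unique(b)) <= {0, 1}

    def test_tie_convention_on_constant_amplitude(self):
        # exactly constant amplitude: the strict '>' comparison yields all-zero
        # bits, 'greater_equal' all-one (documents the tie convention)
        w = np.zeros((21, 1000))
        assert binarize_multichannel(w, LZCConfig(comparison="greater")).sum() == 0
        assert binarize_multichannel(
            w, LZCConfig(comparison="greater_equal")
        ).min() == 1

    def test_gaussian_channels_near_balanced(self):
        for seed in range(5):
            w = np.random.default_rng(seed).standard_normal((21, 1000))
            frac = binarize_multichannel(w).mean()
            assert 0.3 < frac < 0.7


class TestLZCWindow:
    def test_degenerate_allzero_flagged(self):
        res = lzc_window(np.zeros((21, 1000)))
        assert res.degenerate
        assert res.value == 0.0

    def test_iid_matrix_normalizes_to_one(self):
        vals = [
            lzc_window(np.random.default_rng(s).standard_normal((21, 1000)),
                       LZCConfig(), seed=s).value
            for s in range(10)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)
        assert all(abs(v - 1.0) < 0.05 for v in vals)

    def test_correlated_blocks_lower_than_independent(self):
        def blocks(seed):
            r = np.random.default_rng(seed)
            a, b = r.standard_normal((2, 1000))
            return np.vstack(
                [a + 0.1 * r.standard_normal((11, 1000)),
                 b + 0.1 * r.standard_normal((10, 1000))]
            )

        corr = np.mean([lzc_window(blocks(s), seed=s).value for s in range(10)])
        ind = np.mean(
            [
                lzc_window(np.random.default_rng(s).standard_normal((21, 1000)),
                           seed=s).value
                for s in range(10)
            ]
        )
        assert corr < ind


class TestLZCEpoch:
    def test_same_seed_reproducible_different_seed_close(self, make_epoch, rng):
        ep = make_epoch(rng.standard_normal((21, 30000)))
        a = lzc_by_epoch(ep, LZCConfig(rng_seed=1))
        b = lzc_by_epoch(ep, LZCConfig(rng_seed=1))
        c = lzc_by_epoch(ep, LZCConfig(rng_seed=2))
        assert a == b
        assert abs(a - c) / a < 0.02

    def test_default_config_matches_study_settings(self):
        cfg = LZCConfig()
        assert cfg.window_s == 4.0
        assert cfg.n_surrogates == 50
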