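"""Epoch mixed models, associations, and design utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anesrecov.errors import ConstantInputError, DesignError, ParameterError
from anesrecov.neurophys_stats import (
    bonferroni_threshold,
    fit_epoch_lmm,
    pairwise_epoch_contrasts,
    power_unpaired_t,
    region_contrast_at,
    spearman_eeg_cognition,
)


def _balanced_table(rng, n_subj=20, states=("EC1", "LOC", "Maintenance"),
                    effects=(0.0, 0.0, 0.0), subj_sd=0.5, resid_sd=(0.2, 0.2, 0.2)):
    rows = []
    for s in range(n_subj):
        b = rng.normal(0.0, subj_sd)
        for st, eff, sd in zip(states, effects, resid_sd):
            rows.append((f"S{s:02d}", st, 0.8 + eff + b + rng.normal(0.0, sd)))
    return pd.DataFrame(rows, columns=["subject_id", "state", "value"])


class TestEpochLMM:
    def test_balanced_estimates_equal_mean_differences(self, rng):
        df = _balanced_table(rng, effects=(0.0, -0.1, -0.3))
        res = fit_epoch_lmm(df, "LZC")
        ct = pairwise_epoch_contrasts(res)
        means = df.groupby("state")["value"].mean()
        for _, row in ct.iterrows():
            expected = means[row["epoch_a"]] - means[row["epoch_b"]]
            assert row["estimate"] == pytest.approx(expected, abs=1e-6)

    def test_identical_observations_give_null_contrasts(self):
        df = pd.DataFrame(
            [(f"S{s}", st, 0.5) for s in range(6) for st in ("EC1", "LOC")],
            columns=["subject_id", "state", "value"],
        )
        res = fit_epoch_lmm(df, "LZC")
        ct = pairwise_epoch_contrasts(res)
        assert ct["estimate"].abs().max() == pytest.approx(0.0, abs=1e-9)
        assert (ct["p_bonferroni"] >= 1.0 - 1e-9).all()

    def test_heterogeneous_residual_sds_recovered(self):
        # median estimate over replicates lands within 30% of (0.5, 1.0, 2.0)
        est = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = _balanced_table(
                rng, n_subj=30, subj_sd=0.7, resid_sd=(0.5, 1.0, 2.0)
            )
            est.append(fit_epoch_lmm(df, "LZC").sigma_epoch.to_numpy())
        med = np.median(est, axis=0)
        assert np.all(np.abs(med - [0.5, 1.0, 2.0]) / [0.5, 1.0, 2.0] < 0.3)

    def test_two_epoch_model_matches_paired_difference(self, rng):
        df = _balanced_table(rng, states=("EC1", "LOC"), effects=(0.0, -0.2),
                             resid_sd=(0.3, 0.3))
        res = fit_epoch_lmm(df, "LZC")
        ct = pairwise_epoch_contrasts(res)
        wide = df.pivot(index="subject_id", columns="state", values="value")
        assert ct["estimate"].iloc[0] == pytest.approx(
            (wide["EC1"] - wide["LOC"]).mean(), abs=1e-6
        )

    def test_injected_maintenance_deficit_detected(self, rng):
        hits = 0
        for rep in range(5):
            df = _balanced_table(
                np.random.default_rng(rep),
                states=tuple(f"E{i}" for i in range(1, 11)),
                effects=(0.0,) * 2 + (-0.6,) + (0.0,) * 7,  # 3 residual SDs
                resid_sd=(0.2,) * 10, n_subj=30,
            )
            ct = pairwise_epoch_contrasts(fit_epoch_lmm(df, "LZC"))
            row = ct[(ct.epoch_a == "E1") & (ct.epoch_b == "E3")]
            hits += (row["p_bonferroni"] < 0.05).iloc[0]
        assert hits == 5

    def test_null_familywise_error_controlled(self):
        # 10 epochs, 45 Bonferroni-corrected pairs, no true effect
        fw = 0
        n_rep = 100
        for rep in range(n_rep):
            df = _balanced_table(
                np.random.default_rng(1000 + rep),
                states=tuple(f"E{i}" for i in range(10)),
                effects=(0.0,) * 10, resid_sd=(0.2,) * 10, n_subj=12,
            )
            ct = pairwise_epoch_contrasts(fit_epoch_lmm(df, "LZC"))
            fw += (ct["p_bonferroni"] < 0.05).any()
        assert fw / n_rep <= 0.09  # 0.05 target + binomial slack

    def test_region_interaction_model(self, rng):
        rows = []
        for s in range(15):
            b = rng.normal(0, 0.3)
            for st in ("EC1", "EC2"):
                for reg, off in (("frontal", 0.05 if st == "EC2" else 0.0),
                                 ("posterior", 0.0)):
                    rows.append((f"S{s}", st, reg, 0.9 + off + b + rng.normal(0, 0.02)))
        df = pd.DataFrame(rows, columns=["subject_id", "state", "region", "value"])
        res = fit_epoch_lmm(df, "PE")
        rc = region_contrast_at(res, "EC2")
        assert rc["estimate"] == pytest.approx(0.05, abs=0.02)
        assert rc["p"] < 0.05

    def test_unknown_epoch_label_rejected(self, rng):
        res = fit_epoch_lmm(_balanced_table(rng), "LZC")
        with pytest.raises(KeyError):
            pairwise_epoch_contrasts(res, pairs=[("EC1", "nope")])

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame(
            [("S1", "A", 1.0), ("S1", "B", 1.0), ("S2", "A", 0.9), ("S2", "B", 1.1)],
            columns=["subject_id", "state", "value"],
        )
        with pytest.raises(DesignError):
            fit_epoch_lmm(df, "LZC")


class TestBonferroni:
    def test_six_tests_level(self):
        assert bonferroni_threshold(0.05, 6) == pytest.approx(0.0083333333)
        assert round(bonferroni_threshold(0.05, 6), 4) == 0.0083

    def test_identity_and_monotonicity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        levels = [bonferroni_threshold(0.05, k) for k in range(1, 10)]
        assert all(a > b for a, b in zip(levels, levels[1:]))

    def test_invalid_family_size(self):
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.05, 0)

    def test_corrected_p_definition(self, rng):
        res = fit_epoch_lmm(_balanced_table(rng), "LZC")
        ct = pairwise_epoch_contrasts(res)
        np.testing.assert_allclose(
            ct["p_bonferroni"], np.minimum(1.0, len(ct) * ct["p_raw"])
        )


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        r, _ = spearman_eeg_cognition(x, [10, 20, 30, 40, 50, 60])
        assert r == 1.0
        r, _ = spearman_eeg_cognition(x, [60, 50, 40, 30, 20, 10])
        assert r == -1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman_eeg_cognition([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r1, p1 = spearman_eeg_cognition(x, y)
        r2, p2 = spearman_eeg_cognition(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_permutation_small_n(self, rng):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        r, p = spearman_eeg_cognition(x, y)
        # exhaustive permutation reference
        import itertools

        vals = [
            stats.spearmanr(x, perm).statistic
            for perm in itertools.permutations(y)
        ]
        p_ref = np.mean(np.abs(vals) >= abs(r) - 1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


class TestPower:
    def test_design_scenarios(self):
        assert power_unpaired_t(30.0, 40.0, 30, 0.05) > 0.80
        assert power_unpaired_t(90.0, 20.0, 30, 0.001) > 0.99

    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.10):
            assert power_unpaired_t(0.0, 12.0, 30, alpha) == pytest.approx(alpha)

    def test_monotone_in_diff_n_alpha(self):
        p = [power_unpaired_t(d, 40.0, 30) for d in (10, 20, 30, 40)]
        assert all(a < b for a, b in zip(p, p[1:]))
        p = [power_unpaired_t(30.0, 40.0, n) for n in (10, 20, 30, 60)]
        assert all(a < b for a, b in zip(p, p[1:]))
        p = [power_unpaired_t(30.0, 40.0, 30, a) for a in (0.01, 0.05, 0.1)]
        assert all(a < b for a, b in zip(p, p[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            power_unpaired_t(30.0, 0.0, 30)
        with pytest.raises(ParameterError):
            power_unpaired_t(30.0, 40.0, 1)
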