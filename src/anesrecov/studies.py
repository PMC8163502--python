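"""Self-contained validation studies run by the acceptance suite.

Each study regenerates its synthetic inputs from a seed, runs the relevant
pipeline stages, and returns the measured quantities. Problem sizes are the
study-scale defaults (30 subjects per arm for the cognitive model, 20
subjects for the EEG pattern suite, reduced 1,000-draw posteriors for
replicated fits).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import complexity as cx
from . import neurophys_stats as ns
from . import recovery_model as rm
from . import synthetic_data as syn
from ._lz76 import lz76_word_count, lz76_word_count_slow
from .eeg_preprocess import extract_state_epochs, preprocess_eeg


# ---------------------------------------------------------------------------
# Closed-form / oracle checks
# ---------------------------------------------------------------------------

def power_scenarios() -> dict:
    """The two sample-size scenarios of the study design: conservative
    (30-min recovery-time difference, SD 40 min) and liberal (90/20),
    n = 30 per arm."""
    return {
        "power_conservative": ns.power_unpaired_t(30.0, 40.0, 30, 0.05),
        "power_liberal": ns.power_unpaired_t(90.0, 20.0, 30, 0.001),
        "bonferroni_level_6_tests": ns.bonferroni_threshold(0.05, 6),
    }


def lz76_oracle_check(max_len: int = 12) -> dict:
    """Exhaustive agreement between the suffix-array LZ76 parser and the
    brute-force definition on all binary strings of length <= max_len."""
    n_total = 0
    n_agree = 0
    for L in range(1, max_len + 1):
        for bits in itertools.product((0, 1), repeat=L):
            n_total += 1
            n_agree += lz76_word_count(bits) == lz76_word_count_slow(bits)
    return {"n_strings": n_total, "agreement_fraction": n_agree / n_total}


def pe_toy_check() -> dict:
    """Ordinal-pattern distribution of the 7-point toy series by direct
    enumeration (6 consecutive pairs: 4 ascending, 2 descending)."""
    x = (4, 7, 9, 10, 6, 11, 3)
    p = cx.ordinal_pattern_distribution(x, dE=2, tau=1)
    h = cx.permutation_entropy_window(x, cx.PEConfig(dE=2, tau=1, normalize=False))
    return {"p_ascending": float(p[0]), "entropy_bits": h}


# ---------------------------------------------------------------------------
# Parameter-recovery study (recovery model)
# ---------------------------------------------------------------------------

def recovery_parameter_recovery_study(
    seed: int,
    n_replicates: int = 20,
    draws: int = 1000,
    n_per_arm: int = 30,
    tolerance_h: float = 0.25,
) -> dict:
    """Replicated fit of the damped-exponential model on synthetic data.

    Two tests with true recovery times 0.5 h and 1.5 h (a configured 1-hour
    gap) are fitted per replicate; the study reports how often the posterior
    median recovery time lands within ``tolerance_h`` of truth and how often
    the 30-minute-gap posterior probability reaches 0.9.
    """
    tests = (("AM", "accuracy"), ("DSST", "accuracy"))
    base = syn.SyntheticCognitiveSpec()
    spec = syn.SyntheticCognitiveSpec(
        n_per_arm=n_per_arm,
        truths={k: base.truths[k] for k in tests},
    )
    truths = {k: spec.truths[k].recovery_time for k in tests}
    within = {k: 0 for k in tests}
    gap_hits = 0
    gap_probs = []
    medians = {k: [] for k in tests}
    for rep in range(n_replicates):
        records, _ = syn.gen_synthetic_cognitive(spec, seed * 10_000 + rep)
        fits = {}
        for i, key in enumerate(tests):
            cfg = rm.BayesConfig(
                draws=draws, seed=(seed * 100 + rep) * 10 + i
            )
            fits[key] = rm.fit_damped_exponential(records, key[0], key[1], cfg)
            T, rec_mask = fits[key].recovery_time_draws()
            med = float(np.nanmedian(T)) if rec_mask.any() else np.nan
            medians[key].append(med)
            if np.isfinite(med) and abs(med - truths[key]) <= tolerance_h:
                within[key] += 1
        cmp_ = rm.posterior_recovery_comparison(fits[tests[0]], fits[tests[1]])
        gap_probs.append(cmp_.p_diff_gt_threshold)
        gap_hits += cmp_.p_diff_gt_threshold >= 0.9
    n_fits = n_replicates * len(tests)
    return {
        "n_replicates": n_replicates,
        "true_T_h": {"_".join(k): truths[k] for k in tests},
        "median_T_h": {"_".join(k): float(np.nanmean(medians[k])) for k in tests},
        "frac_T_within_tolerance": sum(within.values()) / n_fits,
        "frac_gap_prob_ge_090": gap_hits / n_replicates,
        "mean_gap_prob": float(np.mean(gap_probs)),
    }


# ---------------------------------------------------------------------------
# Paper-pattern suite (EEG complexity across states)
# ---------------------------------------------------------------------------

_LZC_STATES = ("EC1", "Maintenance", "PreROC")
_PE_STATES = ("EC1", "Maintenance", "PreROC", "EC2")


def paper_pattern_study(seed: int, n_subjects: int = 20) -> dict:
    """State-dependence of PE and LZC on generator-default synthetic EEG.

    Measures, per anesthesia subject, frontal PE for EC1 / Maintenance /
    PreROC / EC2 (plus posterior PE at EC2) and epoch LZC for EC1 /
    Maintenance / PreROC; and, for controls, frontal/posterior PE across
    EC1-EC7 with the epoch mixed model and Bonferroni pairwise contrasts.
    """
    spec = syn.SyntheticEEGSpec(n_subjects=n_subjects)
    pe_cfg = cx.PEConfig()
    frontal_pe: dict[str, list[float]] = {s: [] for s in _PE_STATES}
    posterior_pe: dict[str, list[float]] = {s: [] for s in _PE_STATES}
    lzc: dict[str, list[float]] = {s: [] for s in _LZC_STATES}
    control_rows = []
    for rec, events, group in syn.iter_synthetic_eeg(spec, seed):
        clean = preprocess_eeg(rec)
        epochs, _ = extract_state_epochs(clean, events, group)
        by_state = {ep.state: ep for ep in epochs}
        if group == "anesthesia":
            for state in _PE_STATES:
                per_ch = cx.pe_by_epoch(by_state[state], pe_cfg)
                f, p = cx.regional_pe(per_ch)
                frontal_pe[state].append(f)
                posterior_pe[state].append(p)
            lzc_cfg = cx.LZCConfig(rng_seed=seed)
            for state in _LZC_STATES:
                lzc[state].append(cx.lzc_by_epoch(by_state[state], lzc_cfg))
        else:
            for ep in epochs:
                per_ch = cx.pe_by_epoch(ep, pe_cfg)
                f, p = cx.regional_pe(per_ch)
                control_rows.append((rec.subject_id, ep.state, "frontal", f))
                control_rows.append((rec.subject_id, ep.state, "posterior", p))

    control = pd.DataFrame(
        control_rows, columns=["subject_id", "state", "region", "value"]
    )
    fit = ns.fit_epoch_lmm(control, measure="PE")
    contrasts = ns.pairwise_epoch_contrasts(fit)
    mean_f = {s: float(np.mean(v)) for s, v in frontal_pe.items()}
    mean_lzc = {s: float(np.mean(v)) for s, v in lzc.items()}
    return {
        "n_subjects": n_subjects,
        "frontal_pe": mean_f,
        "lzc": mean_lzc,
        "pe_maintenance_minus_ec1": mean_f["Maintenance"] - mean_f["EC1"],
        "pe_preroc_minus_ec1": mean_f["PreROC"] - mean_f["EC1"],
        "lzc_maintenance_minus_ec1": mean_lzc["Maintenance"] - mean_lzc["EC1"],
        "lzc_preroc_minus_ec1": mean_lzc["PreROC"] - mean_lzc["EC1"],
        "ec2_frontal_minus_posterior_pe": float(
            np.mean(frontal_pe["EC2"]) - np.mean(posterior_pe["EC2"])
        ),
        "control_min_bonferroni_p": float(contrasts["p_bonferroni"].min()),
    }


# ---------------------------------------------------------------------------
# Statistical calibration
# ---------------------------------------------------------------------------

def spearman_null_calibration(seed: int, n_replicates: int = 1000, n: int = 30) -> float:
    """Type-I error of the Spearman association test on independent pairs."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        r, p = ns.spearman_eeg_cognition(rng.standard_normal(n), rng.standard_normal(n))
        hits += p < 0.05
    return hits / n_replicates


def anova_null_calibration(
    seed: int,
    n_replicates: int = 200,
    n_per_group: int = 12,
    n_hours: int = 24,
    bump_min_per_h: float = 0.0,
    bump_hours: tuple[int, ...] = (18, 19),
) -> float:
    """Rejection rate of the group (or interaction) effect in the two-way
    inactivity ANOVA when both groups share the same hourly process; with
    ``bump_min_per_h`` > 0, the anesthesia group gains that many inactive
    minutes during ``bump_hours`` (power mode: either effect may reject)."""
    rng = np.random.default_rng(seed)
    hours = np.arange(n_hours)
    rhythm = 30.0 + 20.0 * np.cos(2 * np.pi * (hours - 3.5) / 24.0)
    hits = 0
    for _ in range(n_replicates):
        rows = []
        for group in ("anesthesia", "control"):
            for s in range(n_per_group):
                y = rhythm + rng.normal(0.0, 8.0, n_hours)
                if group == "anesthesia" and bump_min_per_h:
                    y = y + bump_min_per_h * np.isin(hours, bump_hours)
                for h, v in zip(hours, y):
                    rows.append((f"{group[0]}{s}", group, h, v))
        hourly = pd.DataFrame(
            rows, columns=["subject_id", "group", "hour", "inactive_min"]
        )
        from .actigraphy import inactivity_anova

        tab = inactivity_anova(hourly)
        if bump_min_per_h:
            hits += (
                tab.loc["group", "PR(>F)"] < 0.05
                or tab.loc["time_x_group", "PR(>F)"] < 0.05
            )
        else:
            hits += tab.loc["group", "PR(>F)"] < 0.05
    return hits / n_replicates


def power_mc_check(seed: int, n_sim: int = 50_000) -> dict:
    """Monte-Carlo verification of the closed-form t-test power at the two
    design scenarios."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, (diff, sd, n, alpha) in {
        "conservative": (30.0, 40.0, 30, 0.05),
        "liberal": (90.0, 20.0, 30, 0.001),
    }.items():
        a = rng.normal(diff, sd, (n_sim, n))
        b = rng.normal(0.0, sd, (n_sim, n))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt((va + vb) / 2.0)
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2.0 / n))
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, 2 * n - 2)
        mc = float(np.mean(np.abs(t) > tcrit))
        closed = ns.power_unpaired_t(diff, sd, n, alpha)
        out[name] = {"mc": mc, "closed_form": closed, "abs_error": abs(mc - closed)}
    return out
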