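"""End-to-end orchestration: synthetic data -> preprocessing -> complexity
-> statistics -> recovery model -> actigraphy, with seeded reproducibility.

Every stage writes tidy CSV/JSON into the run directory; the summary is
stamped with the configuration hash and seed so that identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import complexity as cx
from . import actigraphy as act
from . import neurophys_stats as ns
from . import recovery_model as rm
from . import synthetic_data as syn
from .eeg_preprocess import extract_state_epochs, preprocess_eeg

log = logging.getLogger("anesrecov")


@dataclass
class PipelineConfig:
    """Single-file configuration with per-stage sections."""

    outdir: str = "anesrecov_run"
    seed: int = 0
    # stage toggles
    run_eeg: bool = True
    run_cognitive: bool = True
    run_actigraphy: bool = True
    # synthetic study sizes (demo scale; the full study used 30 per arm)
    n_eeg_subjects: int = 4
    n_cognitive_per_arm: int = 15
    n_actigraphy_per_group: int = 10
    actigraphy_days: int = 2
    # analysis settings
    pe: dict = field(default_factory=dict)
    lzc: dict = field(default_factory=dict)
    eeg_measures: tuple = ("PE", "LZC")
    draws: int = 1000
    warmup: int = 400
    recovery_tests: tuple = (("AM", "accuracy"), ("DSST", "accuracy"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "recovery_tests" in raw:
            raw["recovery_tests"] = tuple(tuple(x) for x in raw["recovery_tests"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded
        so identical analyses hash identically wherever they are written)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_eeg(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    log.info("EEG stage: %d subjects/group", cfg.n_eeg_subjects)
    pe_cfg = cx.PEConfig(**cfg.pe)
    lzc_cfg = cx.LZCConfig(rng_seed=cfg.seed, **cfg.lzc)
    spec = syn.SyntheticEEGSpec(n_subjects=cfg.n_eeg_subjects)
    tables = []
    for rec, events, group in syn.iter_synthetic_eeg(spec, cfg.seed):
        clean = preprocess_eeg(rec)
        epochs, missing = extract_state_epochs(clean, events, group)
        for m in missing:
            log.warning("subject %s: %s", rec.subject_id, m)
        tab = cx.complexity_table(
            epochs, pe_cfg, lzc_cfg,
            compute_pe="PE" in cfg.eeg_measures,
            compute_lzc="LZC" in cfg.eeg_measures,
        )
        tab["group"] = group
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(outdir / "complexity.csv", index=False)

    anes = table[table["group"] == "anesthesia"]
    summary["eeg"] = {"n_subjects": int(table["subject_id"].nunique())}

    if "LZC" in cfg.eeg_measures:
        lzc = anes[anes["measure"] == "LZC"][["subject_id", "state", "value"]]
        lzc_fit = ns.fit_epoch_lmm(lzc, measure="LZC")
        lzc_contrasts = ns.pairwise_epoch_contrasts(lzc_fit)
        lzc_contrasts.to_csv(outdir / "lzc_epoch_contrasts.csv", index=False)
        summary["eeg"]["maintenance_vs_ec1_lzc"] = float(
            lzc_contrasts.query("epoch_a=='EC1' and epoch_b=='Maintenance'")[
                "estimate"
            ].iloc[0]
        )

    if "PE" in cfg.eeg_measures:
        pe_regional = cx.regional_pe_table(anes)
        pe_fit = ns.fit_epoch_lmm(pe_regional, measure="PE")
        pe_contrasts = ns.pairwise_epoch_contrasts(pe_fit)
        pe_contrasts.to_csv(outdir / "pe_epoch_contrasts.csv", index=False)
        summary["eeg"]["frontal_minus_posterior_ec2"] = ns.region_contrast_at(
            pe_fit, "EC2"
        )["estimate"]

    state_means = (
        table.groupby(["group", "state", "measure"])["value"].mean().reset_index()
    )
    state_means.to_csv(outdir / "complexity_state_means.csv", index=False)


def _stage_cognitive(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    log.info("cognitive stage: %d/arm, %d draws", cfg.n_cognitive_per_arm, cfg.draws)
    spec = syn.SyntheticCognitiveSpec(n_per_arm=cfg.n_cognitive_per_arm)
    records, truth = syn.gen_synthetic_cognitive(spec, cfg.seed)
    records.to_csv(outdir / "cognitive_records.csv", index=False)
    truth.to_csv(outdir / "cognitive_truth.csv", index=False)

    fits = {}
    results = {}
    for i, (test, metric) in enumerate(cfg.recovery_tests):
        bayes = rm.BayesConfig(
            draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed * 1000 + i
        )
        fit = rm.fit_damped_exponential(records, test, metric, bayes)
        fits[(test, metric)] = fit
        T, rec_mask = fit.recovery_time_draws()
        contrast = rm.group_contrast_at_3h(fit)
        results[f"{test}_{metric}"] = {
            "T_median_h": float(np.nanmedian(T)) if rec_mask.any() else None,
            "T_cri90_h": [float(np.nanquantile(T, q)) for q in (0.05, 0.95)]
            if rec_mask.any()
            else None,
            "frac_not_recovered": float(1 - rec_mask.mean()),
            "contrast_3h": {
                "estimate": contrast.estimate,
                "ci": list(contrast.ci),
                "p": contrast.p,
                "corrected_level": contrast.corrected_level,
            },
            "max_rhat": fit.diagnostics["max_rhat"],
        }
        fit.draws.to_csv(outdir / f"draws_{test}_{metric}.csv", index=False)
    comparisons = {}
    keys = list(fits)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            cmp_ = rm.posterior_recovery_comparison(fits[keys[a]], fits[keys[b]])
            comparisons["__vs__".join(["_".join(keys[a]), "_".join(keys[b])])] = {
                "p_diff_gt_30min": cmp_.p_diff_gt_threshold,
                "cri90_h": list(cmp_.cri),
                "excluded_frac": cmp_.excluded_frac,
            }
    summary["cognitive"] = {"fits": results, "comparisons": comparisons}
    (outdir / "recovery_summary.json").write_text(
        json.dumps(summary["cognitive"], indent=2)
    )


def _stage_actigraphy(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    log.info("actigraphy stage: %d/group", cfg.n_actigraphy_per_group)
    spec = syn.SyntheticActigraphySpec(
        n_per_group=cfg.n_actigraphy_per_group, days=cfg.actigraphy_days
    )
    minutes = syn.gen_synthetic_actigraphy(spec, cfg.seed)
    scored = act.score_sleep_cole_kripke(minutes)
    scored.to_csv(outdir / "actigraphy_scored.csv", index=False)
    hourly = act.hourly_inactivity(scored)
    hourly.to_csv(outdir / "actigraphy_hourly.csv", index=False)
    mean_by_hour = hourly.groupby("hour")["inactive_min"].mean()
    fit = act.cosinor_fit(
        mean_by_hour.index.to_numpy(dtype=float) + 0.5, mean_by_hour.to_numpy()
    )
    anova = act.inactivity_anova(hourly)
    anova.to_csv(outdir / "actigraphy_anova.csv")
    cosinor = {
        "mesor": fit.mesor,
        "amplitude": fit.amplitude,
        "acrophase_h": fit.acrophase_h,
        "r_squared": fit.r_squared,
    }
    (outdir / "cosinor.json").write_text(json.dumps(cosinor, indent=2))
    summary["actigraphy"] = {
        "cosinor": cosinor,
        "anova_p": {k: float(v) for k, v in anova["PR(>F)"].dropna().items()},
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return (and write) the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
        if cfg.run_eeg:
            _stage_eeg(cfg, outdir, summary)
        if cfg.run_cognitive:
            _stage_cognitive(cfg, outdir, summary)
        if cfg.run_actigraphy:
            _stage_actigraphy(cfg, outdir, summary)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
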