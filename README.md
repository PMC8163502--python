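# anesrecov

Analysis pipeline for studies of how consciousness and cognition recover
after general anesthesia. It is aimed at researchers who record multichannel
scalp EEG around an anesthetic exposure, administer serial cognitive test
batteries in the hours after emergence, and monitor rest–activity rhythms
with wrist actigraphy — and who want the three analysis strands to be
reproducible, tested, and runnable end-to-end on synthetic data with known
ground truth.

## What it computes

**EEG complexity across behavioural states.** Recordings are down-sampled to
250 Hz, re-referenced to the linked mastoids, reduced to a 21-channel 10-20
montage, band-pass filtered 0.5–30 Hz (zero-phase 4th-order Butterworth),
and cut into labelled 2-minute epochs (baseline eyes-closed, loss of
consciousness, anesthetic maintenance — with a burst-suppression fallback
rule — pre-recovery, and six post-emergence sessions). Two measures are
computed per epoch:

- *Permutation entropy* (dE = 5, τ = 4): the normalized Shannon entropy of
  ordinal patterns, H = −Σ p(π) log₂ p(π) / log₂(dE!), averaged over 10-s
  windows and summarized over frontal and posterior channel sets.
- *Multichannel Lempel–Ziv complexity*: per 4-s window, each channel's
  Hilbert amplitude is binarized at its mean, the channels × time bit matrix
  is flattened time point by time point, parsed with the LZ76 exhaustive
  history, and normalized by the mean count over N = 50 channel-wise
  shuffled surrogates.

Epoch effects are tested with a REML linear mixed model (subject random
intercept, heterogeneous per-epoch residual variance, Bonferroni-corrected
pairwise contrasts), and EEG–cognition associations with Spearman rank
correlation.

**Bayesian recovery-time model.** Standardized cognitive scores follow a
damped exponential, y_t = y_baseline + α + β·e^{γt} (plus a saturating
learning trend shared with non-anesthetized controls), with subject-level
random intercept α and slope β. The recovery time T = ln(−α/β)/γ is the
instant the predicted score re-crosses baseline. The posterior is sampled
by ensemble MCMC after marginalizing the random effects analytically; per
draw, recovery-time differences between tests give P(diff > 30 min) and 90%
credible intervals, and the 3-hour anesthesia-minus-control contrast gets a
Bonferroni-adjusted interval against the corrected level 0.05/6 = 0.0083.

**Actigraphy.** Per-minute counts are scored with the Cole–Kripke 1-minute
algorithm, summarized as hourly minutes of inactivity (with wear-time
exclusion), fitted with a fixed-period 24-h cosinor, and compared across
groups with a two-way time × group ANOVA.

**Synthetic study generator.** Every input modality can be generated with
known truth: state-dependent EEG (bandwidth and cross-channel redundancy
carry the state signal), cognitive trajectories drawn exactly from the
recovery model, and cosinor-rhythmic activity counts. See
`docs/methods.md` for the models, defaults, and what the synthetic
validation does and does not establish.

## Worked example

```python
import numpy as np
from anesrecov.neurophys_stats import power_unpaired_t, bonferroni_threshold
from anesrecov.synthetic_data import SyntheticCognitiveSpec, gen_synthetic_cognitive
from anesrecov.recovery_model import (
    BayesConfig, fit_damped_exponential, posterior_recovery_comparison,
)

print(f"power (diff=30, sd=40, n=30, alpha=0.05) = {power_unpaired_t(30, 40, 30, 0.05):.3f}")
print(f"corrected level 0.05/6 = {bonferroni_threshold(0.05, 6):.4f}")

records, truth = gen_synthetic_cognitive(SyntheticCognitiveSpec(), seed=1)
cfg = BayesConfig(draws=1000, seed=1)
fit_am = fit_damped_exponential(records, "AM", "accuracy", cfg)
fit_dsst = fit_damped_exponential(records, "DSST", "accuracy", cfg)
T, _ = fit_dsst.recovery_time_draws()
print(f"DSST accuracy: posterior median T = {np.nanmedian(T):.2f} h")
cmp_ = posterior_recovery_comparison(fit_am, fit_dsst)
print(f"P(AM recovers >30 min before DSST) = {cmp_.p_diff_gt_threshold:.3f}")
```

prints

```
power (diff=30, sd=40, n=30, alpha=0.05) = 0.815
corrected level 0.05/6 = 0.0083
DSST accuracy: posterior median T = 1.46 h
P(AM recovers >30 min before DSST) = 1.000
```

The synthetic truth behind this run placed abstract-matching (AM) recovery
at T = 0.5 h and digit-symbol (DSST) recovery at T = 1.5 h; the posterior
median lands within a few minutes of truth (1.46 h, 90% CrI 1.31–1.69 h)
and the model is essentially certain AM recovered more than 30 minutes
earlier — the configured gap is a full hour.

A complete run (EEG synthesis → preprocessing → complexity → mixed models →
recovery fits → actigraphy), writing tidy CSVs and a JSON summary:

```bash
anesrecov all --outdir run1 --seed 1 --draws 1000
# or with a config file (see examples/demo.yaml for all keys)
anesrecov all --config examples/demo.yaml --outdir run1 --seed 1
```

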