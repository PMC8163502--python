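# Methods

`anesrecov` implements the computational core of a neurophysiology-and-
cognition study of emergence from general anesthesia: EEG complexity
measures across labelled behavioural states, a Bayesian damped-exponential
model of post-anesthetic cognitive recovery, repeated-measures mixed models
with heterogeneous residual variance, and actigraphy rhythm analysis. All
stages are exercised end-to-end on synthetic data with known ground truth;
this note records the models, the defaults and why, the numerical choices,
and what the synthetic validation does and does not show.

## EEG preprocessing

Recordings are down-sampled to 250 Hz (polyphase, anti-aliased),
re-referenced to the mean of the two mastoids (a config option names a
substitute pair for montages without labelled mastoids), reduced to a
21-channel 10-20 scalp montage — the 19 standard positions plus Fpz and Oz,
configurable — and band-pass filtered 0.5–30 Hz with a 4th-order Butterworth
filter applied forward–backward. Zero-phase two-pass filtering means the
effective magnitude response is the squared single-pass response; the
passband is distortion-free in phase (verified by a zero-lag
cross-correlation test) and a 50 Hz tone is attenuated by more than 40 dB.

Artifact handling is deliberately not automated: a boolean per-sample mask
(or a CSV of masked spans) is supplied with the recording, and state epochs
are only cut from contiguous unmasked data. Ten 2-minute epochs are placed
per anesthetized subject — eyes-closed baseline (EC1), the first 2 min after
loss of consciousness (LOC), the last 2 min of anesthetic maintenance, the
2 min before recovery of consciousness (PreROC), and six post-emergence
eyes-closed sessions (EC2–EC7) — and seven (EC1–EC7) per control. Windows
that collide with the mask shift in 1-s steps within a bounded search region
(forward up to 8 min for resting sessions, backward up to 8 min for
maintenance); epochs that cannot be placed are reported as missing, never
fabricated.

Burst suppression is detected with an amplitude-envelope rule: a span counts
as suppressed when every channel stays below 5 µV for at least 0.5 s (both
thresholds configurable). If the nominal maintenance window contains any
suppression, the extractor falls back to the nearest suppression-free
2-minute window, searching the last 10 min of anesthetic administration
first and the 7 min after discontinuation second. The rule is an auditable
stand-in for visual identification; its thresholds were chosen once for the
synthetic amplitude scale (20 µV RMS states, ~1 µV suppression floor) and
are not tuned per recording.

## Permutation entropy

PE is the Shannon entropy (base 2) of the distribution of ordinal patterns
of delay vectors, with embedding dimension dE = 5 and delay τ = 4 samples
(16 ms at 250 Hz) by default. Ties are ranked by first occurrence (a
deterministic convention; random tie-breaking is available behind a flag).
Entropy is normalized by log2(dE!) so values lie in [0, 1]; the normalization
is a package convention — group contrasts are scale-consistent either way.
Each 2-minute epoch is split into twelve non-overlapping 10-s windows, PE is
computed per window and channel, and window values are averaged. Regional
summaries average the frontal set {Fp1, Fp2, Fpz, F3, F4, Fz} and the
posterior set {P3, P4, Pz, O1, O2, Oz}.

## Multichannel Lempel-Ziv complexity

Per 4-s window: the common average is subtracted from every channel; each
channel's instantaneous amplitude (modulus of the analytic signal) is
binarized at that channel's mean amplitude *within the window* (strict `>`;
the tie convention and a `>=` alternative are explicit in config); the
21 × 1000 bit matrix is flattened column-major — the spatial pattern at each
time point, concatenated over time — and parsed with the Lempel–Ziv 1976
exhaustive history. The raw word count is divided by its mean over N = 50
surrogates in which each channel's bit row is shuffled independently
(per-channel time shuffle), giving a scale-free value near 1 for data that
are as complex as their temporally shuffled counterpart. Window values are
averaged over the 30 windows of an epoch. The surrogate RNG is seeded per
(config seed, window index), so epoch values are bit-reproducible and the
surrogate-mean jitter between seeds is below 2% for white-noise input.

The LZ76 count follows the original exhaustive-history definition: each
word is the shortest prefix of the remaining suffix not producible by
copying from an earlier start (overlapping self-copy allowed); the final
word may be producible. Two independent routes are kept: a brute-force
transcription of the definition, and the production path via suffix array
(prefix doubling with counting sort), Kasai LCP, and the stack-based
longest-previous-factor algorithm, all numba-compiled (~2 ms per 21,000-bit
parse). The two routes agree exhaustively on all binary strings of length
≤ 14 (length ≤ 12 is re-verified in the acceptance suite). Hilbert-transform
edge effects are not padded or tapered: at 4 s × 250 Hz the edge bias is
negligible against the mean-amplitude threshold.

## Damped-exponential recovery model

Standardized cognitive scores (centered and scaled by the pooled
across-subject baseline mean and SD, per test and metric; speed oriented so
higher = faster) are modelled as

    y_t = y_baseline + L(k) + alpha_i + beta_i * exp(gamma * t) + eps,

for anesthetized subject i at time t hours after return of consciousness
(session k), with alpha_i ~ N(mu_alpha, sigma_alpha²) and beta_i ~
N(mu_beta, sigma_beta²) independent, gamma < 0 fixed, and eps ~ N(0,
sigma²). Controls contribute y_baseline + L(k) + eps. The learning term
L(k) = lambda (1 − e^{−k/κ}) is a saturating practice effect shared by both
groups and identified chiefly by the controls; κ is fixed at 2 sessions and
lambda is estimated. The functional form of the practice effect was an open
design choice; a saturating exponential in session index was chosen as the
simplest monotone form that separates cleanly from the deficit term (which
decays in clock time at a free rate). Baseline sessions carry no deficit
term (the deficit exists only post-anesthesia).

The population recovery time is T = ln(−mu_alpha/mu_beta)/gamma, the instant
the predicted deficit re-crosses baseline; draws with −mu_alpha/mu_beta ≤ 0,
gamma = 0, or negative T are "not recovered" (one default test
configuration, PVT accuracy, never recovers by construction).

Inference is fully Bayesian. Priors: N(0, 10²) on the fixed effects
(truncated to gamma < 0 for identifiability of the exponential) and
half-normal(5) on SD components — weakly informative on the standardized
scale. Because the model is linear in (alpha_i, beta_i) given gamma, the
random effects are marginalized analytically: each subject contributes a
multivariate normal likelihood with covariance sigma²I + sigma_alpha² u uᵀ +
sigma_beta² g gᵀ (u the post-ROC indicator, g = u·e^{gamma t}), evaluated
from per-pattern sufficient statistics so the cost is independent of subject
count. The resulting 8-parameter marginal posterior is sampled with an
affine-invariant ensemble (emcee, 32 walkers, differential-evolution moves),
initialized from the posterior mode and its Laplace covariance. Defaults:
10,000 draws after 400 warmup steps; the replicated validation studies use a
reduced 1,000-draw mode. Convergence is monitored with split-Rhat across
walkers and the mean acceptance fraction; a strict mode raises on
Rhat > 1.05. Short DE-move chains flag Rhat ≈ 1.2–1.3 even when their
posterior moments and recovery-time quantiles match a 10×-longer reference
run to well within Monte-Carlo error (checked during development on the
default generator conditions), so the default mode records diagnostics
without raising.

Degenerate variants with the random intercept or random slope removed are
fitted on request and compared by BIC (using the maximum marginal
log-likelihood over the chain); on data simulated with zero slope variance
the fixed-slope variant is preferred in the majority of replicates.

Pairwise recovery-time comparisons are computed per posterior draw, paired
by draw index: P(test A recovers more than 30 min before B) is the
proportion of draws with T_B − T_A > 0.5 h, with a central 90% credible
interval of the difference. Draws where only the earlier test recovers count
as exceeding any finite threshold; draws where neither recovers are excluded
and the excluded fraction reported; a comparison with every draw unrecovered
on one side is flagged as dominated by non-recovery. The 3-hour group
contrast is the posterior of mu_alpha + mu_beta e^{3·gamma} (the model's
predicted anesthesia-minus-control difference at 3 h), reported with a
Bonferroni-adjusted central credible interval over the six tests and a
two-sided posterior tail probability compared against 0.05/6 = 0.0083. In a
fully Bayesian pipeline this tail probability plays the role of the p-value
in the original least-squares-means formulation; null simulations confirm
its calibration is conservative at the corrected level.

## Epoch-wise mixed models

PE and LZC are compared across states with a linear mixed model estimated by
REML: a subject-specific random intercept, cell-mean fixed effects for epoch
(and for PE, epoch × region), and a *diagonal heterogeneous* residual
covariance — each epoch has its own residual variance. statsmodels' MixedLM
does not support per-epoch residual variances, so the REML objective is
written directly: variance parameters are optimized on the log scale
(L-BFGS-B, moment-based start), fixed effects are profiled out by GLS, and
subjects sharing an observation pattern contribute through sufficient
statistics. On balanced data the GLS estimates reduce exactly to epoch
means, which the tests verify against closed form. Pairwise contrasts use
t statistics with n_subjects − 1 degrees of freedom (a conservative choice
that keeps the Bonferroni family-wise error at or below its nominal level in
null simulations); the correction multiplies the raw p by the number of
pairs actually tested (configurable family size). Only the anesthetized
group enters the epoch models; the control group's EC1–EC7 no-difference
check runs in the validation suite.

Spearman associations between EEG measures and cognitive impairment use
tie-corrected ranks with the t approximation for n ≥ 10 and a permutation
p-value below that (exhaustive for n ≤ 8). The design-power utility is the
exact noncentral-t power of the two-sided unpaired t test (df = 2n − 2,
noncentrality (diff/sd)·√(n/2)); it is verified against 50,000-replicate
Monte-Carlo simulation to within ±0.01 at both design scenarios.

## Actigraphy

Per-minute counts are scored with the published Cole–Kripke 1-minute
coefficients (scale 0.001; weights 106, 54, 58, 76, 230, 74, 67 for minutes
t−4…t+2; inactive when the weighted sum < 1), stored in config so alternates
can be swapped; series boundaries are zero-padded. Hours containing a
non-wear run longer than 5 consecutive minutes (configurable) are excluded;
otherwise inactive minutes are counted among worn minutes per clock hour.
The rhythm fit is a fixed-period 24-h cosinor (least squares on the
cosine/sine basis; acrophase = clock time of peak, wrapped to [0, 24)), and
group comparisons use a two-way fixed-effects ANOVA (time in hours × group,
with interaction) with marginal type-II sums of squares, which tolerates the
asynchronous missing hours non-wear creates.

## Synthetic data: what it emulates and what it does not

EEG states are band-limited Gaussian noise with state-dependent bandwidth
and cross-channel redundancy: wakeful states are broadband (0.5–30 Hz) with
15% of variance in shared latent sources; LOC is 0.5–10 Hz with 40% shared;
maintenance is 0.5–4 Hz with 60% shared; PreROC matches baseline. At EC2
the posterior channels carry 0.5–10 Hz activity while frontal channels stay
broadband, inducing the post-emergence frontal > posterior entropy
asymmetry. A configurable fraction of subjects (default 20%, mirroring 6 of
30) receives burst suppression in the last 3 min of maintenance, which
exercises the fallback rule. These choices make PE respond through
bandwidth (fewer ordinal patterns at 16-ms delay spacing for slow activity)
and LZC through both bandwidth and spatial redundancy — which is the
mechanism the analysis is designed to detect — but the data contain no
oscillatory peaks, no 1/f background, no eye blinks or muscle artifact, and
no physiologic topography. Passing the pattern suite therefore shows the
pipeline orders states correctly when bandwidth and redundancy carry the
state signal; it does not certify performance on real EEG.

Cognitive trajectories are drawn exactly from the recovery model (baseline
0, learning amplitude 0.3 SD with κ = 2, residual SD 0.5, random-effect SDs
0.3/0.5, n = 30 per arm), with per-test truths spread over T = 0.5–2 h and
executive function recovering first; they are arbitrary but narrative-
patterned configuration values, not estimates of any human posterior.
Because generator and model share a functional form, the parameter-recovery
study validates inference, not model adequacy.

Actigraphy counts follow a two-state (inactive/active) process in 15-minute
blocks whose inactive probability is a clipped cosinor (mesor 0.45,
amplitude 0.35, acrophase 03:30 — within the observed 3–4 a.m. peak window);
active minutes draw overdispersed negative-binomial counts (mean 300),
inactive minutes near-zero Poisson counts, with ~1 non-wear episode of
30–90 min per day and an optional +0.25 early-evening (18:00–20:00)
inactivity bump in the anesthesia group on the study day. Block structure
keeps bouts long relative to the 7-minute scoring window so the scored
rhythm tracks the generating cosinor; the clipping and scoring nonlinearity
distort amplitude but are symmetric around the peak, so the acrophase is
preserved.

## Problem sizes and runtimes

The validation studies use 20 subjects per group for the EEG pattern suite,
20 replicates at 1,000 draws for parameter recovery, 1,000/200 replicates
for the Spearman/ANOVA null calibrations, and 50,000 simulations for the
power cross-check; together they run in roughly 10–15 minutes on one CPU,
and the bundled demo pipeline configuration completes in about two minutes.

## Known limitations

- The burst-suppression rule is amplitude-based and untested against
  clinically scored recordings.
- Control subjects carry no subject-level random intercept in the recovery
  model (matching the generator); real cognitive data would likely need one.
- The 3-h group contrast is a posterior summary, not a frequentist
  least-squares-means test; its "p" is a tail probability.
- EDF/BrainVision ingestion is a thin wrapper over mne and is not covered by
  binary fixtures; the package's own text matrix format is the tested path.
- LMM contrast degrees of freedom are the conservative n_subjects − 1 rather
  than a Satterthwaite approximation.
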