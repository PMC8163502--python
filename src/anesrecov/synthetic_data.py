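"""Synthetic EEG, cognitive, and actigraphy data with known ground truth.

Every generator is a pure function of (spec, seed) and emits data in exactly
the shapes the analysis pipeline consumes, so each stage can be exercised
end-to-end without any recordings from human subjects.

EEG states are modelled as band-limited Gaussian noise with state-dependent
bandwidth and cross-channel redundancy, not as biophysical simulation:
permutation entropy responds to bandwidth (narrow-band slow activity during
anesthetic maintenance gives fewer distinct ordinal patterns) and
multichannel Lempel-Ziv complexity responds to both bandwidth and spatial
redundancy (shared latent sources reduce the spatial pattern repertoire).
That is sufficient to induce the wake > maintenance orderings the analysis
is meant to detect, without claiming physiological realism.

Cognitive scores follow the damped-exponential recovery model exactly
(baseline + saturating learning shared with controls; anesthesia adds the
subject-level alpha_i + beta_i*exp(gamma t) deficit), so the true population
recovery time of every test is known in closed form.

Actigraphy counts follow a 24-h cosinor inactivity rhythm (default acrophase
03:30) realized as blocks of inactive/active minutes, with overdispersed
counts when active, plus an optional early-evening inactivity bump in the
anesthesia group on the study day and inserted non-wear episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_preprocess import (
    EEGRecording,
    EpochSelectionEvents,
    POSTERIOR_CHANNELS,
    STANDARD_21,
)
from .recovery_model import recovery_time_from_params

# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class StateProfile:
    """Spectral/spatial profile of one behavioural state: band-limited noise
    with a fraction of variance carried by shared latent sources."""

    band: tuple[float, float] = (0.5, 30.0)
    shared_frac: float = 0.15
    n_sources: int = 3


_DEFAULT_PROFILES = {
    "EC1": StateProfile((0.5, 30.0), 0.15),
    "LOC": StateProfile((0.5, 10.0), 0.40),
    "Maintenance": StateProfile((0.5, 4.0), 0.60),
    "PreROC": StateProfile((0.5, 30.0), 0.15),
    "EC2": StateProfile((0.5, 30.0), 0.15),
    "EC3": StateProfile((0.5, 30.0), 0.15),
    "EC4": StateProfile((0.5, 30.0), 0.15),
    "EC5": StateProfile((0.5, 30.0), 0.15),
    "EC6": StateProfile((0.5, 30.0), 0.15),
    "EC7": StateProfile((0.5, 30.0), 0.15),
}


@dataclass
class SyntheticEEGSpec:
    """Study-scale synthetic EEG: one recording per subject containing all
    labelled state segments at their event times."""

    n_subjects: int = 30
    fs: float = 250.0
    amplitude_uv: float = 20.0
    mastoid_amplitude_uv: float = 2.0
    state_profiles: dict = field(default_factory=lambda: dict(_DEFAULT_PROFILES))
    #: at EC2 the posterior channels carry narrower-band activity than the
    #: frontal ones, reproducing the post-emergence frontal > posterior
    #: entropy asymmetry
    frontal_posterior_asymmetry: bool = True
    asymmetry_posterior_band: tuple[float, float] = (0.5, 10.0)
    #: fraction of anesthesia subjects whose nominal (last-2-min) Maintenance
    #: window contains burst suppression, exercising the fallback rule
    burst_suppression_frac: float = 0.2
    burst_s: float = 3.0
    suppression_s: float = 2.0


def _band_noise(rng, band, fs, shape):
    lo, hi = band
    x = rng.standard_normal(shape)
    sos = signal.butter(4, (lo, min(hi, 0.49 * fs * 2 / 2)), btype="bandpass", fs=fs,
                        output="sos")
    y = signal.sosfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _state_segment(rng, profile: StateProfile, n_ch: int, n_samp: int, fs: float,
                   amplitude: float) -> np.ndarray:
    shared = _band_noise(rng, profile.band, fs, (profile.n_sources, n_samp))
    loadings = rng.standard_normal((n_ch, profile.n_sources))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    indep = _band_noise(rng, profile.band, fs, (n_ch, n_samp))
    x = (
        np.sqrt(profile.shared_frac) * loadings @ shared
        + np.sqrt(1.0 - profile.shared_frac) * indep
    )
    return amplitude * x


def _burst_suppression_segment(rng, spec: SyntheticEEGSpec, n_ch: int,
                               n_samp: int) -> np.ndarray:
    """Alternating high-amplitude slow bursts and near-isoelectric spans."""
    slow = _state_segment(
        rng, StateProfile((0.5, 4.0), 0.7), n_ch, n_samp, spec.fs, 2.0 * spec.amplitude_uv
    )
    gate = np.zeros(n_samp)
    period = int(round((spec.burst_s + spec.suppression_s) * spec.fs))
    burst_n = int(round(spec.burst_s * spec.fs))
    for start in range(0, n_samp, period):
        gate[start : start + burst_n] = 1.0
    return slow * gate + 0.5 * rng.standard_normal((n_ch, n_samp))


_ANES_TIMELINE = {
    # state -> (segment start s, segment length s)
    "EC1": (10.0, 180.0),
    "LOC": (220.0, 180.0),
    "Maintenance": (420.0, 600.0),
    "PreROC": (1020.0, 160.0),
    "EC2": (1200.0, 180.0),
    "EC3": (1400.0, 180.0),
    "EC4": (1600.0, 180.0),
    "EC5": (1800.0, 180.0),
    "EC6": (2000.0, 180.0),
    "EC7": (2200.0, 180.0),
}
_ANES_EVENTS = dict(loc=220.0, iso_off=1020.0, roc=1180.0)
_ANES_DURATION = 2390.0

_CONTROL_SESSION_STARTS = [10.0 + 200.0 * j for j in range(7)]
_CONTROL_DURATION = 1400.0


def _assemble_recording(
    rng, spec: SyntheticEEGSpec, subject_id: str, group: str, with_bs: bool
) -> tuple[EEGRecording, EpochSelectionEvents]:
    fs = spec.fs
    labels = list(STANDARD_21) + ["M1", "M2"]
    n_scalp = len(STANDARD_21)
    duration = _ANES_DURATION if group == "anesthesia" else _CONTROL_DURATION
    n = int(round(duration * fs))
    # low-amplitude broadband background everywhere outside state segments
    data = 0.3 * spec.amplitude_uv * rng.standard_normal((n_scalp, n))

    if group == "anesthesia":
        segments = dict(_ANES_TIMELINE)
    else:
        segments = {
            f"EC{j + 1}": (t0, 180.0) for j, t0 in enumerate(_CONTROL_SESSION_STARTS)
        }

    posterior_idx = [STANDARD_21.index(c) for c in POSTERIOR_CHANNELS]
    for state, (t0, length) in segments.items():
        i0, n_seg = int(round(t0 * fs)), int(round(length * fs))
        profile = spec.state_profiles[state]
        seg = _state_segment(rng, profile, n_scalp, n_seg, fs, spec.amplitude_uv)
        # the post-emergence regional asymmetry is an after-effect of the
        # anesthetic state; controls stay symmetric across EC1-EC7
        if (
            state == "EC2"
            and group == "anesthesia"
            and spec.frontal_posterior_asymmetry
        ):
            narrow = StateProfile(
                spec.asymmetry_posterior_band, profile.shared_frac, profile.n_sources
            )
            seg[posterior_idx] = _state_segment(
                rng, narrow, len(posterior_idx), n_seg, fs, spec.amplitude_uv
            )
        if state == "Maintenance" and with_bs:
            # burst suppression fills the last 3 minutes, contaminating the
            # nominal last-2-min window but leaving earlier segments clean
            n_bs = int(round(180.0 * fs))
            seg[:, -n_bs:] = _burst_suppression_segment(rng, spec, n_scalp, n_bs)
        data[:, i0 : i0 + n_seg] = seg

    mastoids = spec.mastoid_amplitude_uv * rng.standard_normal((2, n))
    rec = EEGRecording(
        subject_id, np.vstack([data, mastoids]), fs, labels
    )
    if group == "anesthesia":
        events = EpochSelectionEvents(
            resting_session_starts=[_ANES_TIMELINE["EC1"][0]]
            + [_ANES_TIMELINE[f"EC{j}"][0] for j in range(2, 8)],
            loc_time=_ANES_EVENTS["loc"],
            iso_off_time=_ANES_EVENTS["iso_off"],
            roc_time=_ANES_EVENTS["roc"],
        )
    else:
        events = EpochSelectionEvents(resting_session_starts=_CONTROL_SESSION_STARTS)
    return rec, events


def iter_synthetic_eeg(
    spec: SyntheticEEGSpec, seed: int, groups: tuple[str, ...] = ("anesthesia", "control")
) -> Iterator[tuple[EEGRecording, EpochSelectionEvents, str]]:
    """Yield (recording, events, group) one subject at a time (recordings are
    tens of MB; streaming keeps the working set small)."""
    for gi, group in enumerate(groups):
        n_bs = (
            int(round(spec.burst_suppression_frac * spec.n_subjects))
            if group == "anesthesia"
            else 0
        )
        for si in range(spec.n_subjects):
            rng = np.random.default_rng(np.random.SeedSequence([seed, gi, si]))
            sid = f"{'A' if group == 'anesthesia' else 'C'}{si + 1:02d}"
            yield (*_assemble_recording(rng, spec, sid, group, si < n_bs), group)


def gen_synthetic_eeg(spec: SyntheticEEGSpec, seed: int, **kw):
    """Materialized version of :func:`iter_synthetic_eeg` (small n only)."""
    return list(iter_synthetic_eeg(spec, seed, **kw))


# ---------------------------------------------------------------------------
# Cognitive
# ---------------------------------------------------------------------------

@dataclass
class TruthParams:
    """True population parameters of one test/metric's recovery trajectory."""

    alpha_mu: float
    beta_mu: float
    gamma: float
    alpha_sd: float = 0.3
    beta_sd: float = 0.5

    @property
    def recovery_time(self) -> float:
        return recovery_time_from_params(self.alpha_mu, self.beta_mu, self.gamma)


def _truth(T: float, gamma: float, beta_mu: float = -3.0) -> TruthParams:
    """Truth with a prescribed population recovery time."""
    alpha = -beta_mu * float(np.exp(gamma * T))
    return TruthParams(alpha_mu=alpha, beta_mu=beta_mu, gamma=gamma)


# Executive function (AM) recovers first, reaction-time / processing-speed
# tasks later; PVT accuracy never re-crosses baseline (persistent deficit).
_DEFAULT_TRUTHS = {
    ("AM", "accuracy"): _truth(0.5, -2.0, -2.5),
    ("MP", "accuracy"): _truth(0.75, -1.8, -2.5),
    ("VOLT", "accuracy"): _truth(1.25, -1.5, -3.0),
    ("DSST", "accuracy"): _truth(1.5, -1.5, -3.0),
    ("NBCK", "accuracy"): _truth(2.0, -1.2, -2.5),
    ("PVT", "accuracy"): TruthParams(-0.5, -2.0, -1.5),
    ("AM", "speed"): _truth(0.75, -1.8, -3.0),
    ("MP", "speed"): _truth(1.0, -1.5, -3.0),
    ("VOLT", "speed"): _truth(1.5, -1.4, -3.0),
    ("DSST", "speed"): _truth(1.75, -1.3, -3.0),
    ("NBCK", "speed"): _truth(2.0, -1.2, -2.0),
    ("PVT", "speed"): _truth(1.25, -1.5, -4.0),
}

POST_SESSION_TIMES_H = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class SyntheticCognitiveSpec:
    """Study-scale cognitive trajectories on the standardized-score scale."""

    n_per_arm: int = 30
    y_baseline: float = 0.0
    learn_amp: float = 0.3
    learn_tau_sessions: float = 2.0
    residual_sd: float = 0.5
    truths: dict = field(default_factory=lambda: dict(_DEFAULT_TRUTHS))


def gen_synthetic_cognitive(
    spec: SyntheticCognitiveSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format standardized cognitive records plus a truth table with the
    true population recovery time per test/metric."""
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    rows = []
    sessions = [(0, np.nan)] + [
        (k + 1, t) for k, t in enumerate(POST_SESSION_TIMES_H)
    ]
    for (test, metric), tp in spec.truths.items():
        for group, prefix in (("anesthesia", "A"), ("control", "C")):
            for si in range(spec.n_per_arm):
                sid = f"{prefix}{si + 1:02d}"
                alpha_i = rng.normal(tp.alpha_mu, tp.alpha_sd)
                beta_i = rng.normal(tp.beta_mu, tp.beta_sd)
                for k, t in sessions:
                    y = spec.y_baseline + spec.learn_amp * (
                        1.0 - np.exp(-k / spec.learn_tau_sessions)
                    )
                    if group == "anesthesia" and k >= 1:
                        y += alpha_i + beta_i * np.exp(tp.gamma * t)
                    y += rng.normal(0.0, spec.residual_sd)
                    rows.append((sid, group, test, metric, k, t, y))
    records = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "test", "metric", "session_index", "t_hours",
            "score",
        ],
    )
    truth = pd.DataFrame(
        [
            dict(
                test=test,
                metric=metric,
                alpha_mu=tp.alpha_mu,
                beta_mu=tp.beta_mu,
                gamma=tp.gamma,
                alpha_sd=tp.alpha_sd,
                beta_sd=tp.beta_sd,
                T_true=tp.recovery_time,
            )
            for (test, metric), tp in spec.truths.items()
        ]
    )
    return records, truth


# ---------------------------------------------------------------------------
# Actigraphy
# ---------------------------------------------------------------------------

@dataclass
class SyntheticActigraphySpec:
    """Per-minute activity counts with a 24-h cosinor inactivity rhythm."""

    n_per_group: int = 30
    days: int = 3
    #: cosinor of the probability that a minute belongs to an inactive bout
    mesor: float = 0.45
    amplitude: float = 0.35
    acrophase_h: float = 3.5
    block_min: int = 15
    active_counts_mean: float = 300.0
    active_counts_dispersion: float = 5.0
    inactive_counts_mean: float = 0.3
    #: extra inactivity probability in the anesthesia group during the early
    #: evening of the study day (hours of day, end exclusive)
    bump_magnitude: float = 0.25
    bump_window_h: tuple[float, float] = (18.0, 20.0)
    bump_day: int = 0
    nonwear_per_day: float = 1.0
    nonwear_min_range: tuple[int, int] = (30, 90)


def gen_synthetic_actigraphy(spec: SyntheticActigraphySpec, seed: int) -> pd.DataFrame:
    """Per-minute (subject, group, timestamp_min, counts, worn) table;
    timestamps are minutes from the midnight before the study day."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    total_min = spec.days * 1440
    t_min = np.arange(total_min)
    hours = (t_min / 60.0) % 24.0
    day = t_min // 1440
    rows = []
    for group, prefix in (("anesthesia", "A"), ("control", "C")):
        p = spec.mesor + spec.amplitude * np.cos(
            2.0 * np.pi * (t_min / 60.0 - spec.acrophase_h) / 24.0
        )
        if group == "anesthesia" and spec.bump_magnitude > 0:
            in_bump = (
                (day == spec.bump_day)
                & (hours >= spec.bump_window_h[0])
                & (hours < spec.bump_window_h[1])
            )
            p = p + spec.bump_magnitude * in_bump
        p = np.clip(p, 0.02, 0.98)
        for si in range(spec.n_per_group):
            sid = f"{prefix}{si + 1:02d}"
            inactive = np.empty(total_min, dtype=bool)
            for b0 in range(0, total_min, spec.block_min):
                b1 = min(b0 + spec.block_min, total_min)
                inactive[b0:b1] = rng.random() < p[(b0 + b1) // 2]
            nb_n = spec.active_counts_dispersion
            nb_p = nb_n / (nb_n + spec.active_counts_mean)
            counts = np.where(
                inactive,
                rng.poisson(spec.inactive_counts_mean, total_min),
                rng.negative_binomial(nb_n, nb_p, total_min),
            ).astype(int)
            worn = np.ones(total_min, dtype=bool)
            n_episodes = rng.poisson(spec.nonwear_per_day * spec.days)
            for _ in range(n_episodes):
                length = rng.integers(*spec.nonwear_min_range)
                start = rng.integers(0, max(1, total_min - length))
                worn[start : start + length] = False
            counts[~worn] = 0
            rows.append(
                pd.DataFrame(
                    dict(
                        subject_id=sid,
                        group=group,
                        timestamp_min=t_min,
                        counts=counts,
                        worn=worn,
                    )
                )
            )
    return pd.concat(rows, ignore_index=True)
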