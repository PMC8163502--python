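"""Permutation entropy and surrogate-normalized Lempel-Ziv complexity.

Permutation entropy (PE) is the Shannon entropy of the distribution of
ordinal patterns: for each delay vector (x_t, x_{t+tau}, ..., x_{t+(dE-1)tau})
the pattern is the permutation that sorts it ascending (ties broken by first
occurrence). With the defaults dE=5, tau=4, a 2-minute epoch is split into
non-overlapping 10-s windows, PE is computed per window and channel, and
window values are averaged. PE is normalized by log2(dE!) so 0 = perfectly
regular, 1 = all patterns equiprobable.

Multichannel Lempel-Ziv complexity (LZC) captures the spatiotemporal
repertoire: after removing the common average, each channel's Hilbert
amplitude is binarized at its own mean, the channels x time bit matrix is
flattened time point by time point (all channels at t=1, then t=2, ...), and
the LZ76 exhaustive-parsing word count of the resulting sequence is divided
by its mean over N surrogate matrices in which each channel's time course is
independently shuffled. Values near 1 indicate the signal is as complex as
its time-shuffled (spatially uncorrelated in time) counterpart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from ._lz76 import (  # noqa: F401 (slow route re-exported for cross-checks)
    _lzc_raw_and_surrogate_mean,
    lz76_word_count,
    lz76_word_count_slow,
)
from .eeg_preprocess import FRONTAL_CHANNELS, POSTERIOR_CHANNELS, StateEpoch
from .errors import LengthError, MontageError, ParameterError


@dataclass
class PEConfig:
    """Permutation-entropy parameters (embedding dE, delay tau in samples)."""

    dE: int = 5
    tau: int = 4
    window_s: float = 10.0
    normalize: bool = True
    tie_break: str = "stable"  # or "random"

    def __post_init__(self) -> None:
        if self.dE < 2 or self.tau < 1 or self.window_s <= 0:
            raise ParameterError("require dE >= 2, tau >= 1, window_s > 0")
        if self.tie_break not in ("stable", "random"):
            raise ParameterError("tie_break must be 'stable' or 'random'")


@dataclass
class LZCConfig:
    """Multichannel LZC parameters (4-s windows, N=50 row-shuffle surrogates)."""

    window_s: float = 4.0
    n_surrogates: int = 50
    rng_seed: int = 0
    threshold_rule: str = "mean_amplitude"
    comparison: str = "greater"  # or "greater_equal"

    def __post_init__(self) -> None:
        if self.n_surrogates < 1 or self.window_s <= 0:
            raise ParameterError("require n_surrogates >= 1 and window_s > 0")
        if self.threshold_rule != "mean_amplitude":
            raise ParameterError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.comparison not in ("greater", "greater_equal"):
            raise ParameterError("comparison must be 'greater' or 'greater_equal'")


# ---------------------------------------------------------------------------
# Permutation entropy
# ---------------------------------------------------------------------------

def _ordinal_codes(x: np.ndarray, dE: int, tau: int, tie_break: str = "stable",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Lexicographic index (Lehmer code) of each delay vector's sort order."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size - (dE - 1) * tau
    if n < 1:
        raise LengthError(
            f"need at least {(dE - 1) * tau + 1} samples for dE={dE}, tau={tau}"
        )
    emb = x[np.arange(n)[:, None] + tau * np.arange(dE)[None, :]]
    if tie_break == "random":
        rng = rng or np.random.default_rng()
        scale = np.ptp(emb) or 1.0
        emb = emb + rng.uniform(0.0, 1e-12 * scale, size=emb.shape)
    order = np.argsort(emb, axis=1, kind="stable")
    # Lehmer code of `order`: digit j counts later entries smaller than order[j]
    codes = np.zeros(n, dtype=np.int64)
    for j in range(dE - 1):
        smaller_later = (order[:, j + 1 :] < order[:, j : j + 1]).sum(axis=1)
        codes = codes * (dE - j) + smaller_later
    return codes


def ordinal_pattern_distribution(
    x: Sequence[float], dE: int, tau: int, tie_break: str = "stable",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Probability vector over the dE! ordinal patterns (lexicographic order
    of the sorting permutations)."""
    codes = _ordinal_codes(np.asarray(x, dtype=float), dE, tau, tie_break, rng)
    counts = np.bincount(codes, minlength=math.factorial(dE))
    return counts / counts.sum()


def permutation_entropy_window(x: Sequence[float], cfg: PEConfig | None = None) -> float:
    """Shannon entropy (base 2) of the ordinal-pattern distribution of ``x``;
    divided by log2(dE!) when ``cfg.normalize``."""
    cfg = cfg or PEConfig()
    p = ordinal_pattern_distribution(x, cfg.dE, cfg.tau, cfg.tie_break)
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    if cfg.normalize:
        h /= math.log2(math.factorial(cfg.dE))
    return h


def pe_by_epoch(epoch: StateEpoch, cfg: PEConfig | None = None) -> pd.Series:
    """Per-channel PE: mean over the non-overlapping windows of the epoch
    (12 windows of 10 s for a 2-minute epoch); trailing partial windows are
    dropped."""
    cfg = cfg or PEConfig()
    w = int(round(cfg.window_s * epoch.fs))
    n_win = epoch.data.shape[1] // w
    if n_win < 1:
        raise LengthError("epoch shorter than one PE window")
    values = {}
    for ch, row in zip(epoch.channel_labels, epoch.data):
        pes = [
            permutation_entropy_window(row[i * w : (i + 1) * w], cfg)
            for i in range(n_win)
        ]
        values[ch] = float(np.mean(pes))
    return pd.Series(values, name="PE")


def regional_pe(
    per_channel_pe: Mapping[str, float],
    frontal: Sequence[str] = FRONTAL_CHANNELS,
    posterior: Sequence[str] = POSTERIOR_CHANNELS,
) -> tuple[float, float]:
    """Arithmetic means of PE over the frontal and posterior six-channel sets."""
    for ch in tuple(frontal) + tuple(posterior):
        if ch not in per_channel_pe:
            raise MontageError(f"channel {ch!r} missing from per-channel PE")
    f = float(np.mean([per_channel_pe[ch] for ch in frontal]))
    p = float(np.mean([per_channel_pe[ch] for ch in posterior]))
    return f, p


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity
# ---------------------------------------------------------------------------

@dataclass
class LZCResult:
    """Normalized LZC value plus a degeneracy flag (all-equal bit matrix)."""

    value: float
    degenerate: bool = False


def binarize_multichannel(window: np.ndarray, cfg: LZCConfig | None = None) -> np.ndarray:
    """Common-average removal, per-channel Hilbert amplitude, binarized at
    each channel's mean amplitude over the window."""
    cfg = cfg or LZCConfig()
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    if window.shape[1] < 2:
        raise LengthError("need at least 2 samples to binarize")
    centered = window - window.mean(axis=0, keepdims=True)
    amp = np.abs(hilbert(centered, axis=1))
    thr = amp.mean(axis=1, keepdims=True)
    if cfg.comparison == "greater":
        bits = amp > thr
    else:
        bits = amp >= thr
    return bits.astype(np.uint8)


def lzc_window(
    window: np.ndarray,
    cfg: LZCConfig | None = None,
    seed: int | None = None,
) -> LZCResult:
    """Surrogate-normalized LZC of one multichannel window.

    The bit matrix is flattened column-major (the spatial pattern at each
    time point, concatenated over time). Each of ``cfg.n_surrogates``
    surrogates shuffles every channel's bit row independently before
    identical flattening and parsing; the result is raw / mean(surrogates).
    """
    cfg = cfg or LZCConfig()
    if seed is None:
        seed = cfg.rng_seed
    bits = binarize_multichannel(window, cfg)
    if bits.min() == bits.max():
        return LZCResult(0.0, degenerate=True)
    raw, surr_mean = _lzc_raw_and_surrogate_mean(
        np.ascontiguousarray(bits), cfg.n_surrogates, seed % 2**31
    )
    return LZCResult(float(raw / surr_mean), degenerate=False)


def lzc_by_epoch(epoch: StateEpoch, cfg: LZCConfig | None = None) -> float:
    """Mean window-level normalized LZC over the non-overlapping windows of
    an epoch (30 windows of 4 s for a 2-minute epoch). The surrogate RNG is
    seeded from (cfg.rng_seed, window index) for bitwise reproducibility."""
    cfg = cfg or LZCConfig()
    w = int(round(cfg.window_s * epoch.fs))
    n_win = epoch.data.shape[1] // w
    if n_win < 1:
        raise LengthError("epoch shorter than one LZC window")
    values = []
    n_degenerate = 0
    for i in range(n_win):
        seed = int(np.random.SeedSequence([cfg.rng_seed, i]).generate_state(1)[0] % 2**31)
        res = lzc_window(epoch.data[:, i * w : (i + 1) * w], cfg, seed)
        if res.degenerate:
            n_degenerate += 1
        else:
            values.append(res.value)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate}/{n_win} degenerate (all-equal) LZC windows skipped",
            stacklevel=2,
        )
    if not values:
        return 0.0
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Tidy output
# ---------------------------------------------------------------------------

def complexity_table(
    epochs: Sequence[StateEpoch],
    pe_cfg: PEConfig | None = None,
    lzc_cfg: LZCConfig | None = None,
    compute_pe: bool = True,
    compute_lzc: bool = True,
) -> pd.DataFrame:
    """Tidy per subject/state table: one PE row per channel, one LZC row per
    epoch (channel = 'global')."""
    rows = []
    for ep in epochs:
        if compute_pe:
            pe = pe_by_epoch(ep, pe_cfg)
            for ch, v in pe.items():
                rows.append((ep.subject_id, ep.state, ch, "PE", v))
        if compute_lzc:
            v = lzc_by_epoch(ep, lzc_cfg)
            rows.append((ep.subject_id, ep.state, "global", "LZC", v))
    return pd.DataFrame(
        rows, columns=["subject_id", "state", "channel", "measure", "value"]
    )


def regional_pe_table(
    table: pd.DataFrame,
    frontal: Sequence[str] = FRONTAL_CHANNELS,
    posterior: Sequence[str] = POSTERIOR_CHANNELS,
) -> pd.DataFrame:
    """Collapse a per-channel PE table to frontal/posterior means per
    subject and state (long format with a ``region`` column)."""
    pe = table[table["measure"] == "PE"]
    rows = []
    for (sid, state), grp in pe.groupby(["subject_id", "state"], sort=False):
        per_ch = dict(zip(grp["channel"], grp["value"]))
        f, p = regional_pe(per_ch, frontal, posterior)
        rows.append((sid, state, "frontal", f))
        rows.append((sid, state, "posterior", p))
    return pd.DataFrame(rows, columns=["subject_id", "state", "region", "value"])
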