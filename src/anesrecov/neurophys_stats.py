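"""Epoch-wise mixed-model inference on EEG complexity, EEG-cognition
associations, and design/power utilities.

The epoch model follows the repeated-measures specification used for
PE/LZC comparisons: a subject-specific random intercept, fixed effects for
the studied epoch (and, for PE, region and the epoch x region interaction),
and a *diagonal heterogeneous* residual covariance — each epoch has its own
residual variance — estimated by restricted maximum likelihood. Fixed
effects use cell-mean coding, so least-squares means and their contrasts
are linear functions of the coefficient vector; post hoc pairwise contrasts
report the estimate, 95% CI, and Bonferroni-corrected p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConstantInputError, DesignError, ParameterError

# ---------------------------------------------------------------------------
# Heteroscedastic random-intercept LMM (REML)
# ---------------------------------------------------------------------------

@dataclass
class EpochLMMResult:
    """REML fit of the epoch model for one measure."""

    measure: str
    beta: pd.Series  # cell means, indexed by (state,) or (state, region)
    cov_beta: np.ndarray
    sigma_subject: float
    sigma_epoch: pd.Series  # residual SD per epoch
    df: int
    states: list[str]
    regions: list[str] | None
    n_subjects: int
    reml_criterion: float
    converged: bool = True

    def _contrast(self, c: np.ndarray) -> tuple[float, float]:
        est = float(c @ self.beta.to_numpy())
        se = float(np.sqrt(c @ self.cov_beta @ c))
        return est, se


def _pattern_groups(df: pd.DataFrame, cell_index: pd.Index) -> list[dict]:
    """Group subjects by their set of observed cells; return, per pattern,
    the stacked responses and the epoch index of each observation."""
    cell_pos = {cell: i for i, cell in enumerate(cell_index)}
    per_subject = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        cells = tuple(sorted(cell_pos[c] for c in grp["_cell"]))
        if len(cells) != len(grp):
            raise DesignError(f"duplicate cell observations for subject {sid}")
        y = grp.set_index("_cell")["value"]
        per_subject.setdefault(cells, []).append(
            y.loc[[cell_index[i] for i in cells]].to_numpy()
        )
    patterns = []
    for cells, ys in per_subject.items():
        patterns.append(dict(cells=np.array(cells, dtype=int), Y=np.vstack(ys)))
    return patterns


def fit_epoch_lmm(
    table: pd.DataFrame,
    measure: str = "LZC",
    value_col: str = "value",
) -> EpochLMMResult:
    """Fit the epoch model by REML.

    ``table`` is long format with columns subject_id, state, ``value_col``
    and, for PE, a region column (the PE model's fixed effects are epoch,
    region, and their interaction, realized as cell means per
    epoch x region). Missing epochs are tolerated; each epoch keeps its own
    residual variance.
    """
    df = table.rename(columns={value_col: "value"}).copy()
    has_region = "region" in df.columns and df["region"].notna().all() and measure == "PE"
    states = list(dict.fromkeys(df["state"]))
    regions = list(dict.fromkeys(df["region"])) if has_region else None
    if len(states) < 2:
        raise DesignError("need at least two epochs")
    counts = df.groupby("state")["subject_id"].nunique()
    if (counts < 3).any():
        raise DesignError("need at least 3 subjects per epoch")

    if has_region:
        df["_cell"] = list(zip(df["state"], df["region"]))
        cell_index = pd.Index(
            [(s, r) for s in states for r in regions], tupleize_cols=False
        )
    else:
        df["_cell"] = df["state"]
        cell_index = pd.Index(states)
    state_of_cell = np.array(
        [states.index(c[0] if has_region else c) for c in cell_index]
    )
    patterns = _pattern_groups(df, cell_index)
    n_subjects = df["subject_id"].nunique()
    n_states = len(states)
    p_cells = len(cell_index)

    # moment-based starting values
    resid_sd = df.groupby("state")["value"].std().reindex(states).fillna(0.1)
    subj_sd = df.groupby("subject_id")["value"].mean().std()
    theta0 = np.log(
        np.concatenate([[max(subj_sd, 1e-3)], np.maximum(resid_sd, 1e-3)])
    )

    def reml(theta: np.ndarray, want_beta: bool = False):
        sig_b2 = math.exp(2.0 * theta[0])
        sig_e2 = np.exp(2.0 * theta[1:])
        XtVX = np.zeros((p_cells, p_cells))
        XtVy = np.zeros(p_cells)
        logdet = 0.0
        quad_parts = []
        for pat in patterns:
            cells = pat["cells"]
            m = cells.size
            V = sig_b2 * np.ones((m, m)) + np.diag(sig_e2[state_of_cell[cells]])
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf
            Vi = np.linalg.inv(V)
            n_i = pat["Y"].shape[0]
            logdet += n_i * 2.0 * np.log(np.diag(L)).sum()
            XtVX[np.ix_(cells, cells)] += n_i * Vi
            XtVy[cells] += Vi @ pat["Y"].sum(axis=0)
            quad_parts.append((pat["Y"], Vi, cells))
        try:
            cov_b = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError:
            return np.inf
        beta = cov_b @ XtVy
        quad = 0.0
        for Y, Vi, cells in quad_parts:
            R = Y - beta[cells][None, :]
            quad += np.einsum("ij,jk,ik->", R, Vi, R)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        crit = logdet + quad + logdet_xvx
        if want_beta:
            return crit, beta, cov_b
        return crit

    res = optimize.minimize(
        reml, theta0, method="L-BFGS-B",
        bounds=[(-8.0, 5.0)] * (1 + n_states),
    )
    if not np.isfinite(res.fun):
        raise DesignError(
            "singular REML fit; consider pooling residual variances across epochs"
        )
    crit, beta, cov_b = reml(res.x, want_beta=True)
    return EpochLMMResult(
        measure=measure,
        beta=pd.Series(beta, index=cell_index),
        cov_beta=cov_b,
        sigma_subject=float(math.exp(res.x[0])),
        sigma_epoch=pd.Series(np.exp(res.x[1:]), index=states),
        df=n_subjects - 1,
        states=states,
        regions=regions,
        n_subjects=n_subjects,
        reml_criterion=float(crit),
        converged=bool(res.success),
    )


def _epoch_contrast_vector(result: EpochLMMResult, a: str, b: str) -> np.ndarray:
    """Least-squares-mean contrast epoch a minus epoch b (averaged over
    regions for the PE model)."""
    cells = list(result.beta.index)
    c = np.zeros(len(cells))
    for state, sign in ((a, 1.0), (b, -1.0)):
        if result.regions:
            members = [i for i, cell in enumerate(cells) if cell[0] == state]
        else:
            members = [i for i, cell in enumerate(cells) if cell == state]
        if not members:
            raise KeyError(f"unknown epoch label {state!r}")
        for i in members:
            c[i] = sign / len(members)
    return c


def pairwise_epoch_contrasts(
    result: EpochLMMResult,
    pairs: Sequence[tuple[str, str]] | None = None,
    family_size: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Post hoc pairwise epoch contrasts with Bonferroni correction.

    The corrected p is min(1, m * p_raw) where m defaults to the number of
    pairs actually tested.
    """
    if pairs is None:
        pairs = list(itertools.combinations(result.states, 2))
    m = family_size if family_size is not None else len(pairs)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, result.df)
    rows = []
    for a, b in pairs:
        c = _epoch_contrast_vector(result, a, b)
        est, se = result._contrast(c)
        if se <= 0:
            tval, p_raw = 0.0, 1.0
        else:
            tval = est / se
            p_raw = 2.0 * stats.t.sf(abs(tval), result.df)
        rows.append(
            dict(
                epoch_a=a,
                epoch_b=b,
                estimate=est,
                se=se,
                ci_low=est - tcrit * se,
                ci_high=est + tcrit * se,
                t=tval,
                p_raw=p_raw,
                p_bonferroni=min(1.0, m * p_raw),
            )
        )
    return pd.DataFrame(rows)


def region_contrast_at(
    result: EpochLMMResult, state: str, region_a: str = "frontal",
    region_b: str = "posterior", ci_level: float = 0.95,
) -> dict:
    """Frontal-minus-posterior (by default) contrast at one epoch."""
    if not result.regions:
        raise DesignError("model has no region factor")
    cells = list(result.beta.index)
    c = np.zeros(len(cells))
    c[cells.index((state, region_a))] = 1.0
    c[cells.index((state, region_b))] = -1.0
    est, se = result._contrast(c)
    tval = est / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(tval), result.df) if se > 0 else 1.0
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, result.df)
    return dict(
        state=state, estimate=est, se=se,
        ci_low=est - tcrit * se, ci_high=est + tcrit * se, p=p,
    )


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

def spearman_eeg_cognition(
    eeg_values: Sequence[float],
    impairments: Sequence[float],
    exact_below_n: int = 10,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with a two-sided p-value.

    For n >= ``exact_below_n`` the t approximation is used; below that, a
    permutation p-value (exhaustive for n <= 8, Monte-Carlo otherwise).
    """
    x = np.asarray(eeg_values, dtype=float)
    y = np.asarray(impairments, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ParameterError("need paired samples with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    if x.size >= exact_below_n:
        return float(rho), float(p)

    def statistic(perm_y):
        return stats.spearmanr(x, perm_y).statistic

    if x.size <= 8:
        perms = itertools.permutations(y)
        vals = np.array([statistic(np.array(p_)) for p_ in perms])
    else:
        rng = np.random.default_rng(seed)
        vals = np.array(
            [statistic(rng.permutation(y)) for _ in range(n_resamples)]
        )
    p_exact = float(np.mean(np.abs(vals) >= abs(rho) - 1e-12))
    return float(rho), p_exact


def association_table(
    eeg_wide: pd.DataFrame,
    impairment_wide: pd.DataFrame,
    on: str = "subject_id",
) -> pd.DataFrame:
    """All-pairs Spearman associations between EEG measure columns and
    impairment columns, joined on subject."""
    merged = eeg_wide.merge(impairment_wide, on=on)
    rows = []
    for ecol in [c for c in eeg_wide.columns if c != on]:
        for icol in [c for c in impairment_wide.columns if c != on]:
            sub = merged[[ecol, icol]].dropna()
            r, p = spearman_eeg_cognition(sub[ecol], sub[icol])
            rows.append(dict(eeg_measure=ecol, outcome=icol, n=len(sub), r=r, p=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design utilities
# ---------------------------------------------------------------------------

def power_unpaired_t(
    diff: float, sd: float, n_per_arm: int, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided two-sample t test via the noncentral t
    distribution (df = 2n-2, noncentrality (diff/sd) * sqrt(n/2))."""
    if sd <= 0 or n_per_arm < 2 or not 0 < alpha < 1:
        raise ParameterError("require sd > 0, n_per_arm >= 2, alpha in (0,1)")
    df = 2 * n_per_arm - 2
    ncp = (diff / sd) * math.sqrt(n_per_arm / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Corrected per-test significance level alpha / k."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0,1)")
    return alpha / k
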