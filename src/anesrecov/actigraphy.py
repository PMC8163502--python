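"""Actigraphy scoring, hourly summaries, cosinor rhythm fit, and the
time x group ANOVA.

Per-minute activity counts are classified into inactive/active bouts with
the Cole-Kripke weighted moving sum for 1-minute epochs: the score of
minute t is

    S_t = P * (W-4 A_{t-4} + ... + W0 A_t + ... + W+2 A_{t+2}),

and the minute is scored inactive (sleep) when S_t < 1. The published
1-minute coefficients (P = 0.001; W = 106, 54, 58, 76, 230, 74, 67 for
minutes t-4..t+2) are stored in configuration so alternates can be swapped.
Series boundaries are zero-padded.

Hourly minutes of inactivity (among worn minutes) feed a fixed-period 24-h
cosinor, y = M + A cos(2 pi (t - phi)/24), fitted by least squares on the
cosine/sine basis, and a two-way fixed-effects ANOVA with time (hour) and
treatment group as factors, using marginal (type-II) sums of squares to
tolerate the asynchronous missing hours produced by non-wear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DataError, DesignError, ParameterError

#: Cole-Kripke 1-minute rescoring weights for minutes t-4 .. t+2.
COLE_KRIPKE_1MIN = dict(
    scale=0.001,
    weights=(106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0),
    offset=4,  # first weight applies to minute t-4
    threshold=1.0,
)


def cole_kripke_scores(counts: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Weighted moving-sum score per minute (zero-padded boundaries)."""
    p = params or COLE_KRIPKE_1MIN
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise DataError("negative activity counts")
    w = np.asarray(p["weights"], dtype=float)
    off = int(p["offset"])
    padded = np.concatenate([np.zeros(off), counts, np.zeros(len(w) - off - 1)])
    # valid-mode correlation aligns window t-off .. t+(len(w)-off-1) on t
    return p["scale"] * np.correlate(padded, w, mode="valid")


def score_sleep_cole_kripke(
    minutes: pd.DataFrame, params: dict | None = None
) -> pd.DataFrame:
    """Add an ``inactive`` column to a per-minute (subject_id, timestamp_min,
    counts, worn) table; classification is only meaningful where worn."""
    p = params or COLE_KRIPKE_1MIN
    out = []
    for sid, grp in minutes.groupby("subject_id", sort=False):
        grp = grp.sort_values("timestamp_min").copy()
        ts = grp["timestamp_min"].to_numpy()
        if ts.size > 1 and not np.all(np.diff(ts) == 1):
            raise DataError(f"non-contiguous minute series for subject {sid}")
        s = cole_kripke_scores(grp["counts"].to_numpy(), p)
        grp["inactive"] = (s < p["threshold"]) & grp["worn"].to_numpy()
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def hourly_inactivity(
    scored: pd.DataFrame, max_consecutive_nonworn: int = 5
) -> pd.DataFrame:
    """Minutes of inactivity per clock hour and subject.

    An hour is excluded entirely when it contains a non-wear run longer than
    ``max_consecutive_nonworn`` minutes (the wear-time validation rule);
    otherwise inactive minutes are counted among worn minutes.
    """
    df = scored.copy()
    df["hour"] = df["timestamp_min"] // 60
    rows = []
    group_cols = ["subject_id", "hour"] + (["group"] if "group" in df.columns else [])
    for keys, grp in df.groupby(group_cols, sort=True):
        worn = grp.sort_values("timestamp_min")["worn"].to_numpy()
        # longest run of consecutive non-worn minutes
        run = best = 0
        for w in worn:
            run = 0 if w else run + 1
            best = max(best, run)
        if best > max_consecutive_nonworn:
            continue
        rec = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        rec["inactive_min"] = int((grp["inactive"] & grp["worn"]).sum())
        rec["worn_min"] = int(grp["worn"].sum())
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cosinor
# ---------------------------------------------------------------------------

@dataclass
class CosinorFit:
    """Fixed-period cosinor: y = mesor + amplitude*cos(2 pi (t - acrophase)/period)."""

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float = 24.0
    r_squared: float = float("nan")

    def predict(self, t_hours: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (np.asarray(t_hours, dtype=float) - self.acrophase_h)
            / self.period_h
        )


def cosinor_fit(
    t_hours: np.ndarray, y: np.ndarray, period_h: float = 24.0
) -> CosinorFit:
    """Least-squares cosinor with fixed period; acrophase is the clock time
    of the fitted peak, wrapped to [0, period)."""
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    if period_h <= 0:
        raise ParameterError("period must be positive")
    if np.unique(np.mod(t, period_h)).size < 3:
        raise DesignError("need >= 3 distinct time points within a period")
    if np.ptp(np.mod(t, period_h)) <= period_h / 2 and np.unique(
        np.mod(t, period_h)
    ).size < 4:
        raise DesignError("time points must span more than half a period")
    w = 2.0 * np.pi * t / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = coef
    amplitude = float(np.hypot(bc, bs))
    acrophase = float(np.arctan2(bs, bc) * period_h / (2.0 * np.pi)) % period_h
    if amplitude == 0:
        acrophase = 0.0
    resid = y - X @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return CosinorFit(float(mesor), amplitude, acrophase, period_h, r2)


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

def inactivity_anova(hourly: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA on hourly inactivity with factors time
    (hour) and treatment group plus their interaction; marginal (type-II)
    sums of squares; reports F, p, and the share of total variance."""
    df = hourly.copy()
    for col in ("hour", "group", "inactive_min"):
        if col not in df.columns:
            raise DesignError(f"missing column {col!r}")
    if df["group"].nunique() < 2 or df["hour"].nunique() < 2:
        raise DesignError("need >= 2 groups and >= 2 time levels")
    cell_n = df.groupby(["hour", "group"]).size().unstack(fill_value=0)
    if (cell_n == 0).any().any():
        raise DesignError("empty hour x group cells make the interaction inestimable")
    model = smf.ols("inactive_min ~ C(hour) * C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_total = table["sum_sq"].sum()
    table = table.rename(
        index={
            "C(hour)": "time",
            "C(group)": "group",
            "C(hour):C(group)": "time_x_group",
            "Residual": "residual",
        }
    )
    table["variance_share"] = table["sum_sq"] / ss_total
    return table
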