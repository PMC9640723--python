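"""Two-isoform usage, switch detection, trend testing and survival analysis.

Isoform usage is each transcript's expression normalized to total gene
expression (isoform fraction, IF).  A sample is dominated by one isoform
when the other's IF falls below ``both_threshold`` (default 0.2); otherwise
it expresses both.  A patient counts as *exposed* to the short isoform when
any of their tumors is short- or both-dominant.

The between-group usage test is deliberately simple: a two-sided rank-sum
test on per-sample IF_short with a Benjamini-Hochberg correction across
tested genes and an effect-size gate on dIF (the difference of group mean
IF_short).  Survival uses Cox proportional hazards (Efron tie handling, via
lifelines) and Kaplan-Meier medians with log-log confidence intervals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BOTH_THRESHOLD = 0.2
DIF_THRESHOLD = 0.1


# ---------------------------------------------------------------------------
# usage and exposure
# ---------------------------------------------------------------------------

def compute_usage(counts: pd.DataFrame, both_threshold: float = BOTH_THRESHOLD,
                  ) -> pd.DataFrame:
    """Per-sample isoform fractions and dominance calls.

    Input columns: sample_id, isoform_long, isoform_short.  Output adds
    total, if_short, if_long (NaN when total = 0) and dominance in
    {long, short, both, none}.
    """
    if (counts[["isoform_long", "isoform_short"]] < 0).any().any():
        raise ValueError("negative isoform counts")
    df = counts.copy()
    df["total"] = df["isoform_long"] + df["isoform_short"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["if_short"] = np.where(df["total"] > 0, df["isoform_short"] / df["total"], np.nan)
    df["if_long"] = 1.0 - df["if_short"]

    def _dominance(row) -> str:
        if row["total"] == 0:
            return "none"
        if min(row["if_short"], row["if_long"]) >= both_threshold:
            return "both"
        return "short" if row["if_short"] > row["if_long"] else "long"

    df["dominance"] = df.apply(_dominance, axis=1)
    return df


def exposure_by_patient(usage: pd.DataFrame) -> Optional[bool]:
    """True iff any tumor of the patient is short- or both-dominant.

    Returns None (patient excluded) when every tumor has zero total counts.
    """
    expressed = usage[usage["total"] > 0]
    if expressed.empty:
        logger.warning("patient has no tumor with isoform expression; exposure undefined")
        return None
    return bool(expressed["dominance"].isin(["short", "both"]).any())


# ---------------------------------------------------------------------------
# Mantel-Haenszel trend test
# ---------------------------------------------------------------------------

@dataclass
class MHResult:
    statistic: float
    p_value: float
    n_strata: int


def mantel_haenszel_trend(tables: Sequence[np.ndarray], correction: bool = True) -> MHResult:
    """Mantel-Haenszel chi-squared test across 2x2 strata (1 df).

    Each table is [[a, b], [c, d]].  The statistic uses the hypergeometric
    variance (the (n-1) form, matching R's ``mantelhaen.test``), with a 0.5
    continuity correction by default.  With a single stratum this equals the
    Yates-corrected chi-square scaled by (n-1)/n.
    """
    tables = [np.asarray(t, dtype=float) for t in tables]
    if not tables:
        raise ValueError("need at least one 2x2 stratum")
    num = 0.0
    expected = 0.0
    var = 0.0
    used = 0
    for t in tables:
        if t.shape != (2, 2):
            raise ValueError(f"each stratum must be 2x2, got {t.shape}")
        n = t.sum()
        r1, r2 = t.sum(axis=1)
        c1, c2 = t.sum(axis=0)
        if n < 2 or r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
            continue  # degenerate stratum carries no information
        num += t[0, 0]
        expected += r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        used += 1
    if used == 0 or var == 0:
        raise ValueError("all strata degenerate: no informative margins")
    cc = 0.5 if correction else 0.0
    stat = (max(abs(num - expected) - cc, 0.0)) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return MHResult(statistic=float(stat), p_value=p, n_strata=used)


def dominance_tables_by_group(usage: pd.DataFrame, groups: Sequence[str],
                              strata_col: str | None = None) -> list[np.ndarray]:
    """Build 2x2 tables (group membership x short-vs-long dominance).

    With ``strata_col`` given, one table per stratum level; otherwise one
    table per consecutive group pair (groups[i] vs groups[i+1]).
    """
    sub = usage[usage["dominance"].isin(["short", "long"])]
    tables = []
    if strata_col is None:
        for g1, g2 in zip(groups, groups[1:]):
            a = sub[(sub["group"] == g1) & (sub["dominance"] == "short")].shape[0]
            b = sub[(sub["group"] == g1) & (sub["dominance"] == "long")].shape[0]
            c = sub[(sub["group"] == g2) & (sub["dominance"] == "short")].shape[0]
            d = sub[(sub["group"] == g2) & (sub["dominance"] == "long")].shape[0]
            tables.append(np.array([[a, b], [c, d]], dtype=float))
    else:
        for _, stratum in sub.groupby(strata_col):
            a = stratum[(stratum["group"] == groups[0]) & (stratum["dominance"] == "short")].shape[0]
            b = stratum[(stratum["group"] == groups[0]) & (stratum["dominance"] == "long")].shape[0]
            c = stratum[(stratum["group"] != groups[0]) & (stratum["dominance"] == "short")].shape[0]
            d = stratum[(stratum["group"] != groups[0]) & (stratum["dominance"] == "long")].shape[0]
            tables.append(np.array([[a, b], [c, d]], dtype=float))
    return tables


# ---------------------------------------------------------------------------
# isoform switch detection
# ---------------------------------------------------------------------------

@dataclass
class SwitchResult:
    dif: float
    p_value: float
    q_value: float
    is_switch: bool
    n_a: int
    n_b: int


def detect_isoform_switch(if_short_a: Sequence[float], if_short_b: Sequence[float],
                          dif_threshold: float = DIF_THRESHOLD,
                          alpha: float = 0.05,
                          q_value: float | None = None) -> SwitchResult:
    """Test one gene for differential transcript usage between two groups.

    dIF = mean IF_short(B) - mean IF_short(A); p from a two-sided rank-sum
    test on per-sample IF_short.  The switch flag requires |dIF| >=
    ``dif_threshold`` and q < alpha; when testing several genes, compute q
    with :func:`benjamini_hochberg` and pass it in, otherwise q = p.
    """
    a = np.asarray([x for x in if_short_a if not np.isnan(x)], dtype=float)
    b = np.asarray([x for x in if_short_b if not np.isnan(x)], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >=3 samples with defined IF per group, got {len(a)}/{len(b)}")
    res = stats.mannwhitneyu(b, a, alternative="two-sided")
    p = float(res.pvalue)
    q = p if q_value is None else q_value
    dif = float(b.mean() - a.mean())
    return SwitchResult(dif=dif, p_value=p, q_value=q,
                        is_switch=bool(abs(dif) >= dif_threshold and q < alpha),
                        n_a=len(a), n_b=len(b))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    return multipletests(p_values, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class CoxTerm:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


def fit_cox(records: pd.DataFrame, covariates: Sequence[str] = ("exposure",),
            duration_col: str = "os_months", event_col: str = "event",
            ) -> list[CoxTerm]:
    """Cox proportional-hazards fit (Efron tie handling) via lifelines.

    ``covariates`` is an explicit specification: univariate exposure for the
    breast analysis, exposure plus recurrent status for the ovarian one.
    Returns hazard ratio, 95% Wald CI (exp(coef +/- 1.96 SE)) and Wald p per
    term.  Non-convergence propagates as an error.
    """
    from lifelines import CoxPHFitter

    df = records[[duration_col, event_col, *covariates]].copy()
    for c in covariates:
        if df[c].dtype == bool:
            df[c] = df[c].astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    out = []
    for term in covariates:
        coef = float(cph.params_[term])
        se = float(cph.standard_errors_[term])
        out.append(CoxTerm(
            term=term,
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p_value=float(cph.summary.loc[term, "p"]),
        ))
    return out


@dataclass
class KMArm:
    arm: str
    n: int
    n_events: int
    median: float
    ci_low: float
    ci_high: float  # inf for an open-ended interval


def km_medians(records: pd.DataFrame, by: str = "exposure",
               duration_col: str = "os_months", event_col: str = "event") -> list[KMArm]:
    """Kaplan-Meier median survival with 95% CI per arm.

    An undefined median (curve never crossing 0.5) or CI bound is reported
    as inf rather than an error.  Requires >=2 events per arm.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    out = []
    for value, sub in records.groupby(by):
        n_events = int(sub[event_col].sum())
        if n_events < 2:
            raise ValueError(f"arm {by}={value}: need >=2 events, got {n_events}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], event_observed=sub[event_col])
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        out.append(KMArm(arm=str(value), n=len(sub), n_events=n_events,
                         median=float(kmf.median_survival_time_),
                         ci_low=lo, ci_high=hi))
    return sorted(out, key=lambda a: a.arm)


def plot_km(records: pd.DataFrame, path: str, by: str = "exposure",
            duration_col: str = "os_months", event_col: str = "event") -> None:
    """Optional Kaplan-Meier plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for value, sub in records.groupby(by):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], event_observed=sub[event_col], label=f"{by}={value}")
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("overall survival (months)")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
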