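"""IHC H-score computation and cohort-level association/survival statistics.

The H-score summarizes an immunostained section as
``percent stained epithelial cells x staining intensity`` with intensity
graded 0-3, giving a 0-300 scale.  Positivity can be called either against
the cohort median H-score (default threshold 30, strict) or against a fixed
25%-stained-cells rule.  Cohort association uses Pearson's chi-square with a
Fisher-exact fallback for sparse 2x2 tables, Benjamini-Hochberg step-up
adjustment for multiplicity, and Kaplan-Meier / log-rank comparisons for
censored survival outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SUBTYPES = ("basal-like", "ERBB2+", "luminal A", "luminal B")

MEDIAN_HSCORE_THRESHOLD = 30.0
PERCENT_CELLS_THRESHOLD = 25.0


def h_score(percent_stained: float, intensity: int) -> float:
    """H-score = percent stained cells (0-100) x intensity (integer 0-3)."""
    if not 0 <= percent_stained <= 100:
        raise ValueError("percent_stained must be in [0, 100]")
    if intensity != int(intensity) or not 0 <= int(intensity) <= 3:
        raise ValueError("intensity must be an integer in 0..3")
    return float(percent_stained) * int(intensity)


def classify_positive(
    percent_stained: float,
    intensity: int,
    rule: str = "median_hscore",
    threshold: float | None = None,
    strict: bool = True,
) -> bool:
    """Positivity call under the median-H-score or percent-cells rule.

    ``median_hscore``: positive iff H-score exceeds the threshold (default 30,
    strict ``>`` so roughly half the cohort is positive when 30 is the cohort
    median; pass ``strict=False`` for ``>=``).  ``percent_cells``: positive
    iff at least 25% of tumor cells stain, regardless of intensity.
    """
    if rule == "median_hscore":
        thr = MEDIAN_HSCORE_THRESHOLD if threshold is None else threshold
        h = h_score(percent_stained, intensity)
        return h > thr if strict else h >= thr
    if rule == "percent_cells":
        thr = PERCENT_CELLS_THRESHOLD if threshold is None else threshold
        if not 0 <= percent_stained <= 100:
            raise ValueError("percent_stained must be in [0, 100]")
        return percent_stained >= thr
    raise ValueError(f"unknown positivity rule {rule!r}")


def round_half_away(x: float) -> int:
    """Round half away from zero (matches hand-rounded printed percentages)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def positivity_summary(cohort: pd.DataFrame, group_by: str, rule: str = "median_hscore", **rule_kwargs) -> pd.DataFrame:
    """Positive counts and integer percents per stratum of ``group_by``.

    ``cohort`` needs ``percent_stained`` and ``intensity`` columns.  Percent
    is rounded half-away-from-zero; empty strata report a missing percent.
    The overall row aggregates the strata exactly.
    """
    df = cohort.copy()
    df["positive"] = [
        classify_positive(p, i, rule=rule, **rule_kwargs)
        for p, i in zip(df["percent_stained"], df["intensity"])
    ]
    rows = []
    for stratum, sub in df.groupby(group_by, sort=False, dropna=False, observed=False):
        rows.append({group_by: stratum, "n_positive": int(sub["positive"].sum()), "n_total": len(sub)})
    rows.append({group_by: "overall", "n_positive": int(df["positive"].sum()), "n_total": len(df)})
    out = pd.DataFrame(rows)
    out["percent"] = [
        float(round_half_away(100.0 * p / t)) if t else np.nan
        for p, t in zip(out["n_positive"], out["n_total"])
    ]
    return out


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    dof: int
    method: str  # "pearson" | "fisher" | "pearson-lowcount"


def chi2_association(table) -> AssociationResult:
    """Pearson chi-square association test on a 2xK contingency table.

    Falls back to Fisher's exact test when any expected count is below 5 and
    the table is 2x2 (the classical applicability condition); larger sparse
    tables keep the Pearson statistic but are flagged ``pearson-lowcount``.
    A table with zero statistic (identical row profiles) returns p = 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table must contain nonnegative integers")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected < 5):
        if obs.shape == (2, 2):
            _, p_f = stats.fisher_exact(obs.astype(int))
            return AssociationResult(float(chi2), float(p_f), int(dof), "fisher")
        warnings.warn("expected count < 5 in a table larger than 2x2; Pearson p may be inaccurate")
        return AssociationResult(float(chi2), float(p), int(dof), "pearson-lowcount")
    return AssociationResult(float(chi2), float(p), int(dof), "pearson")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class KMResult:
    curves: Mapping[str, pd.DataFrame]   # per group: timeline, survival
    medians: Mapping[str, float]          # NaN when the median is never reached
    statistic: float
    p_value: float


def km_logrank(times, events, groups) -> KMResult:
    """Kaplan-Meier curves per group, median survival, and the log-rank test.

    The median is the first time the product-limit estimate drops to 0.5 or
    below (NaN when it never does).  Identical groups give statistic 0, p = 1.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for g in pd.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        sf = kmf.survival_function_
        curves[g] = sf.reset_index().set_axis(["time", "survival"], axis=1)
        medians[g] = float(kmf.median_survival_time_)  # inf -> not reached
        if not np.isfinite(medians[g]):
            medians[g] = float("nan")
    res = multivariate_logrank_test(times, groups, events)
    return KMResult(curves=curves, medians=medians,
                    statistic=float(res.test_statistic), p_value=float(res.p_value))


def table_one(cohort: pd.DataFrame, covariates, rule: str = "median_hscore", adjust: bool = True) -> pd.DataFrame:
    """Cohort characteristics vs positivity, chi-square per covariate, BH-adjusted.

    For each categorical covariate, builds the positive/negative x category
    contingency table and reports the association test; p-values across
    covariates are BH-adjusted when ``adjust`` is set.
    """
    df = cohort.copy()
    df["positive"] = [
        classify_positive(p, i, rule=rule)
        for p, i in zip(df["percent_stained"], df["intensity"])
    ]
    rows = []
    for cov in covariates:
        tab = pd.crosstab(df["positive"], df[cov])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append({"covariate": cov, "statistic": np.nan, "p_value": np.nan, "method": "degenerate"})
            continue
        res = chi2_association(tab.to_numpy())
        rows.append({"covariate": cov, "statistic": res.statistic, "p_value": res.p_value, "method": res.method})
    out = pd.DataFrame(rows)
    if adjust and out["p_value"].notna().any():
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
        out["p_adjusted"] = adj
    return out


def plot_km(result: KMResult, path, ylabel: str = "survival probability") -> None:
    """Step-plot of the per-group Kaplan-Meier curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, curve in result.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(g))
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel(ylabel)
    ax.legend()
    ax.set_title(f"log-rank p = {result.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
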