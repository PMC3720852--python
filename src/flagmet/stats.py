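"""Statistical procedures used around the pipeline: the per-experiment
proportion transform for cytokine concentrations, a one-tailed Mann-Whitney
U test (exact for small untied samples), Kruskal-Wallis across groups, and
Spearman rank association with multiple-testing adjustment.

Rank statistics are delegated to scipy; this module fixes the conventions
(one-tailed alternatives, exact-vs-asymptotic mode selection, tie handling)
and the output layout.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# proportion transform


def to_proportions(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert concentrations to within-experiment proportions.

    Each value is divided by the sum of all treatment values from the same
    experiment, which removes day-to-day scale differences between
    independent experiments.  Input columns: ``experiment``, ``treatment``,
    and a value column (``concentration`` or ``value``).  Proportions within
    one experiment sum to 1.
    """
    value_col = "concentration" if "concentration" in raw.columns else "value"
    for col in ("experiment", "treatment", value_col):
        if col not in raw.columns:
            raise StatsError(f"missing column {col!r}")
    df = raw.copy()
    if (df[value_col] < 0).any():
        raise StatsError("negative concentrations")
    sums = df.groupby("experiment")[value_col].transform("sum")
    zero = df.loc[sums <= 0, "experiment"].unique()
    if len(zero):
        raise StatsError(f"experiment(s) with all-zero values: {sorted(zero)}")
    counts = df.groupby("experiment")["treatment"].transform("count")
    if (counts < 2).any():
        raise StatsError("every experiment needs at least 2 treatments")
    df["proportion"] = df[value_col] / sums
    return df


# --------------------------------------------------------------------------
# Mann-Whitney U


class MwuResult(NamedTuple):
    U: float
    p: float
    mode: str  # "exact", "asymptotic" or "degenerate-ties"


def mann_whitney_one_tailed(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> MwuResult:
    """One-tailed Mann-Whitney U test.

    The p-value is exact (full enumeration of rank arrangements) when the
    pooled sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie correction is used.  The mode actually
    used is recorded in the result.  Completely tied data (zero rank
    variance) carries no evidence either way and returns p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise StatsError(f"alternative must be greater or less, got {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        u = len(x) * len(y) / 2.0
        return MwuResult(U=u, p=1.0, mode="degenerate-ties")
    if not has_ties and len(pooled) <= 12:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return MwuResult(U=float(res.statistic), p=float(res.pvalue), mode="exact")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return MwuResult(U=float(res.statistic), p=float(res.pvalue), mode="asymptotic")


# --------------------------------------------------------------------------
# Kruskal-Wallis


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis H with mid-rank tie correction and chi-square p-value."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    for g in arrays:
        if len(g) == 0:
            raise StatsError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations identical: no rank variation at all
        return KruskalResult(H=0.0, df=len(groups) - 1, p=1.0)
    H, p = sps.kruskal(*arrays)
    return KruskalResult(H=float(H), df=len(groups) - 1, p=float(p))


# --------------------------------------------------------------------------
# Spearman with multiple-testing adjustment


def spearman_with_adjustment(
    abundance: dict[str, Sequence[float]],
    biomarker: Sequence[float],
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Spearman rank correlation of each species' abundances with a biomarker.

    Returns one row per species with rho, the raw p (t approximation) and
    the p adjusted across species by ``bonferroni`` (default) or ``bh``
    (Benjamini-Hochberg).  Species whose abundance vector is constant have
    undefined rho and are flagged rather than adjusted.
    """
    if method not in ("bonferroni", "bh"):
        raise StatsError(f"unknown adjustment method {method!r}")
    if not abundance:
        raise StatsError("need at least one species")
    biomarker = np.asarray(list(biomarker), dtype=float)
    if len(biomarker) < 3:
        raise StatsError("need at least 3 paired observations")
    rows = []
    for sp, vec in abundance.items():
        vec = np.asarray(list(vec), dtype=float)
        if len(vec) != len(biomarker):
            raise StatsError(f"species {sp!r}: length mismatch with biomarker vector")
        if np.ptp(vec) == 0 or np.ptp(biomarker) == 0:
            rows.append({"species": sp, "rho": np.nan, "p": np.nan, "constant": True})
            continue
        rho, p = sps.spearmanr(vec, biomarker)
        rows.append({"species": sp, "rho": float(rho), "p": float(p), "constant": False})
    df = pd.DataFrame(rows).set_index("species")
    df["p_adj"] = np.nan
    testable = ~df["constant"]
    if testable.any():
        sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
        # adjust across ALL species tested, counting constant-vector species
        # in the correction denominator would be wrong: they produced no test
        _, p_adj, _, _ = multipletests(df.loc[testable, "p"], method=sm_method)
        df.loc[testable, "p_adj"] = p_adj
    df["method"] = method
    return df.reset_index()
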