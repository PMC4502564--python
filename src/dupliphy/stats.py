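"""Downstream statistics: conservation-vs-divergence regression,
tissue-specificity comparisons, and highest-tissue enrichment tests.

Small-sample tests are exact: Fisher's Exact two-sided p-values sum the
hypergeometric probabilities of all same-margin tables no more probable
than the observed one, and Mann-Whitney U p-values are computed by exact
enumeration when both samples are small and untied. Families of related
tests are Bonferroni-corrected per analysis panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionFit",
    "conserved_proportion_by_pair",
    "fit_linear_regression",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "bonferroni",
    "highest_tissue_enrichment",
    "specificity_comparison",
    "significance_stars",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    f_pvalue: float
    slope_t_pvalue: float
    n_points: int


def fit_linear_regression(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> RegressionFit:
    """Ordinary least-squares fit of y on x.

    The fit is tested with an F-statistic and the slope with a two-sided
    t-test (p-values require >= 3 points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("at least two points are required")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_pvalue=float(model.f_pvalue) if x.size >= 3 else math.nan,
        slope_t_pvalue=float(model.pvalues[1]) if x.size >= 3 else math.nan,
        n_points=int(x.size),
    )


def mann_whitney_u(
    sample_a: Sequence[float] | np.ndarray, sample_b: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration p-value when both samples have <= 10 observations and
    there are no ties; normal approximation with tie correction otherwise.
    Returns (U statistic for sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    result = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> tuple[float, float]:
    """Fisher's Exact test on a 2x2 count table.

    Two-sided p-value by the probability-mass rule (sum over same-margin
    tables with probability <= the observed table's); the reported odds
    ratio is the conditional maximum-likelihood estimate.
    Returns (odds_ratio, p_value).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("negative entries")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(int)
    if arr.sum() == 0:
        raise ValueError("at least one entry must be nonzero")
    _, pvalue = sps.fisher_exact(arr, alternative="two-sided")
    try:
        odds = float(sps.contingency.odds_ratio(arr, kind="conditional").statistic)
    except Exception:
        odds = math.nan
    return odds, float(pvalue)


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m); m defaults to the family size."""
    pvals = list(pvalues)
    if any(not (0 <= p <= 1) for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, p * m) for p in pvals]


def significance_stars(p_adjusted: float) -> str:
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return ""


def conserved_proportion_by_pair(
    records: pd.DataFrame,
    ks_per_pair: Mapping[tuple[str, str], float],
    baselines: Mapping[tuple[str, str], np.ndarray] | None = None,
    cutoffs: Mapping[tuple[str, str], float] | None = None,
    ka_per_pair: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Per-species-pair fraction of duplicate pairs classified CONSERVED.

    When baseline distances and cutoffs are supplied, the single-copy
    analogue — the fraction of single-copy ortholog pairs whose E_S1,S2 is
    at or below the pair's cutoff ("functionally conserved" single-copy
    genes) — is computed alongside.
    """
    from .classification import species_pair_key

    rows = []
    grouped = records.groupby(["focal_species", "outgroup_species"], sort=True)
    for (focal, outgroup), group in grouped:
        pair = species_pair_key(focal, outgroup)
        if pair not in ks_per_pair:
            raise ValueError(f"missing K_s for species pair {pair}")
        n_total = len(group)
        n_conserved = int((group["label"] == "CONSERVED").sum())
        row = {
            "species_1": pair[0],
            "species_2": pair[1],
            "ks_median": float(ks_per_pair[pair]),
            "n_conserved": n_conserved,
            "n_total": n_total,
            "proportion_conserved": n_conserved / n_total,
        }
        if ka_per_pair is not None and pair in ka_per_pair:
            row["ka_median"] = float(ka_per_pair[pair])
        if baselines is not None and cutoffs is not None and pair in baselines:
            base = np.asarray(baselines[pair], dtype=float)
            row["proportion_conserved_single_copy"] = float(
                np.mean(base <= cutoffs[pair])
            )
            row["n_single_copy"] = int(base.size)
        rows.append(row)
    return pd.DataFrame(rows)


def highest_tissue_enrichment(
    tables: Mapping[str, Mapping[str, int]],
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Fisher tests of highest-expression tissue composition.

    ``tables`` maps each gene group (e.g. single-copy / outgroup /
    conserved / neofunctionalized) to its per-tissue counts of genes with
    highest expression in that tissue. For every tissue and unordered group
    pair a 2x2 table (in-tissue vs not, group A vs B) is tested; the
    Bonferroni family is all tissue x group-pair tests of the panel.
    """
    if len(tables) < 2:
        raise ValueError("at least two groups are required")
    totals = {g: sum(c.values()) for g, c in tables.items()}
    empty = [g for g, n in totals.items() if n == 0]
    if empty:
        raise ValueError(f"group(s) with zero genes: {empty}")
    if tissues is None:
        tissues = sorted({t for counts in tables.values() for t in counts})
    groups = list(tables)
    rows = []
    for tissue in tissues:
        for i, g_a in enumerate(groups):
            for g_b in groups[i + 1 :]:
                a = int(tables[g_a].get(tissue, 0))
                b = totals[g_a] - a
                c = int(tables[g_b].get(tissue, 0))
                d = totals[g_b] - c
                odds, p = fisher_exact_2x2([[a, b], [c, d]])
                rows.append(
                    {
                        "tissue": tissue,
                        "group_a": g_a,
                        "group_b": g_b,
                        "a": a,
                        "b": b,
                        "c": c,
                        "d": d,
                        "odds_ratio": odds,
                        "p": p,
                    }
                )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = bonferroni(frame["p"].tolist())
    frame["stars"] = [significance_stars(p) for p in frame["p_adjusted"]]
    frame.attrs["bonferroni_m"] = len(frame)
    return frame


def specificity_comparison(
    group_scores: Mapping[str, Sequence[float]],
    single_copy_scores: Sequence[float],
) -> pd.DataFrame:
    """Mann-Whitney comparison of each group's tissue specificities against
    the pooled single-copy distribution, Bonferroni-corrected over groups."""
    single = np.asarray(single_copy_scores, dtype=float)
    if single.size == 0:
        raise ValueError("empty single-copy reference")
    rows = []
    for group, scores in group_scores.items():
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValueError(f"empty group: {group}")
        u, p = mann_whitney_u(scores, single)
        rows.append(
            {
                "group": group,
                "n": int(scores.size),
                "median_specificity": float(np.median(scores)),
                "single_copy_median": float(np.median(single)),
                "U": u,
                "p": p,
            }
        )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = bonferroni(frame["p"].tolist())
    frame["stars"] = [significance_stars(p) for p in frame["p_adjusted"]]
    frame.attrs["bonferroni_m"] = len(frame)
    return frame
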