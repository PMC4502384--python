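"""The two headline statistical procedures and gene-set binding summaries.

* The motif-association screen correlates predicted promoter binding
  (occupancy scores) with observed ChIP enrichment, per motif and factor,
  and categorizes correlations: high (> 0.19), negative (< 0), else medium;
  between-factor differences are shared (< 0.04), differential (> 0.14),
  else intermediate.
* The site-strength comparison pools the −log10 p-values of non-overlapping
  motif sites from co-bound vs. single-factor promoters and applies a
  one-sided Mann-Whitney U test ("co-bound stronger") at α = 0.05.
* Gene-set summaries report the fraction of each set bound by each factor
  with a hypergeometric enrichment p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_engine import MotifSite
from .peak_annotation import CoBindingTable

R_HIGH = 0.19          # correlation called "high"
DELTA_SHARED = 0.04    # |r_A − r_B| below which a motif is shared
DELTA_DIFFERENTIAL = 0.14
ALPHA = 0.05


@dataclass(frozen=True)
class StrengthCompareResult:
    motif_id: str
    n_cobound: int
    n_single: int
    u_statistic: Optional[float]
    p_cobound_greater: Optional[float]
    p_single_greater: Optional[float]
    direction: Optional[str]       # 'co_bound' | 'single' | 'tied'
    significant: Optional[bool]    # p_cobound_greater < alpha
    testable: bool


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (not 0) when either vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _categorize_r(r: float) -> Optional[str]:
    if math.isnan(r):
        return None
    if r > R_HIGH:
        return "high"
    if r < 0:
        return "negative"
    return "medium"


def _categorize_delta(delta: float) -> Optional[str]:
    if math.isnan(delta):
        return None
    if delta < DELTA_SHARED:
        return "shared"
    if delta > DELTA_DIFFERENTIAL:
        return "differential"
    return "intermediate"


def motif_association_screen(occupancy: pd.DataFrame,
                             enrichment_a: Mapping[str, float],
                             enrichment_b: Mapping[str, float]) -> pd.DataFrame:
    """Per-motif Pearson correlations of occupancy against both factors.

    ``occupancy`` is a motif x gene DataFrame.  Correlations are computed on
    the intersection of the three gene universes (>= 3 genes required).
    Motifs with constant occupancy get NaN correlations and are retained
    with ``undefined=True``.  Output is sorted by max(r_A, r_B) descending.
    """
    genes = [g for g in occupancy.columns
             if g in enrichment_a and g in enrichment_b]
    if len(genes) < 3:
        raise ValueError("gene universes intersect in fewer than 3 genes")
    ea = np.array([enrichment_a[g] for g in genes])
    eb = np.array([enrichment_b[g] for g in genes])
    rows = []
    for motif_id in occupancy.index:
        occ = occupancy.loc[motif_id, genes].to_numpy(dtype=float)
        if np.ptp(occ) == 0 or np.ptp(ea) == 0:
            r_a = float("nan")
        else:
            r_a = pearson_correlation(occ, ea)
        if np.ptp(occ) == 0 or np.ptp(eb) == 0:
            r_b = float("nan")
        else:
            r_b = pearson_correlation(occ, eb)
        delta = abs(r_a - r_b)
        rows.append({
            "motif_id": motif_id,
            "r_A": r_a,
            "r_B": r_b,
            "delta": delta,
            "category_A": _categorize_r(r_a),
            "category_B": _categorize_r(r_b),
            "delta_category": _categorize_delta(delta),
            "undefined": math.isnan(r_a) or math.isnan(r_b),
        })
    df = pd.DataFrame(rows)
    df["_rank"] = df[["r_A", "r_B"]].max(axis=1)
    df = df.sort_values("_rank", ascending=False, na_position="last",
                        kind="mergesort").drop(columns="_rank")
    return df.reset_index(drop=True)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "x_greater") -> tuple[float, float]:
    """Mann-Whitney U (midranks) with a one-sided p-value.

    Exact p by enumeration when n_x + n_y <= 20 with no ties; otherwise the
    normal approximation with tie and continuity corrections.  Returns
    (U of x, one-sided p for the requested alternative).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("x_greater", "y_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) + len(y) <= 20 and no_ties) else "asymptotic"
    scipy_alt = "greater" if alternative == "x_greater" else "less"
    res = stats.mannwhitneyu(x, y, alternative=scipy_alt, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def site_strength_comparison(sites: Sequence[MotifSite],
                             site_genes: Sequence[str],
                             cobinding: CoBindingTable,
                             motif_id: str,
                             alpha: float = ALPHA) -> StrengthCompareResult:
    """Compare −log10 site p-values between co-bound and B-only promoters.

    ``sites`` must already be non-overlapping per promoter; ``site_genes``
    gives the promoter gene for each site.  Sites are pooled within each
    group.  The headline one-sided test is always "co-bound stronger"; the
    opposite direction is reported as its own column, never silently
    flipped.  A group with zero sites makes the result untestable.
    """
    cobound_genes = cobinding.genes_in("both")
    single_genes = cobinding.genes_in("B_only")
    strengths = {"co_bound": [], "single": []}
    for site, gene in zip(sites, site_genes):
        if site.motif_id != motif_id:
            continue
        if gene in cobound_genes:
            strengths["co_bound"].append(-math.log10(site.p_value))
        elif gene in single_genes:
            strengths["single"].append(-math.log10(site.p_value))
    xs, ys = strengths["co_bound"], strengths["single"]
    if not xs or not ys:
        return StrengthCompareResult(motif_id, len(xs), len(ys), None, None,
                                     None, None, None, testable=False)
    u, p_greater = mann_whitney_u(xs, ys, "x_greater")
    _, p_less = mann_whitney_u(xs, ys, "y_greater")
    mid = len(xs) * len(ys) / 2
    direction = "co_bound" if u > mid else ("single" if u < mid else "tied")
    return StrengthCompareResult(motif_id, len(xs), len(ys), u, p_greater,
                                 p_less, direction, p_greater < alpha,
                                 testable=True)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (advisory column)."""
    return stats.false_discovery_control(np.asarray(pvalues, float), method="bh")


def hypergeom_enrichment_p(universe_n: int, bound_n: int, set_n: int,
                           overlap_n: int) -> float:
    """Upper-tail hypergeometric p of seeing >= overlap_n bound genes in a set."""
    return float(stats.hypergeom.sf(overlap_n - 1, universe_n, bound_n, set_n))


def binding_fraction_summary(gene_sets: Mapping[str, Sequence[str]],
                             cobinding: CoBindingTable) -> pd.DataFrame:
    """Per gene set and factor: fraction bound plus hypergeometric enrichment.

    Factor A counts genes in both ∪ A_only, factor B both ∪ B_only.  Genes
    absent from the co-binding universe are counted separately, never
    silently dropped.
    """
    universe = set(cobinding.classes)
    bound = {"A": cobinding.genes_in("both", "A_only"),
             "B": cobinding.genes_in("both", "B_only")}
    rows = []
    for name, members in gene_sets.items():
        members = list(dict.fromkeys(members))
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        present = [g for g in members if g in universe]
        missing = len(members) - len(present)
        for factor in ("A", "B"):
            k = sum(g in bound[factor] for g in present)
            frac = k / len(present) if present else float("nan")
            p = (hypergeom_enrichment_p(len(universe), len(bound[factor]),
                                        len(present), k)
                 if present else float("nan"))
            rows.append({"gene_set": name, "factor": factor,
                         "n_set": len(members), "n_in_universe": len(present),
                         "n_missing": missing, "n_bound": k,
                         "fraction_bound": frac, "hypergeom_p": p})
    return pd.DataFrame(rows)
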