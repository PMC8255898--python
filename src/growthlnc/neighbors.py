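"""Co-expressed and cis-neighboring lncRNA–mRNA pairs, plus enrichment.

A lncRNA–mRNA pair is *co-expressed* when the Pearson correlation of their
expression across shared samples satisfies |r| > 0.8 with two-sided
p < 0.05, and a *cis neighbor* when additionally the two loci lie on the
same chromosome within a 100-kb window (gap between the closest interval
ends; 0 if they overlap) and |r| > 0.9. The window is symmetric — upstream
and downstream collapse to one distance — and gene coordinates are the
union span over a gene's transcripts. With few samples (n = 6 in a 3-vs-3
design) the t-based correlation p-value is fragile; it is reported, not
adjusted.

Enrichment of a neighbor-gene set against user-supplied gene-set maps uses
the hypergeometric upper tail with Benjamini–Hochberg adjustment across
sets.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pearson_with_p", "find_pairs", "PairsResult", "enrich", "gene_spans"]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and the two-sided p-value from the t transform.

    p comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom (the
    standard exact null for bivariate normal data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gene_spans(annotation: pd.DataFrame) -> pd.DataFrame:
    """Union span per gene: chrom, min start, max end (1-based inclusive).

    A gene annotated on more than one chromosome is an error.
    """
    grp = annotation.groupby("gene_id")
    chroms = grp["chrom"].nunique()
    bad = chroms.index[chroms > 1].tolist()
    if bad:
        raise ValueError(f"gene(s) on multiple chromosomes: {bad[:5]}")
    return pd.DataFrame(
        {
            "chrom": grp["chrom"].first(),
            "start": grp["start"].min(),
            "end": grp["end"].max(),
        }
    )


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    # 1-based inclusive intervals; bp strictly between them, 0 if overlapping
    lo0 = max(s1, s2) - 1  # 0-based half-open
    hi0 = min(e1, e2)
    return max(0, lo0 - hi0)


class PairsResult(NamedTuple):
    pairs: pd.DataFrame
    missing_annotation: list[str]
    constant_genes: list[str]


def find_pairs(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 100_000,
    coexpr_threshold: float = 0.8,
    cis_pcc_threshold: float = 0.9,
    p_threshold: float = 0.05,
) -> PairsResult:
    """Screen all lncRNA × mRNA pairs for co-expression and cis neighbors.

    Both expression matrices are genes × samples with identical sample
    columns. ``annotation`` provides transcript coordinates; genes missing
    from it are excluded from the distance test (and listed), as are genes
    with constant expression. Returns the qualifying pairs (with r, p and
    genomic distance where defined) plus the two exclusion lists.
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        common = [c for c in lnc_expr.columns if c in set(mrna_expr.columns)]
        if len(common) < 3:
            raise ValueError("matrices share fewer than 3 sample columns")
        lnc_expr = lnc_expr[common]
        mrna_expr = mrna_expr[common]
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples")

    def standardize(df: pd.DataFrame):
        a = df.to_numpy(dtype=float)
        sd = a.std(axis=1, ddof=1)
        keep = sd > 0
        z = (a[keep] - a[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        return z, df.index[keep].tolist(), df.index[~keep].tolist()

    zl, lnc_ids, const_l = standardize(lnc_expr)
    zm, mrna_ids, const_m = standardize(mrna_expr)
    constant = const_l + const_m
    if not lnc_ids or not mrna_ids:
        return PairsResult(_empty_pairs(), [], constant)

    r = (zl @ zm.T) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    spans = gene_spans(annotation)
    known = set(spans.index)
    missing = [g for g in lnc_ids + mrna_ids if g not in known]

    rows = []
    for i, lnc in enumerate(lnc_ids):
        for j, mr in enumerate(mrna_ids):
            rij, pij = float(r[i, j]), float(p[i, j])
            if abs(rij) <= coexpr_threshold or pij >= p_threshold:
                continue
            distance = np.nan
            cis = False
            if lnc in known and mr in known:
                a, b = spans.loc[lnc], spans.loc[mr]
                if a["chrom"] == b["chrom"]:
                    distance = _interval_gap(
                        a["start"], a["end"], b["start"], b["end"]
                    )
                    cis = (
                        distance <= window
                        and abs(rij) > cis_pcc_threshold
                        and pij < p_threshold
                    )
            rows.append(
                {
                    "lnc_id": lnc,
                    "mrna_id": mr,
                    "pcc": rij,
                    "pcc_p": pij,
                    "distance": distance,
                    "relation": "cis_neighbor" if cis else "co_expressed",
                }
            )
    pairs = pd.DataFrame(rows) if rows else _empty_pairs()
    pairs = pairs.sort_values(
        ["lnc_id", "mrna_id"], ignore_index=True
    ) if len(pairs) else pairs
    return PairsResult(pairs, missing, constant)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["lnc_id", "mrna_id", "pcc", "pcc_p", "distance", "relation"]
    )


def enrich(
    neighbor_genes: set,
    gene_sets: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list against gene sets.

    For each set, p_raw is the upper-tail hypergeometric probability of
    observing at least the seen overlap between ``neighbor_genes`` (the
    draw) and the set (the successes) within ``universe``; p_adjusted is
    Benjamini–Hochberg across all tested sets. Sets empty after
    intersection with the universe are dropped. Result is sorted by
    p_adjusted then set id.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    neighbors = set(neighbor_genes)
    if not neighbors <= set(universe):
        extra = sorted(neighbors - set(universe))
        raise ValueError(f"neighbor genes outside universe: {extra[:5]}")
    n_univ = len(universe)
    n_draw = len(neighbors)
    rows = []
    for set_id, members in gene_sets.items():
        in_univ = set(members) & set(universe)
        if not in_univ:
            continue
        k = len(neighbors & in_univ)
        K = len(in_univ)
        p_raw = float(stats.hypergeom.sf(k - 1, n_univ, K, n_draw))
        fold = (
            (k / n_draw) / (K / n_univ) if n_draw > 0 else float("nan")
        )
        rows.append(
            {
                "set_id": set_id,
                "overlap": k,
                "set_size": K,
                "fold": fold,
                "p_raw": p_raw,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "overlap", "set_size", "fold", "p_raw", "p_adjusted"]
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out.sort_values(
        ["p_adjusted", "set_id"], ignore_index=True
    )
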