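"""TPM quantification and empirical-noise differential expression.

The DE engine follows the NOISeq idea for replicated designs: for each
gene, the signal is the pair (M, D) where M is the log2 ratio of condition
means (pseudocount-stabilised) and D the absolute difference of means. A
null distribution of (M*, D*) is built from every within-condition
replicate pair, pooled over all genes — what replicate noise alone can
produce. The p-value of a gene is the (add-one smoothed) fraction of null
points at least as extreme in both coordinates. A gene is called
significant when p < 0.05 and |M| ≥ 1, the conventional thresholds for
this design. With two conditions labelled A and B, "up" means higher in
condition A.

Swapping the condition labels negates every M and leaves every p-value
unchanged, since the null uses within-condition pairs and both
exceedance tests are on |M|.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["compute_tpm", "de_test", "de_summary"]


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a genes × samples count matrix.

    ``lengths`` gives each gene's transcript length in nt. Per sample,
    counts are divided by length in kb and rescaled so the column sums to
    10⁶. A sample with zero total counts is an error (named).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"no length for genes: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with all-zero counts: {zero}")
    return rate.div(totals, axis=1) * 1e6


def _condition_groups(expr: pd.DataFrame, conditions) -> tuple:
    cond = pd.Series(conditions)
    if not cond.index.isin(expr.columns).all() or len(cond) != expr.shape[1]:
        # accept a sample sheet DataFrame too
        raise ValueError("conditions must map every expression column")
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    a_cols = cond.index[cond == levels[0]].tolist()
    b_cols = cond.index[cond == levels[1]].tolist()
    return levels, a_cols, b_cols


def de_test(
    expr: pd.DataFrame,
    conditions,
    pseudocount: float = 0.5,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Empirical-noise differential expression on a genes × samples matrix.

    ``conditions`` maps each sample column to one of two condition labels
    (dict or Series keyed by sample id). Expression should be TPM (counts
    are accepted; the statistic is scale-dependent only through D, which
    is compared within the same matrix). Requires ≥ 2 replicates per
    condition; with a single replicate no empirical null exists — rerun
    with replicates or apply a fold-change-only screen explicitly.

    Returns one row per gene: mean_a, mean_b, log2fc (A over B), d_stat,
    p_value, significant, direction.
    """
    if isinstance(conditions, pd.DataFrame):
        conditions = conditions.set_index("sample_id")["condition"]
    (level_a, level_b), a_cols, b_cols = _condition_groups(expr, conditions)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            "de_test needs >= 2 replicates per condition to build the "
            "empirical null; with one replicate, filter on fold change "
            "alone (explicitly) instead"
        )
    x = expr[a_cols].to_numpy(dtype=float)
    y = expr[b_cols].to_numpy(dtype=float)
    mean_a = x.mean(axis=1)
    mean_b = y.mean(axis=1)
    # difference of logs (not log of ratio) so that swapping the condition
    # labels negates M exactly in floating point
    m = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    d = np.abs(mean_a - mean_b)

    null_m, null_d = [], []
    for block in (x, y):
        for i, j in combinations(range(block.shape[1]), 2):
            null_m.append(
                np.log2(block[:, i] + pseudocount)
                - np.log2(block[:, j] + pseudocount)
            )
            null_d.append(np.abs(block[:, i] - block[:, j]))
    nm = np.abs(np.concatenate(null_m))
    nd = np.concatenate(null_d)

    abs_m = np.abs(m)
    n_null = nm.size
    p = np.empty(m.size)
    chunk = max(1, int(2e7) // max(n_null, 1))
    for s in range(0, m.size, chunk):
        e = min(s + chunk, m.size)
        exceed = (nm[None, :] >= abs_m[s:e, None]) & (
            nd[None, :] >= d[s:e, None]
        )
        p[s:e] = (1.0 + exceed.sum(axis=1)) / (1.0 + n_null)

    significant = (p < p_threshold) & (abs_m >= fc_threshold)
    res = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": m,
            "d_stat": d,
            "p_value": p,
            "significant": significant,
            "direction": np.where(m > 0, "up", "down"),
        },
        index=expr.index,
    )
    res.attrs["condition_a"] = level_a
    res.attrs["condition_b"] = level_b
    return res


def de_summary(
    results: pd.DataFrame, biotypes: pd.Series | None = None
) -> dict:
    """Counts of significant genes: total, up, down, optionally per biotype.

    "up" means higher in condition A (the first condition label in sorted
    order, e.g. the inflection-point group in an IP-vs-PP design).
    """
    sig = results[results["significant"]]
    out = {
        "total": int(len(sig)),
        "up": int((sig["direction"] == "up").sum()),
        "down": int((sig["direction"] == "down").sum()),
    }
    if biotypes is not None:
        per = {}
        for biotype, grp in sig.groupby(biotypes.reindex(sig.index)):
            per[str(biotype)] = {
                "total": int(len(grp)),
                "up": int((grp["direction"] == "up").sum()),
                "down": int((grp["direction"] == "down").sum()),
            }
        out["by_biotype"] = per
    return out
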