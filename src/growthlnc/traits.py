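"""Two-group comparison of carcass / meat-quality traits and fatty acids.

Traits are compared between two groups (e.g. animals slaughtered at the
growth inflection point vs the plateau phase) with a two-sided t-test.
Welch's unequal-variance form is the default — group variances in this
kind of trait table routinely differ several-fold — with the pooled
Student form available. Individual fatty-acid columns (shorthand C16:0,
C18:1, ...) are summed into saturated / monounsaturated / polyunsaturated
classes via a fully overridable class map.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compare_traits", "fatty_acid_classes", "DEFAULT_FA_CLASSES"]

DEFAULT_FA_CLASSES: dict[str, tuple[str, ...]] = {
    "SFA": ("C14:0", "C16:0", "C18:0", "C20:0"),
    "MUFA": ("C16:1", "C18:1", "C20:1"),
    "PUFA": ("C18:2", "C18:3", "C20:4", "C20:5", "C22:6"),
}

_FA_PATTERN = re.compile(r"^C\d+:\d+$")


def compare_traits(
    table: pd.DataFrame,
    traits: list[str],
    group_col: str = "group",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-trait group means ± SD and a two-sided t-test.

    ``table`` holds one row per animal with a group label column and the
    trait columns. ``equal_var=False`` (default) is Welch's test; True
    gives the pooled Student's test. A trait with fewer than 2 non-missing
    observations in either group is skipped with a warning.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    rows = []
    for trait in traits:
        a = table.loc[table[group_col] == ga, trait].dropna().to_numpy(float)
        b = table.loc[table[group_col] == gb, trait].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            warnings.warn(
                f"trait {trait!r} skipped: fewer than 2 observations in a group",
                stacklevel=2,
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "trait": trait,
                f"mean_{ga}": a.mean(),
                f"sd_{ga}": a.std(ddof=1),
                f"n_{ga}": a.size,
                f"mean_{gb}": b.mean(),
                f"sd_{gb}": b.std(ddof=1),
                f"n_{gb}": b.size,
                "t_stat": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def fatty_acid_classes(
    table: pd.DataFrame,
    class_map: dict[str, tuple[str, ...]] | None = None,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal and per-group SFA/MUFA/PUFA totals.

    Every column whose name looks like a fatty-acid shorthand (``C<m>:<n>``)
    must be assigned to exactly one class by ``class_map`` (default
    :data:`DEFAULT_FA_CLASSES`); an unmapped fatty-acid column is an error.
    Class totals are plain sums of member columns present in the table, and
    ``total_FA`` is their sum, so additivity is exact.

    Returns (per-animal table with class totals, per-group mean table).
    """
    class_map = class_map or DEFAULT_FA_CLASSES
    fa_cols = [c for c in table.columns if _FA_PATTERN.match(str(c))]
    mapped = {fa for members in class_map.values() for fa in members}
    unmapped = [c for c in fa_cols if c not in mapped]
    if unmapped:
        raise ValueError(f"fatty-acid columns not in class map: {unmapped}")

    per_animal = pd.DataFrame(index=table.index)
    for col in ("animal_id", group_col):
        if col in table.columns:
            per_animal[col] = table[col]
    for cls, members in class_map.items():
        present = [fa for fa in members if fa in table.columns]
        per_animal[cls] = (
            table[present].sum(axis=1) if present else 0.0
        )
    per_animal["total_FA"] = per_animal[list(class_map)].sum(axis=1)

    if group_col in per_animal.columns:
        per_group = (
            per_animal.groupby(group_col)[list(class_map) + ["total_FA"]]
            .mean()
            .reset_index()
        )
    else:
        per_group = per_animal[list(class_map) + ["total_FA"]].mean().to_frame().T
    return per_animal, per_group
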