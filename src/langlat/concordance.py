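"""Agreement between the multitask multimodal classification and external
labelings (e.g. Gaussian-mixture HFLI categories, per-hemisphere SVM
dominance): contingency tables with conditional percentages, the adjusted
Rand index, and alluvial-style flow tables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = ["cross_tabulate", "alluvial_table"]


def cross_tabulate(
    labels_a: pd.Series,
    labels_b: pd.Series,
) -> dict:
    """Full contingency analysis of two aligned categorical labelings.

    Returns a dict with the contingency table (row/column margins included),
    row- and column-conditional percentages, and the adjusted Rand index.
    ARI of a constant labeling is defined as 0 (with a warning): the strict
    formula is 0/0 there.
    """
    a = pd.Series(labels_a).dropna()
    b = pd.Series(labels_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared ids between the two labelings")
    a, b = a.loc[shared].astype(str), b.loc[shared].astype(str)
    table = pd.crosstab(a, b, margins=True, margins_name="total")
    core = pd.crosstab(a, b)
    row_pct = core.div(core.sum(axis=1), axis=0) * 100.0
    col_pct = core.div(core.sum(axis=0), axis=1) * 100.0
    if a.nunique() < 2 or b.nunique() < 2:
        warnings.warn(
            "constant labeling: adjusted Rand index set to 0 by convention"
        )
        ari = 0.0
    else:
        ari = float(adjusted_rand_score(a, b))
    return {
        "table": table,
        "row_pct": row_pct,
        "col_pct": col_pct,
        "ari": ari,
        "n": int(len(shared)),
    }


def alluvial_table(
    labels: pd.DataFrame,
    columns: list[str] | None = None,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Long-format flow table: one row per unique label combination.

    ``columns`` orders the axes (default: all columns except the optional
    stratifier); flow counts sum to the number of rows within each stratum.
    """
    cols = columns or [c for c in labels.columns if c != stratify_by]
    if len(cols) < 2:
        raise ValueError("need at least 2 label columns for a flow table")
    group_cols = ([stratify_by] if stratify_by else []) + cols
    flows = (
        labels.groupby(group_cols, dropna=False, observed=True)
        .size()
        .reset_index(name="count")
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return flows
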