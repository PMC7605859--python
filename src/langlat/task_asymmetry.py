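"""Network-level functional asymmetries from hROI task-contrast values.

For each participant and task contrast (sentence minus word-list during
production PROD, listening LISN, reading READ) the per-hROI left and right
BOLD contrast values are differenced pairwise and averaged over the pairs of
a region set with volumetric weights:

    asym = sum_i w_i (L_i - R_i) / sum_i w_i,   w_i = pair volume

Positive values are leftward (typical) lateralization.  The region set is
either the full 18-pair SENT_CORE network or the 3-pair SENT_HUBS subset.
The asymmetry is a raw left-minus-right difference, not a normalized
laterality quotient: the conventional 0.05 dissociation band and the
published group means live on this scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import Atlas

__all__ = [
    "TASKS",
    "ROI_SETS",
    "PROFILE_COLUMNS",
    "network_asymmetry",
    "asymmetry_profiles",
]

TASKS = ("PROD", "LISN", "READ")
ROI_SETS = ("CORE", "HUBS")

#: Fixed order of the six signed asymmetry columns of a profile table.
PROFILE_COLUMNS = tuple(f"{rs}_{t}" for rs in ROI_SETS for t in TASKS)

CONTRAST_COLUMNS = ("participant_id", "task", "pair_name", "hemisphere", "bold")


def _check_contrasts(contrasts: pd.DataFrame, atlas: Atlas) -> None:
    missing = [c for c in CONTRAST_COLUMNS if c not in contrasts.columns]
    if missing:
        raise ValueError(f"contrast table is missing columns {missing}")
    if not np.isfinite(contrasts["bold"].to_numpy(dtype=float)).all():
        raise ValueError("contrast table contains non-finite BOLD values")


def _wide_differences(
    contrasts: pd.DataFrame, atlas: Atlas
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot to (participant, task) x pair left/right tables; check grid."""
    wide = contrasts.pivot_table(
        index=["participant_id", "task"],
        columns=["pair_name", "hemisphere"],
        values="bold",
        aggfunc="first",
    )
    counts = contrasts.groupby(
        ["participant_id", "task", "pair_name", "hemisphere"], observed=True
    ).size()
    if (counts > 1).any():
        dup = counts[counts > 1].index[0]
        raise ValueError(f"duplicate contrast cell {dup}")
    pairs = list(atlas.pair_names)
    for hemi in ("L", "R"):
        for p in pairs:
            if (p, hemi) not in wide.columns:
                raise ValueError(f"contrast table has no column for hROI ({p}, {hemi})")
    left = wide.loc[:, [(p, "L") for p in pairs]]
    right = wide.loc[:, [(p, "R") for p in pairs]]
    if left.isna().any().any() or right.isna().any().any():
        stacked = wide.isna().stack(future_stack=True)
        where = stacked[stacked].index[0]
        raise ValueError(f"missing contrast value at {where}")
    left.columns = right.columns = pairs
    return left, right


def network_asymmetry(
    contrasts: pd.DataFrame,
    atlas: Atlas,
    roi_set: str,
    participant: str,
    task: str,
) -> float:
    """Volume-weighted mean left-minus-right asymmetry for one participant/task."""
    sub = contrasts[
        (contrasts["participant_id"] == participant) & (contrasts["task"] == task)
    ]
    if sub.empty:
        raise ValueError(f"no contrast rows for ({participant}, {task})")
    _check_contrasts(sub, atlas)
    left, right = _wide_differences(sub, atlas)
    pairs = atlas.pairs(roi_set)
    weights = np.array([atlas.pair_volume(p) for p in pairs])
    diffs = left[list(pairs)].to_numpy()[0] - right[list(pairs)].to_numpy()[0]
    return float(np.dot(weights, diffs) / weights.sum())


def asymmetry_profiles(contrasts: pd.DataFrame, atlas: Atlas) -> pd.DataFrame:
    """Per-participant signed and absolute network asymmetries for all tasks.

    Returns one row per participant with column order
    ``participant_id, CORE_PROD, CORE_LISN, CORE_READ, HUBS_PROD, HUBS_LISN,
    HUBS_READ`` followed by the matching ``ABS_*`` columns.
    """
    _check_contrasts(contrasts, atlas)
    left, right = _wide_differences(contrasts, atlas)
    tasks_present = set(left.index.get_level_values("task"))
    missing_tasks = set(TASKS) - tasks_present
    if missing_tasks:
        raise ValueError(f"contrast table lacks tasks {sorted(missing_tasks)}")
    diffs = left.to_numpy() - right.to_numpy()
    pairs = list(atlas.pair_names)
    out = {}
    for roi_set in ROI_SETS:
        sel = [pairs.index(p) for p in atlas.pairs(roi_set)]
        weights = np.array([atlas.pair_volume(pairs[i]) for i in sel])
        asym = diffs[:, sel] @ weights / weights.sum()
        out[roi_set] = pd.Series(asym, index=left.index)
    table = pd.DataFrame(out).unstack("task")
    table.columns = [f"{rs}_{t}" for rs, t in table.columns]
    table = table[[c for c in PROFILE_COLUMNS]]
    for col in PROFILE_COLUMNS:
        table[f"ABS_{col}"] = table[col].abs()
    table = table.reset_index().rename(columns={"index": "participant_id"})
    return table
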