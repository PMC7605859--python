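"""Phenotype classification: feature assembly, Ward clustering, group
labelling and dissociation (crossed lateralization) detection.

Nine standardized variables describe each participant: the six signed
task asymmetries (SENT_CORE and SENT_HUBS for PROD, LISN, READ), the sum
and the asymmetry of the two hemispheric degree centralities, and the mean
interhemispheric homotopic correlation.  Participants are agglomerated with
Ward's minimum-variance criterion on Euclidean distances; the number of
clusters is picked by a majority vote of internal validity indices; clusters
are labelled TYP_STRONG / TYP_MILD / ATYP from their mean task asymmetries.

Independently of clustering, each participant is labelled CROSSED when, in
at least one region set, the three task asymmetries point in opposite
directions beyond a +/-0.05 band, and CONGRUENT otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import validity
from .task_asymmetry import PROFILE_COLUMNS, ROI_SETS, TASKS

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "ClusterTree",
    "build_features",
    "ward_tree",
    "select_k",
    "assign_groups",
    "direction_labels",
    "classify_dissociation",
    "dissociation_table",
    "GROUPS",
]

log = logging.getLogger(__name__)

GROUPS = ("TYP_STRONG", "TYP_MILD", "ATYP")

#: Fixed column order of the clustering feature matrix.
FEATURE_COLUMNS = (
    "CORE_PROD",
    "CORE_LISN",
    "CORE_READ",
    "HUBS_PROD",
    "HUBS_LISN",
    "HUBS_READ",
    "rs_dc_sum",
    "rs_dc_asym",
    "mihhc",
)

TASK_FEATURES = FEATURE_COLUMNS[:6]


@dataclass
class FeatureMatrix:
    """n x 9 clustering variables with a fixed column order."""

    ids: list[str]
    values: np.ndarray
    columns: tuple[str, ...] = FEATURE_COLUMNS
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "participant_id", self.ids)
        return df

    def standardize(self) -> "FeatureMatrix":
        """Z-score each column (sample sd, ddof=1); keeps means/sds."""
        if self.standardized:
            return self
        means = self.values.mean(axis=0)
        sds = self.values.std(axis=0, ddof=1)
        if np.any(sds == 0):
            dead = [c for c, s in zip(self.columns, sds) if s == 0]
            raise ValueError(f"zero-variance feature column(s) {dead}")
        return FeatureMatrix(
            ids=list(self.ids),
            values=(self.values - means) / sds,
            columns=self.columns,
            standardized=True,
            means=means,
            sds=sds,
        )


@dataclass
class ClusterTree:
    """Agglomeration history: scipy linkage matrix (n-1 merges)."""

    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.linkage) + 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        return fcluster(self.linkage, t=k, criterion="maxclust")

    def to_merge_list(self) -> list[dict]:
        return [
            {"a": int(a), "b": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.linkage
        ]


def build_features(
    profiles: pd.DataFrame,
    metrics: pd.DataFrame,
    standardize: bool = False,
) -> FeatureMatrix:
    """Join asymmetry profiles with connectivity metrics into the 9 variables.

    ``mihhc`` enters on the r scale (after standardization the r/z choice is
    an almost-monotone rescaling with no practical effect on the clustering).
    """
    a_ids, m_ids = set(profiles["participant_id"]), set(metrics["participant_id"])
    if a_ids != m_ids:
        raise ValueError(
            f"participant ids differ between tables: only-in-profiles="
            f"{sorted(a_ids - m_ids)[:5]}, only-in-metrics={sorted(m_ids - a_ids)[:5]}"
        )
    merged = profiles.merge(metrics, on="participant_id").sort_values(
        "participant_id", kind="stable"
    )
    cols = list(TASK_FEATURES) + ["rs_dc_sum", "rs_dc_asym", "mihhc_r"]
    block = merged[cols].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("feature matrix contains missing values")
    fm = FeatureMatrix(
        ids=list(merged["participant_id"]), values=block, columns=FEATURE_COLUMNS
    )
    return fm.standardize() if standardize else fm


def ward_tree(features: FeatureMatrix) -> ClusterTree:
    """Ward minimum-variance agglomeration on Euclidean distances."""
    X = features.values
    if len(X) < 2:
        raise ValueError("need at least 2 observations to build a tree")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    return ClusterTree(linkage(X, method="ward"))


def select_k(
    features: FeatureMatrix,
    tree: ClusterTree,
    k_range: tuple[int, int] = (2, 8),
    index_set=validity.DEFAULT_INDICES,
    seed: int = 0,
) -> tuple[int, dict[str, int]]:
    """Majority vote of validity indices over cuts of the tree."""
    return validity.select_k_from_tree(
        features.values, tree.linkage, k_range=k_range, indices=index_set, seed=seed
    )


def assign_groups(
    features: FeatureMatrix, tree: ClusterTree, k: int
) -> pd.DataFrame:
    """Label clusters from their mean task asymmetries.

    For k = 3: the cluster with the lowest mean of the six task-asymmetry
    columns is ATYP (a warning is logged and labels suffixed ``_unverified``
    if that mean is not negative); of the remaining two, the one with the
    higher mean SENT_CORE PROD asymmetry is TYP_STRONG, the other TYP_MILD.
    Other k produce generic ``cluster_i`` labels.
    """
    if features.standardized:
        raise ValueError("assign_groups needs unstandardized features")
    labels = tree.cut(k)
    df = features.to_frame()
    task_block = df[list(TASK_FEATURES)]
    cluster_ids = np.unique(labels)
    if k != 3 or len(cluster_ids) != 3:
        log.warning("k=%d != 3: using generic cluster labels", k)
        mapping = {c: f"cluster_{i + 1}" for i, c in enumerate(cluster_ids)}
    else:
        task_means = {
            c: task_block[labels == c].mean(axis=None) for c in cluster_ids
        }
        atyp = min(cluster_ids, key=lambda c: task_means[c])
        rest = [c for c in cluster_ids if c != atyp]
        prod_means = {c: df.loc[labels == c, "CORE_PROD"].mean() for c in rest}
        strong = max(rest, key=lambda c: prod_means[c])
        mild = next(c for c in rest if c != strong)
        mapping = {atyp: "ATYP", strong: "TYP_STRONG", mild: "TYP_MILD"}
        if not task_means[atyp] < 0:
            log.warning(
                "lowest-asymmetry cluster has non-negative mean (%.3f); "
                "group labels are unverified",
                task_means[atyp],
            )
            mapping = {c: f"{g}_unverified" for c, g in mapping.items()}
    return pd.DataFrame(
        {
            "participant_id": features.ids,
            "cluster_id": labels,
            "group": [mapping[c] for c in labels],
        }
    )


# -- dissociation rule -------------------------------------------------------


def direction_labels(asymmetries: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """L / R / N labels: L if a >= +threshold, R if a <= -threshold, else N."""
    a = np.asarray(asymmetries, dtype=float)
    out = np.full(a.shape, "N", dtype="<U1")
    out[a >= threshold] = "L"
    out[a <= -threshold] = "R"
    return out


def _is_crossed(values_by_set: dict[str, np.ndarray], threshold: float, rule: str) -> bool:
    for vals in values_by_set.values():
        has_l, has_r = np.any(vals >= threshold), np.any(vals <= -threshold)
        if rule == "both_poles":
            # both directions must exceed the band
            if has_l and has_r:
                return True
        elif rule == "one_pole":
            # one supra-threshold task opposed by any opposite-signed task,
            # even one inside the neutral band
            if (has_l and np.any(vals < 0)) or (has_r and np.any(vals > 0)):
                return True
        else:
            raise ValueError(f"unknown dissociation_rule {rule!r}")
    return False


def classify_dissociation(
    profile: pd.Series | dict,
    threshold: float = 0.05,
    rule: str = "both_poles",
) -> tuple[dict[str, str], str]:
    """Direction labels per task x region set and CROSSED/CONGRUENT status.

    A participant is CROSSED when, within SENT_CORE or SENT_HUBS (or both),
    the three task labels contain both an L and an R (``both_poles``, the
    default); tasks inside the neutral band never trigger a dissociation.
    """
    labels: dict[str, str] = {}
    by_set: dict[str, np.ndarray] = {}
    for rs in ROI_SETS:
        vals = np.array([float(profile[f"{rs}_{t}"]) for t in TASKS])
        labs = direction_labels(vals, threshold)
        by_set[rs] = vals
        for t, lab in zip(TASKS, labs):
            labels[f"{rs}_{t}"] = str(lab)
    status = "CROSSED" if _is_crossed(by_set, threshold, rule) else "CONGRUENT"
    return labels, status


def dissociation_table(
    profiles: pd.DataFrame,
    threshold: float = 0.05,
    rule: str = "both_poles",
) -> pd.DataFrame:
    """Vectorized dissociation classification for a whole profile table."""
    rows = []
    for _, row in profiles.iterrows():
        labels, status = classify_dissociation(row, threshold=threshold, rule=rule)
        rec = {"participant_id": row["participant_id"], **labels,
               "dissociation": status}
        rows.append(rec)
    return pd.DataFrame(rows)


def classify_cohort(
    profiles: pd.DataFrame,
    metrics: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    index_set=validity.DEFAULT_INDICES,
    threshold: float = 0.05,
    rule: str = "both_poles",
    seed: int = 0,
    label_k: int | None = None,
) -> dict:
    """Full classification: features -> tree -> k vote -> labels -> dissociation.

    Returns a dict with keys ``features`` (standardized FeatureMatrix),
    ``tree``, ``k``, ``votes`` and ``labels`` (one row per participant with
    cluster id, group, six direction labels and dissociation status).
    ``label_k`` fixes the cut used for group labelling (e.g. the canonical
    three phenotypes) independently of the voted ``k``.
    """
    raw = build_features(profiles, metrics)
    std = raw.standardize()
    tree = ward_tree(std)
    k, votes = select_k(std, tree, k_range=k_range, index_set=index_set, seed=seed)
    groups = assign_groups(raw, tree, label_k or k)
    diss = dissociation_table(profiles, threshold=threshold, rule=rule)
    labels = groups.merge(diss, on="participant_id")
    return {
        "features": std,
        "raw_features": raw,
        "tree": tree,
        "k": k,
        "votes": votes,
        "labels": labels,
    }
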