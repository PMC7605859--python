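import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from langlat.classifier import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    assign_groups,
    build_features,
    classify_dissociation,
    dissociation_table,
    select_k,
    ward_tree,
)
from langlat.task_asymmetry import PROFILE_COLUMNS


def profiles_from(rows):
    cols = ["participant_id"] + list(PROFILE_COLUMNS)
    df = pd.DataFrame(rows, columns=cols)
    for c in PROFILE_COLUMNS:
        df[f"ABS_{c}"] = df[c].abs()
    return df


def metrics_from(rows):
    df = pd.DataFrame(
        rows, columns=["participant_id", "rs_dc_left", "rs_dc_right", "mihhc_r"]
    )
    df["rs_dc_sum"] = df.rs_dc_left + df.rs_dc_right
    df["rs_dc_asym"] = df.rs_dc_left - df.rs_dc_right
    df["rs_dc_mean"] = (df.rs_dc_left + df.rs_dc_right) / 2
    df["mihhc_z"] = np.arctanh(df.mihhc_r)
    return df


# -- feature assembly --------------------------------------------------------


def test_build_features_arithmetic():
    profiles = profiles_from([["s1", 0.5, 0.3, 0.4, 0.7, 0.4, 0.5]])
    metrics = metrics_from([["s1", 9.0, 9.2, 0.6]])
    fm = build_features(profiles, metrics)
    row = dict(zip(fm.columns, fm.values[0]))
    assert row["rs_dc_sum"] == pytest.approx(18.2)
    assert row["rs_dc_asym"] == pytest.approx(-0.2)
    assert fm.columns == FEATURE_COLUMNS


def test_standardization_contract():
    rng = np.random.default_rng(0)
    n = 40
    profiles = profiles_from(
        [[f"s{i}"] + list(rng.normal(0.3, 0.2, 6)) for i in range(n)]
    )
    metrics = metrics_from(
        [[f"s{i}", rng.normal(9, 1), rng.normal(8.5, 1), rng.uniform(0.3, 0.7)]
         for i in range(n)]
    )
    std = build_features(profiles, metrics, standardize=True)
    assert std.standardized
    assert np.allclose(std.values.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(std.values.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_zscore_of_three_values():
    x = np.array([1.0, 2.0, 3.0])
    fm = FeatureMatrix(ids=list("abc"), values=np.tile(x[:, None], (1, 9)))
    z = fm.standardize()
    assert np.allclose(z.values[:, 0], [-1.0, 0.0, 1.0])


def test_id_mismatch_is_error():
    profiles = profiles_from([["s1", 0.5, 0.3, 0.4, 0.7, 0.4, 0.5]])
    metrics = metrics_from([["s2", 9.0, 9.2, 0.6]])
    with pytest.raises(ValueError, match="ids differ"):
        build_features(profiles, metrics)


# -- Ward clustering ----------------------------------------------------------


def brute_force_ward(X):
    """Exhaustive Ward agglomeration: evaluate the within-cluster variance
    increase of every candidate merge at every step."""
    clusters = [[i] for i in range(len(X))]
    partitions = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = X[clusters[i]], X[clusters[j]]
            na, nb = len(a), len(b)
            delta = (
                na * nb / (na + nb) * np.sum((a.mean(0) - b.mean(0)) ** 2)
            )
            if best is None or delta < best[0]:
                best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        partitions.append([tuple(sorted(c)) for c in clusters])
    return partitions


def scipy_partitions(Z, n):
    from scipy.cluster.hierarchy import fcluster

    parts = []
    for k in range(n - 1, 0, -1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        groups = {}
        for idx, lab in enumerate(labels):
            groups.setdefault(lab, []).append(idx)
        parts.append(sorted(tuple(sorted(g)) for g in groups.values()))
    return parts


def test_ward_matches_exhaustive_oracle():
    rng = np.random.default_rng(12)
    for _ in range(5):
        X = rng.standard_normal((8, 3))
        fm = FeatureMatrix(
            ids=[str(i) for i in range(8)], values=np.hstack([X] * 3)
        )
        tree = ward_tree(fm)
        got = scipy_partitions(tree.linkage, 8)
        want = [sorted(p) for p in brute_force_ward(np.hstack([X] * 3))]
        assert got == want


def test_two_points_merge_at_their_distance():
    X = np.array([[0.0] * 9, [3.0] + [0.0] * 8])
    fm = FeatureMatrix(ids=["a", "b"], values=X)
    tree = ward_tree(fm)
    assert tree.linkage.shape == (1, 4)
    assert tree.linkage[0, 2] == pytest.approx(3.0)


def test_heights_non_decreasing():
    rng = np.random.default_rng(1)
    fm = FeatureMatrix(
        ids=[str(i) for i in range(60)], values=rng.standard_normal((60, 9))
    )
    h = ward_tree(fm).heights
    assert (np.diff(h) >= -1e-12).all()


def test_partition_invariant_to_row_order():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 9))
    ids = [f"s{i}" for i in range(40)]
    fm = FeatureMatrix(ids=ids, values=X)
    labels = dict(zip(ids, ward_tree(fm).cut(3)))
    perm = rng.permutation(40)
    fm2 = FeatureMatrix(ids=[ids[i] for i in perm], values=X[perm])
    labels2 = dict(zip(fm2.ids, ward_tree(fm2).cut(3)))
    # same partition: co-membership must agree for every pair
    for a, b in itertools.combinations(ids, 2):
        assert (labels[a] == labels[b]) == (labels2[a] == labels2[b])


# -- k selection ---------------------------------------------------------------


def blobs(centers, n_per, seed):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per, 4)) + c for c in centers])
    return FeatureMatrix(
        ids=[str(i) for i in range(len(X))], values=X,
        columns=("a", "b", "c", "d"), standardized=True,
    )


def test_select_k_three_blobs():
    centers = np.array([[0, 0, 0, 0], [10, 0, 0, 0], [0, 10, 0, 0]], float)
    fm = blobs(centers, 20, seed=42)
    tree = ward_tree(fm)
    k, votes = select_k(fm, tree, seed=0)
    assert k == 3
    share = sum(v == 3 for v in votes.values()) / len(votes)
    assert share >= 0.75
    assert set(votes) and all(2 <= v <= 8 for v in votes.values())


def test_select_k_two_blobs():
    centers = np.array([[0, 0, 0, 0], [10, 0, 0, 0]], float)
    fm = blobs(centers, 30, seed=42)
    k, votes = select_k(fm, ward_tree(fm), seed=0)
    assert k == 2


def test_select_k_range_validation():
    fm = blobs(np.zeros((1, 4)), 10, seed=0)
    with pytest.raises(ValueError, match="k_range"):
        select_k(fm, ward_tree(fm), k_range=(2, 50))


# -- group labelling -----------------------------------------------------------


def clusters_with_task_means(means, n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    rows_p, rows_m = [], []
    i = 0
    for mu in means:
        for _ in range(n_per):
            i += 1
            rows_p.append([f"s{i:03d}"] + list(rng.normal(mu, 0.02, 6)))
            rows_m.append(
                [f"s{i:03d}", rng.normal(9.0, 0.5), rng.normal(8.5, 0.5),
                 rng.uniform(0.5, 0.7)]
            )
    return build_features(profiles_from(rows_p), metrics_from(rows_m))


def test_assign_groups_rule():
    fm = clusters_with_task_means([0.45, 0.24, -0.15])
    tree = ward_tree(fm.standardize())
    labels = assign_groups(fm, tree, 3)
    merged = labels.copy()
    merged["mu"] = np.repeat([0.45, 0.24, -0.15], 20)
    mapping = merged.groupby("mu")["group"].agg(lambda s: s.mode()[0])
    assert mapping[0.45] == "TYP_STRONG"
    assert mapping[0.24] == "TYP_MILD"
    assert mapping[-0.15] == "ATYP"


def test_assign_groups_unverified_when_all_positive(caplog):
    fm = clusters_with_task_means([0.6, 0.4, 0.2])
    tree = ward_tree(fm.standardize())
    labels = assign_groups(fm, tree, 3)
    assert labels["group"].str.endswith("_unverified").all()


# -- dissociation rule ---------------------------------------------------------


def profile_row(core, hubs):
    row = {"participant_id": "s1"}
    for t, v in zip(("PROD", "LISN", "READ"), core):
        row[f"CORE_{t}"] = v
    for t, v in zip(("PROD", "LISN", "READ"), hubs):
        row[f"HUBS_{t}"] = v
    return row


@pytest.mark.parametrize(
    "core, hubs, expected",
    [
        ((0.3, 0.2, 0.1), (0.4, 0.3, 0.2), "CONGRUENT"),
        ((0.20, -0.15, -0.18), (0.25, -0.29, -0.35), "CROSSED"),
        ((0.2, 0.04, -0.04), (0.3, 0.1, 0.02), "CONGRUENT"),
        ((0.2, 0.1, 0.3), (0.1, 0.06, -0.4), "CROSSED"),  # hub-only dissociation
    ],
)
def test_dissociation_examples(core, hubs, expected):
    labels, status = classify_dissociation(profile_row(core, hubs))
    assert status == expected
    if expected == "CROSSED" and core[0] > 0.05 and core[1] < -0.05:
        assert labels["CORE_PROD"] == "L"
        assert labels["CORE_LISN"] == "R"


def test_dissociation_truth_table_oracle():
    """Both-poles rule agrees with exhaustive enumeration over all 3^6
    sign-band configurations."""
    vals = {"L": 0.2, "N": 0.02, "R": -0.2}
    for combo in itertools.product("LNR", repeat=6):
        core, hubs = combo[:3], combo[3:]
        row = profile_row([vals[c] for c in core], [vals[c] for c in hubs])
        _, status = classify_dissociation(row)
        want = (
            "CROSSED"
            if ({"L", "R"} <= set(core)) or ({"L", "R"} <= set(hubs))
            else "CONGRUENT"
        )
        assert status == want, combo


@given(
    core=st.lists(st.floats(-0.6, 0.6), min_size=3, max_size=3),
    hubs=st.lists(st.floats(-0.6, 0.6), min_size=3, max_size=3),
)
def test_dissociation_sign_flip_invariance(core, hubs):
    _, a = classify_dissociation(profile_row(core, hubs))
    _, b = classify_dissociation(
        profile_row([-v for v in core], [-v for v in hubs])
    )
    assert a == b


def test_one_pole_rule_is_more_sensitive():
    row = profile_row((0.2, -0.04, 0.1), (0.3, 0.1, 0.1))
    assert classify_dissociation(row, rule="both_poles")[1] == "CONGRUENT"
    assert classify_dissociation(row, rule="one_pole")[1] == "CROSSED"


def test_dissociation_table_matches_scalar(default_cohort):
    prof = default_cohort["profiles"].head(20)
    table = dissociation_table(prof)
    for _, row in prof.iterrows():
        _, status = classify_dissociation(row)
        got = table.loc[
            table.participant_id == row.participant_id, "dissociation"
        ].item()
        assert got == status
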