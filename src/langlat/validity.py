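"""Internal cluster-validity indices and majority-vote selection of k.

The number of clusters is chosen the way the NbClust-style protocol does it:
each index votes for the k (over cuts of one hierarchical tree) it considers
optimal, and the modal k wins, ties going to the smallest k.  Twelve classic
indices are implemented; Calinski-Harabasz, silhouette and Davies-Bouldin are
delegated to scikit-learn, the remainder are computed from their standard
definitions.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = ["DEFAULT_INDICES", "vote_for_k", "select_k_from_tree"]

DEFAULT_INDICES = (
    "calinski_harabasz",
    "silhouette",
    "davies_bouldin",
    "dunn",
    "c_index",
    "mcclain_rao",
    "point_biserial",
    "pbm",
    "gap",
    "xie_beni",
    "ratkowsky_lance",
    "ball_hall",
)


def _centroids(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return np.vstack([X[labels == c].mean(axis=0) for c in np.unique(labels)])


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(total)


def _within_between_masks(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask: True where a pair is within one cluster."""
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    return same[iu]


# -- simple per-k scalar indices -------------------------------------------


def _dunn(X, labels, dist):
    D = squareform(dist)
    clusters = [np.where(labels == c)[0] for c in np.unique(labels)]
    diam = max(D[np.ix_(idx, idx)].max() for idx in clusters)
    sep = np.inf
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            sep = min(sep, D[np.ix_(clusters[i], clusters[j])].min())
    return sep / diam if diam > 0 else np.inf


def _c_index(X, labels, dist):
    within = _within_between_masks(labels)
    nw = int(within.sum())
    if nw == 0:
        return np.inf
    sw = dist[within].sum()
    ordered = np.sort(dist)
    smin, smax = ordered[:nw].sum(), ordered[-nw:].sum()
    return (sw - smin) / (smax - smin) if smax > smin else 0.0


def _mcclain_rao(X, labels, dist):
    within = _within_between_masks(labels)
    nw, nb = int(within.sum()), int((~within).sum())
    if nw == 0 or nb == 0:
        return np.inf
    return (dist[within].mean()) / (dist[~within].mean())


def _point_biserial(X, labels, dist):
    within = _within_between_masks(labels)
    nw, nb = int(within.sum()), int((~within).sum())
    nt = nw + nb
    sd = dist.std()
    if sd == 0 or nw == 0 or nb == 0:
        return -np.inf
    return (dist[~within].mean() - dist[within].mean()) * np.sqrt(
        nw * nb / nt**2
    ) / sd


def _pbm(X, labels, dist):
    k = len(np.unique(labels))
    grand = X.mean(axis=0)
    e1 = np.linalg.norm(X - grand, axis=1).sum()
    cents = _centroids(X, labels)
    ek = sum(
        np.linalg.norm(X[labels == c] - cents[i], axis=1).sum()
        for i, c in enumerate(np.unique(labels))
    )
    dk = max(pdist(cents)) if k > 1 else 0.0
    return (e1 * dk / (k * ek)) ** 2 if ek > 0 else 0.0


def _xie_beni(X, labels, dist):
    cents = _centroids(X, labels)
    compact = 0.0
    for i, c in enumerate(np.unique(labels)):
        compact += ((X[labels == c] - cents[i]) ** 2).sum()
    sep = min(pdist(cents)) ** 2 if len(cents) > 1 else np.inf
    return compact / (len(X) * sep)


def _ratkowsky_lance(X, labels, dist):
    k = len(np.unique(labels))
    tss = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    bgss = np.zeros(X.shape[1])
    for c in np.unique(labels):
        sub = X[labels == c]
        bgss += len(sub) * (sub.mean(axis=0) - X.mean(axis=0)) ** 2
    ok = tss > 0
    cbar = np.sqrt(bgss[ok] / tss[ok]).mean()
    return cbar / np.sqrt(k)


_SCALAR_INDICES = {
    "calinski_harabasz": (lambda X, l, d: calinski_harabasz_score(X, l), "max"),
    "silhouette": (lambda X, l, d: silhouette_score(X, l), "max"),
    "davies_bouldin": (lambda X, l, d: davies_bouldin_score(X, l), "min"),
    "dunn": (_dunn, "max"),
    "c_index": (_c_index, "min"),
    "mcclain_rao": (_mcclain_rao, "min"),
    "point_biserial": (_point_biserial, "max"),
    "pbm": (_pbm, "max"),
    "xie_beni": (_xie_beni, "min"),
    "ratkowsky_lance": (_ratkowsky_lance, "max"),
}


# -- indices with sequence rules -------------------------------------------


def _ball_hall_vote(X, labels_by_k, ks):
    """Vote for the k with the largest drop of mean within dispersion W_k/k."""
    ball = {}
    ball[1] = _within_ss(X, np.zeros(len(X), dtype=int))  # k=1: W/1
    for k in ks:
        ball[k] = _within_ss(X, labels_by_k[k]) / k
    diffs = {k: ball[k - 1 if k - 1 in ball else 1] - ball[k] for k in ks}
    # successive differences where the predecessor cut exists; k=min uses k=1
    best = max(ks, key=lambda k: (diffs[k], -k))
    return best


def _gap_vote(X, labels_by_k, ks, rng, n_refs=10):
    """Tibshirani gap statistic with a uniform box reference.

    Votes for the smallest k with gap(k) >= gap(k+1) - s(k+1); if the
    criterion never holds, the largest k in range.
    """
    from scipy.cluster.hierarchy import linkage

    logW = {k: np.log(_within_ss(X, labels_by_k[k])) for k in ks}
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logW = {k: [] for k in ks}
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        Zr = linkage(ref, method="ward")
        for k in ks:
            lr = fcluster(Zr, t=k, criterion="maxclust")
            ref_logW[k].append(np.log(_within_ss(ref, lr)))
    gap = {k: np.mean(ref_logW[k]) - logW[k] for k in ks}
    s = {
        k: np.std(ref_logW[k]) * np.sqrt(1.0 + 1.0 / n_refs) for k in ks
    }
    ks_sorted = sorted(ks)
    for i, k in enumerate(ks_sorted[:-1]):
        nxt = ks_sorted[i + 1]
        if gap[k] >= gap[nxt] - s[nxt]:
            return k
    return ks_sorted[-1]


def vote_for_k(
    X: np.ndarray,
    labels_by_k: dict[int, np.ndarray],
    indices=DEFAULT_INDICES,
    seed: int = 0,
) -> dict[str, int]:
    """Each index's preferred k over the supplied partitions."""
    ks = sorted(labels_by_k)
    dist = pdist(X)
    votes: dict[str, int] = {}
    for name in indices:
        if name in _SCALAR_INDICES:
            func, sense = _SCALAR_INDICES[name]
            scores = {k: func(X, labels_by_k[k], dist) for k in ks}
            if sense == "max":
                votes[name] = max(ks, key=lambda k: (scores[k], -k))
            else:
                votes[name] = min(ks, key=lambda k: (scores[k], k))
        elif name == "ball_hall":
            votes[name] = _ball_hall_vote(X, labels_by_k, ks)
        elif name == "gap":
            rng = np.random.default_rng(seed)
            votes[name] = _gap_vote(X, labels_by_k, ks, rng)
        else:
            raise ValueError(f"unknown validity index {name!r}")
    return votes


def select_k_from_tree(
    X: np.ndarray,
    Z: np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    indices=DEFAULT_INDICES,
    seed: int = 0,
) -> tuple[int, dict[str, int]]:
    """Modal optimal k over cuts of a linkage tree; ties go to the smallest k."""
    kmin, kmax = k_range
    n = len(X)
    if kmin < 2 or kmax > n - 1 or kmin > kmax:
        raise ValueError(f"k_range {k_range} outside [2, n-1] = [2, {n - 1}]")
    labels_by_k = {
        k: fcluster(Z, t=k, criterion="maxclust") for k in range(kmin, kmax + 1)
    }
    votes = vote_for_k(X, labels_by_k, indices=indices, seed=seed)
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(sorted(counts), key=lambda k: (counts[k], -k))
    return best, votes
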