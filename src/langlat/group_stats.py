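"""Group-level statistics: covariate residualization, repeated-measures
MANOVA (Pillai's trace, Type-III), Tukey HSD post hocs, Pearson chi-square
proportion tests, promax-rotated PCA, and the anatomy comparison.

The repeated-measures MANOVA uses the multivariate approach: within-subject
effects are tested on orthonormal difference contrasts of the repeated
measures, between-subject effects on the subject means, both through a
sum-coded (effects-coded) linear model so that each term's test is a
Type-III test of its coefficients.  Pillai's trace is reported with the
standard F approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "residualize",
    "repeated_manova",
    "tukey_hsd",
    "proportion_test",
    "PcaResult",
    "pca_promax",
    "anatomy_comparison",
]


# --------------------------------------------------------------------------
# Residualization
# --------------------------------------------------------------------------


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + numeric covariates + dummy-coded categoricals."""
    n = len(covariates)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype.kind in "biufc":
            blocks.append(series.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep: list[int] = []
        collinear = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                collinear.append(names[j])
        raise ValueError(f"singular covariate design; collinear columns: {collinear}")
    return X


def residualize(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    covariate_set: list[str] | None = None,
) -> pd.DataFrame:
    """OLS residuals of each score column on the covariates (plus intercept).

    An empty covariate set mean-centres the scores.  Categorical covariates
    are dummy-coded automatically.
    """
    values = scores.to_numpy(dtype=float)
    if covariates is None or (covariate_set is not None and not covariate_set):
        X = np.ones((len(scores), 1))
    else:
        cov = covariates[covariate_set] if covariate_set is not None else covariates
        X = _covariate_design(cov)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return pd.DataFrame(resid, columns=scores.columns, index=scores.index)


# --------------------------------------------------------------------------
# Multivariate linear model with Pillai's trace
# --------------------------------------------------------------------------


def _sum_coding(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(map(str, series.unique()))
    if len(levels) < 2:
        raise ValueError(f"factor {series.name!r} needs >= 2 levels")
    vals = series.astype(str).to_numpy()
    cols = []
    for lev in levels[:-1]:
        c = (vals == lev).astype(float) - (vals == levels[-1]).astype(float)
        cols.append(c)
    return np.column_stack(cols), levels[:-1]


def _between_design(between: pd.DataFrame) -> tuple[np.ndarray, dict[str, slice]]:
    n = len(between)
    main = {f: _sum_coding(between[f])[0] for f in between.columns}
    X_parts = [np.ones((n, 1))]
    terms: dict[str, slice] = {"intercept": slice(0, 1)}
    pos = 1
    factors = list(between.columns)
    for size in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, size):
            block = main[combo[0]]
            for f in combo[1:]:
                block = np.einsum("ni,nj->nij", block, main[f]).reshape(n, -1)
            name = ":".join(combo)
            terms[name] = slice(pos, pos + block.shape[1])
            X_parts.append(block)
            pos += block.shape[1]
    return np.hstack(X_parts), terms


def _pillai_f(H: np.ndarray, E: np.ndarray, q_h: int, v: int) -> tuple[float, float, float, float, float]:
    """Pillai's trace and its F approximation (value, F, df1, df2, p)."""
    p_dim = H.shape[0]
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p_dim, q_h)
    m = (abs(p_dim - q_h) - 1) / 2.0
    nn = (v - p_dim - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    denom = s - V
    if denom <= 0:
        return V, np.inf, df1, df2, 0.0
    F = (df2 / df1) * (V / denom)
    p = float(stats.f.sf(F, df1, df2))
    return V, float(F), df1, df2, p


def _mlm_test(Y: np.ndarray, X: np.ndarray, cols: slice) -> tuple[float, float, float, float, float]:
    """Test H0: coefficients in ``cols`` are zero, multivariate response Y."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    L = np.zeros((cols.stop - cols.start, k))
    for i, j in enumerate(range(cols.start, cols.stop)):
        L[i, j] = 1.0
    LB = L @ B
    M = L @ XtX_inv @ L.T
    H = LB.T @ np.linalg.inv(M) @ LB
    v = n - np.linalg.matrix_rank(X)
    return _pillai_f(H, E, q_h=L.shape[0], v=v)


def _difference_contrasts(p: int) -> np.ndarray:
    """Orthonormal (Helmert-style) contrasts spanning the p-1 differences."""
    C = np.zeros((p, p - 1))
    for j in range(1, p):
        C[:j, j - 1] = 1.0 / j
        C[j, j - 1] = -1.0
        C[:, j - 1] /= np.linalg.norm(C[:, j - 1])
    return C


def repeated_manova(
    dep: pd.DataFrame,
    between: pd.DataFrame,
    within_name: str = "task",
    effects: list[str] | None = None,
) -> pd.DataFrame:
    """Repeated-measures MANOVA over a wide table of repeated measures.

    ``dep`` holds one column per within-subject level (each participant must
    have all levels — rows with missing cells are rejected); ``between``
    holds the grouping factor column(s).  Returns an effect table with
    Pillai's trace, F, dfs and p for every between term, the within main
    effect, and each within x between interaction.
    """
    if dep.isna().any().any():
        bad = dep.index[dep.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing within-level measurements for rows {bad}")
    if len(dep) != len(between):
        raise ValueError("dep and between must have the same length")
    for col in between.columns:
        counts = between[col].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError(f"between factor {col!r} needs >= 2 levels with n >= 2")
    Y = dep.to_numpy(dtype=float)
    n, p = Y.shape
    X, terms = _between_design(between)
    requested = effects or [t for t in terms if t != "intercept"]

    rows = []
    Ymean = Y.mean(axis=1, keepdims=True)
    for term in requested:
        V, F, df1, df2, pv = _mlm_test(Ymean, X, terms[term])
        rows.append((term, "Pillai", V, df1, df2, F, pv))
    if p > 1:
        Yc = Y @ _difference_contrasts(p)
        V, F, df1, df2, pv = _mlm_test(Yc, X, terms["intercept"])
        rows.append((within_name, "Pillai", V, df1, df2, F, pv))
        for term in requested:
            V, F, df1, df2, pv = _mlm_test(Yc, X, terms[term])
            rows.append((f"{within_name}:{term}", "Pillai", V, df1, df2, F, pv))
    out = pd.DataFrame(
        rows, columns=["effect", "statistic", "value", "df1", "df2", "F", "p"]
    )
    if not out["p"].between(0, 1).all():
        raise RuntimeError("p-value outside [0, 1] — numerical failure")
    return out


# --------------------------------------------------------------------------
# Post hocs and proportions
# --------------------------------------------------------------------------


def tukey_hsd(values: pd.Series | np.ndarray, group: pd.Series | np.ndarray) -> pd.DataFrame:
    """Studentized-range adjusted pairwise comparisons (Tukey HSD)."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group).astype(str)
    labels, counts = np.unique(group, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"group(s) with n < 2: {small}")
    res = pairwise_tukeyhsd(values, group)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return pd.DataFrame(
        {
            "group_a": frame["group1"].astype(str),
            "group_b": frame["group2"].astype(str),
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
        }
    )


def proportion_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# --------------------------------------------------------------------------
# PCA with promax rotation
# --------------------------------------------------------------------------


@dataclass
class PcaResult:
    n_components: int
    loadings: pd.DataFrame  # variables x components, promax-rotated
    variance_explained: np.ndarray  # % per retained component, pre-rotation
    scores: pd.DataFrame  # participants x components
    eigenvalues: np.ndarray  # all eigenvalues of the correlation matrix


def _varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation with Kaiser row normalization."""
    p, k = L.shape
    if k < 2:
        return L.copy()
    comm = np.sqrt((L**2).sum(axis=1))
    comm[comm == 0] = 1.0
    A = L / comm[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Ar = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (Ar**3 - Ar @ np.diag((Ar**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return (A @ R) * comm[:, None]


def _promax(L: np.ndarray, power: int = 4) -> np.ndarray:
    """Promax oblique rotation (varimax target raised to ``power``)."""
    X = _varimax(L)
    if X.shape[1] < 2:
        return X
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    return X @ U


def _scree_count(eigenvalues: np.ndarray) -> int:
    """Elbow via acceleration of the eigenvalue profile, Kaiser fallback.

    Retains the components before the largest drop in successive eigenvalue
    differences (the acceleration elbow).  The elbow is accepted when it is
    unique and consistent with the Kaiser line — i.e. every discarded
    component has an eigenvalue below 1; a steep first eigenvalue otherwise
    produces a spurious one-component elbow on profiles whose later
    components still carry above-average variance.  Without a usable elbow,
    the Kaiser count (eigenvalues > 1) is returned.
    """
    lam = np.sort(eigenvalues)[::-1]
    kaiser = int((lam > 1.0).sum()) or 1
    if len(lam) < 3:
        return kaiser
    d = -np.diff(lam)
    accel = d[:-1] - d[1:]  # accel[i-1] -> elbow after component i
    best = float(accel.max())
    if best <= 0 or (np.isclose(accel, best, atol=1e-12).sum() > 1):
        return kaiser
    elbow = int(accel.argmax()) + 1
    if elbow < len(lam) and lam[elbow] > 1.0:
        return kaiser
    return elbow


def pca_promax(
    residuals: pd.DataFrame,
    retain: str | int = "scree",
    promax_power: int = 4,
) -> PcaResult:
    """PCA of the score residuals' correlation matrix with promax rotation.

    ``retain="scree"`` picks the component count from the eigenvalue elbow
    (acceleration criterion with Kaiser fallback); an integer fixes it.
    Variance explained is reported pre-rotation.
    """
    X = residuals.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > {p} observations, got {n}")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Z, rowvar=False)
    lam, vecs = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vecs = np.clip(lam[order], 0.0, None), vecs[:, order]
    if retain == "scree":
        k = _scree_count(lam)
    else:
        k = int(retain)
        if not 1 <= k <= p:
            raise ValueError(f"retain must be in [1, {p}], got {k}")
    load = vecs[:, :k] * np.sqrt(lam[:k])
    # orient each component towards positive mean loading
    signs = np.sign(load.sum(axis=0))
    signs[signs == 0] = 1.0
    load = load * signs
    rotated = _promax(load, power=promax_power)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(rotated, index=residuals.columns, columns=comp_names)
    scores_arr = Z @ rotated @ np.linalg.pinv(rotated.T @ rotated)
    scores = pd.DataFrame(scores_arr, columns=comp_names, index=residuals.index)
    return PcaResult(
        n_components=k,
        loadings=loadings,
        variance_explained=100.0 * lam[:k] / p,
        scores=scores,
        eigenvalues=lam,
    )


# --------------------------------------------------------------------------
# Anatomy comparison
# --------------------------------------------------------------------------


def anatomy_comparison(
    anatomy: pd.DataFrame,
    labels: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Organization x dissociation effects on anatomical asymmetries and CC.

    Grey- and white-matter asymmetries (left minus right) are residualized
    on the covariates and entered in a repeated-measures ANOVA over the
    tissue compartment with organization (TYP = merged typical groups vs
    ATYP) and dissociation as between factors; corpus-callosum volume
    residuals go into a factorial ANOVA with the same factors.  Returns
    (effect table, Tukey pairwise table of the mean asymmetry residual by
    organization x dissociation cell).
    """
    df = anatomy.merge(labels, on="participant_id")
    if covariates is not None:
        df = df.merge(covariates, on="participant_id")
        cov = covariates.drop(columns=["participant_id"])
        cov = cov.set_axis(df.index)
    else:
        cov = None
    org = df["group"].map(
        lambda g: "ATYP" if str(g).startswith("ATYP") else "TYP"
    )
    between = pd.DataFrame(
        {"organization": org, "dissociation": df["dissociation"]}
    )
    asym = pd.DataFrame(
        {
            "gm_asym": df["gm_left"] - df["gm_right"],
            "wm_asym": df["wm_left"] - df["wm_right"],
            "cc_volume": df["cc_volume"],
        }
    )
    resid = residualize(asym, cov)
    effects_asym = repeated_manova(
        resid[["gm_asym", "wm_asym"]], between, within_name="compartment"
    )
    effects_asym.insert(0, "variable", "tissue_asymmetry")
    effects_cc = repeated_manova(resid[["cc_volume"]], between)
    effects_cc.insert(0, "variable", "cc_volume")
    effects = pd.concat([effects_asym, effects_cc], ignore_index=True)
    cell = between["organization"] + "_" + between["dissociation"].astype(str)
    pairwise = tukey_hsd(
        resid[["gm_asym", "wm_asym"]].mean(axis=1), cell
    )
    return effects, pairwise
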