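"""PCA scores, PERMANOVA, PLS-based VIP ranking, and monotone stage trends.

PERMANOVA follows the classical one-way formulation on a distance matrix:
SS_total = Σ_{i<j} d²ᵢⱼ / n, SS_within sums the same quantity within each
group, pseudo-F = (SS_between/df_b)/(SS_within/df_w), and the p-value is
the add-one permutation fraction (1 + #{F_perm ≥ F_obs}) / (1 + n_perm),
so p is never reported as zero.  VIP scores come from a NIPALS partial
least squares fit against a one-vs-rest cluster indicator; by
construction the mean squared VIP over predictors equals one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .diffstats import bh_adjust
from .exceptions import DegenerateDataError, ValidationError


def pca_scores(
    X: np.ndarray, n_components: int = 2, scale: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA via SVD with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive, making repeated runs bit-identical.  Returns (scores,
    explained-variance ratios, loadings).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise DegenerateDataError("constant matrix has no principal components")
    if scale:
        sd = X.std(axis=0)
        Xc = Xc / np.where(sd < 1e-12, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    loadings = pca.components_
    for a in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[a])))
        if loadings[a, j] < 0:
            loadings[a] *= -1
            scores[:, a] *= -1
    return scores, pca.explained_variance_ratio_, loadings


@dataclass
class PermanovaResult:
    r2: float
    f_stat: float
    p: float
    n_perm: int


def _permanova_ss(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova_f(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R²) for one labeling of a squared-distance matrix."""
    n = D2.shape[0]
    a = np.unique(groups).size
    ss_total, ss_within = _permanova_ss(D2, groups)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    X: np.ndarray | None = None,
    groups=None,
    D: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "euclidean",
) -> PermanovaResult:
    """One-way PERMANOVA with seeded label permutations.

    Provide either a samples × features matrix ``X`` (distances computed
    with ``metric``, Euclidean by default) or a precomputed distance
    matrix ``D``.
    """
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    for g, c in zip(*np.unique(groups, return_counts=True)):
        if c < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    if D is None:
        if X is None:
            raise ValidationError("provide X or D")
        D = squareform(pdist(np.asarray(X, dtype=float), metric=metric))
    D = np.asarray(D, dtype=float)
    if D.shape[0] != groups.size:
        raise ValidationError("distance matrix and groups disagree on n")
    D2 = D**2
    f_obs, r2 = permanova_f(D2, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = permanova_f(D2, rng.permutation(groups))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(r2=r2, f_stat=f_obs, p=float(p), n_perm=n_perm)


@dataclass
class VipRanking:
    vip: pd.DataFrame  # features × clusters
    top: dict  # cluster -> ordered list of top-k features
    shared: set  # features appearing in the top-k of >= 2 clusters


def _vip_scores(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """VIPⱼ = sqrt(p · Σ_a SSYₐ (wⱼₐ/‖wₐ‖)² / Σ_a SSYₐ) from a PLS fit."""
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y.astype(float))
    W = pls.x_weights_  # (p, A)
    T = pls.x_scores_  # (n, A)
    Q = pls.y_loadings_  # (1, A)
    p = X.shape[1]
    ssy = (T**2).sum(axis=0) * Q.ravel() ** 2
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())
    return vip


def pls_vip(
    X: pd.DataFrame | np.ndarray,
    labels,
    n_components: int = 2,
    top_k: int = 20,
) -> VipRanking:
    """Per-cluster VIP ranking from one-vs-rest PLS models.

    ``labels`` assigns each sample (pixel or subject) to a cluster; one
    PLS model is fitted per cluster against its one-vs-rest indicator.
    Features appearing in the top-k of two or more clusters are flagged
    as shared.
    """
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        features = [f"f{i}" for i in range(M.shape[1])]
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("need at least 2 clusters for one-vs-rest PLS")
    if M.shape[0] <= n_components:
        raise ValidationError("n_samples must exceed n_components")
    cols = {}
    top = {}
    for c in np.unique(labels):
        y = (labels == c).astype(float)
        vip = _vip_scores(M, y, n_components)
        s = pd.Series(vip, index=features)
        cols[c] = s
        top[c] = list(s.sort_values(ascending=False).head(top_k).index)
    vip_df = pd.DataFrame(cols)
    counts: dict[str, int] = {}
    for lst in top.values():
        for f in lst:
            counts[f] = counts.get(f, 0) + 1
    shared = {f for f, k in counts.items() if k >= 2}
    return VipRanking(vip=vip_df, top=top, shared=shared)


def trend_volcano(
    matrix: pd.DataFrame,
    stages: pd.Series,
    alpha: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """Monotone-increase screen across ordered disease stages.

    Spearman ρ of each metabolite against the stage code (0 = MGUS
    non-progressive, 1 = progressive MGUS, 2 = MM), BH-adjusted across
    metabolites; ``monotone`` requires ρ > 0 and q < alpha (one-sided by
    design: decreasing metabolites are never flagged).  ``strict``
    additionally requires non-decreasing stage medians.
    """
    codes = stages.loc[matrix.index].to_numpy()
    if np.unique(codes).size < 2:
        raise ValidationError("need subjects in at least 2 stages")
    rows = []
    for met in matrix.columns:
        x = matrix[met].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append({"metabolite": met, "spearman_rho": np.nan, "p": 1.0})
            continue
        res = stats.spearmanr(x, codes)
        rows.append(
            {
                "metabolite": met,
                "spearman_rho": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = bh_adjust(out["p"].to_numpy())
    monotone = (out["spearman_rho"] > 0) & (out["q"] < alpha)
    if strict:
        ok = []
        for met in out.index:
            med = [
                np.median(matrix.loc[codes == s, met])
                for s in sorted(np.unique(codes))
            ]
            ok.append(bool(np.all(np.diff(med) >= 0)))
        monotone &= pd.Series(ok, index=out.index)
    out["monotone"] = monotone
    return out
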