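"""Pixel normalization, bisecting k-means segmentation and niche calling.

The segmentation strategy mirrors common MSI practice: each pixel spectrum
is scaled to unit total ion current (TIC), log-transformed and per-feature
z-scored within the section, then partitioned by bisecting k-means with
the *largest within-cluster sum of squares* split rule — the most
heterogeneous region is split first.  The plasma-cell-rich clusters are
then called from a marker feature set, and the resulting per-subject niche
pixel fraction is validated against conventional pathology (marrow
plasma-cell percentage) via correlation on variance-stabilized scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array

from ._utils import logit
from .exceptions import DegenerateDataError, ValidationError
from .io import MSIDataset

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Per-pixel labels plus the bisecting split tree and niche call."""

    labels: np.ndarray  # per-pixel cluster ids in 0..K-1
    tree: list[dict]  # one entry per split: parent, sse_before, children
    niche_labels: set[int] = field(default_factory=set)
    niche_fraction: float = 0.0
    flagged: bool = False  # True when no cluster passed the marker threshold

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def normalize_pixels(data: MSIDataset) -> MSIDataset:
    """TIC-scale each pixel, log1p, then per-feature z-score.

    All-zero pixels are dropped with a warning.  Constant features z-score
    to exactly zero (the standard deviation is clamped).  The TIC step is
    idempotent: re-normalizing an already TIC-scaled matrix changes
    nothing.
    """
    X = data.intensities
    tic = X.sum(axis=1)
    keep = tic > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero pixels in section "
            f"{data.section_id!r}",
            stacklevel=2,
        )
    X = X[keep] / tic[keep, None]
    X = np.log1p(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mu) / sd
    return MSIDataset(
        section_id=data.section_id,
        subject_id=data.subject_id,
        coords=data.coords[keep],
        intensities=Z,
        feature_ids=list(data.feature_ids),
        feature_mz=data.feature_mz,
        normalized=True,
    )


def tic_normalize(data: MSIDataset) -> MSIDataset:
    """TIC scaling only (each pixel sums to 1); used to build diversity
    abundance profiles, which must stay non-negative."""
    X = data.intensities
    tic = X.sum(axis=1)
    keep = tic > 0
    return MSIDataset(
        section_id=data.section_id,
        subject_id=data.subject_id,
        coords=data.coords[keep],
        intensities=X[keep] / tic[keep, None],
        feature_ids=list(data.feature_ids),
        feature_mz=data.feature_mz,
    )


def _cluster_sse(X: np.ndarray, idx: np.ndarray) -> float:
    sub = X[idx]
    if sub.shape[0] < 2:
        return 0.0
    c = sub.mean(axis=0)
    return float(((sub - c) ** 2).sum())


class BisectingKMeans(ClusterMixin, BaseEstimator):
    """Bisecting k-means with the largest-SSE split rule.

    Starts from a single cluster and repeatedly splits the cluster with
    the largest within-cluster sum of squared Euclidean distances using
    2-means (k-means++ initialization, best of ``n_restarts``), until
    ``n_clusters`` clusters exist.  Deterministic for a fixed
    ``random_state``.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Final cluster labels in ``0..n_clusters-1``.
    tree_ : list of dict
        One entry per split with keys ``parent`` (cluster id split),
        ``sse_before`` (its SSE before the split) and ``children``
        (the two resulting cluster ids; the first reuses the parent id).
    inertia_ : float
        Total within-cluster SSE of the final partition.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_restarts: int = 10,
        random_state: int | None = 0,
        max_split_retries: int = 5,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.max_split_retries = max_split_retries

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        K = self.n_clusters
        if K < 1:
            raise ValidationError("n_clusters must be >= 1")
        if K > n:
            raise ValidationError(f"n_clusters={K} exceeds n_samples={n}")

        ss = np.random.SeedSequence(self.random_state)
        split_seeds = ss.generate_state(max(K - 1, 1) * (self.max_split_retries + 1))

        labels = np.zeros(n, dtype=int)
        sse = {0: _cluster_sse(X, np.arange(n))}
        tree: list[dict] = []
        next_id = 1
        seed_i = 0
        while next_id < K:
            # split the cluster with the largest SSE; ties -> lowest id
            candidates = [
                c for c in sorted(sse) if (labels == c).sum() >= 2 and sse[c] > 1e-12
            ]
            if not candidates:
                raise ValidationError(
                    "cannot reach the requested number of clusters: no "
                    "remaining cluster is splittable"
                )
            parent = max(candidates, key=lambda c: (sse[c], -c))
            idx = np.nonzero(labels == parent)[0]
            sub_labels = None
            for _ in range(self.max_split_retries):
                km = KMeans(
                    n_clusters=2,
                    n_init=self.n_restarts,
                    init="k-means++",
                    random_state=int(split_seeds[seed_i] % (2**31 - 1)),
                )
                seed_i += 1
                trial = km.fit_predict(X[idx])
                if len(np.unique(trial)) == 2:
                    sub_labels = trial
                    break
            if sub_labels is None:
                raise ValidationError(
                    f"2-means split of cluster {parent} repeatedly produced "
                    "an empty child"
                )
            child = next_id
            labels[idx[sub_labels == 1]] = child
            tree.append(
                {"parent": parent, "sse_before": sse[parent], "children": (parent, child)}
            )
            sse[parent] = _cluster_sse(X, np.nonzero(labels == parent)[0])
            sse[child] = _cluster_sse(X, np.nonzero(labels == child)[0])
            next_id += 1

        self.labels_ = labels
        self.tree_ = tree
        self.inertia_ = float(sum(sse.values()))
        self.cluster_sse_ = sse
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def bisecting_kmeans(X: np.ndarray, K: int, seed: int = 0) -> SegmentationResult:
    """Functional wrapper over :class:`BisectingKMeans`."""
    model = BisectingKMeans(n_clusters=K, random_state=seed).fit(X)
    return SegmentationResult(labels=model.labels_, tree=model.tree_)


def call_niche_clusters(
    seg: SegmentationResult,
    data: MSIDataset,
    markers: list[str],
    threshold: float = 0.0,
) -> SegmentationResult:
    """Designate plasma-cell-rich clusters from a marker feature set.

    Marker scores are per-feature z-scores of log-intensities *without*
    TIC scaling — marker abundance is the biological signal, and dividing
    by total ion current would couple it to unrelated dominant features.
    Cluster mean marker scores are sorted and cut at their largest gap;
    the clusters on the high side are called niche, provided the maximal
    mean exceeds ``threshold`` (default 0) — otherwise the niche set is
    empty, the fraction is 0 and the result is flagged.  The gap rule
    recombines large niches that the SSE-first split rule subdivided: in
    a majority-niche section the z-score center lies inside the niche, so
    a flat positivity cut would drop true niche subclusters.
    """
    if not markers:
        raise ValidationError("marker feature list must be non-empty")
    if data.n_pixels != seg.labels.shape[0]:
        raise ValidationError("segmentation labels do not match pixel count")
    cols = [data.feature_index(m) for m in markers]
    if data.normalized:
        M = data.intensities[:, cols]
    else:
        M = np.log1p(data.intensities[:, cols])
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    marker_z = ((M - mu) / sd).mean(axis=1)
    means = {
        int(c): float(marker_z[seg.labels == c].mean())
        for c in np.unique(seg.labels)
    }
    order = sorted(means, key=means.get, reverse=True)
    niche: set[int] = set()
    if means[order[0]] > threshold:
        if len(order) == 1:
            niche = {order[0]}
        else:
            gaps = [means[a] - means[b] for a, b in zip(order, order[1:])]
            cut = int(np.argmax(gaps))
            niche = set(order[: cut + 1])
    flagged = len(niche) == 0
    frac = (
        0.0
        if flagged
        else float(np.isin(seg.labels, list(niche)).mean())
    )
    if flagged:
        logger.warning(
            "no cluster exceeded the marker threshold in section %s "
            "(cluster marker means: %s)",
            data.section_id,
            means,
        )
    return SegmentationResult(
        labels=seg.labels,
        tree=seg.tree,
        niche_labels=niche,
        niche_fraction=frac,
        flagged=flagged,
    )


def segment_section(
    data: MSIDataset,
    K: int = 4,
    seed: int = 0,
    markers: list[str] | None = None,
) -> SegmentationResult:
    """Normalize, cluster at K, and (optionally) call niche clusters.

    Clustering runs on TIC + log + z-scored spectra; niche calling scores
    the markers on the raw (un-TIC'd) log intensities of the same pixels.
    """
    norm = normalize_pixels(data)
    seg = bisecting_kmeans(norm.intensities, K, seed=seed)
    if markers is not None:
        raw_kept = data
        if norm.n_pixels != data.n_pixels:
            keep = data.intensities.sum(axis=1) > 0
            raw_kept = MSIDataset(
                section_id=data.section_id,
                subject_id=data.subject_id,
                coords=data.coords[keep],
                intensities=data.intensities[keep],
                feature_ids=list(data.feature_ids),
                feature_mz=data.feature_mz,
            )
        seg = call_niche_clusters(seg, raw_kept, markers)
    return seg


@dataclass
class ConcordanceResult:
    x: np.ndarray  # log10(niche fraction + 1e-4)
    y: np.ndarray  # logit(pc_percent)
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def concordance(
    niche_fractions: np.ndarray, pc_percents: np.ndarray
) -> ConcordanceResult:
    """Niche-fraction vs pathology plasma-cell-percentage concordance.

    Pearson is computed on transformed scales (x = log10(fraction + 1e-4),
    y = logit(pc)) to satisfy linearity/normality assumptions; Spearman is
    computed on the original scales.
    """
    f = np.asarray(niche_fractions, dtype=float)
    pc = np.asarray(pc_percents, dtype=float)
    if f.shape != pc.shape or f.ndim != 1 or f.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.std(f) == 0 or np.std(pc) == 0:
        raise DegenerateDataError("correlation undefined: zero variance input")
    x = np.log10(f + 1e-4)
    y = logit(pc)
    pr = stats.pearsonr(x, y)
    sp = stats.spearmanr(f, pc)
    return ConcordanceResult(
        x=x,
        y=y,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sp.statistic),
        spearman_p=float(sp.pvalue),
    )


def simpson_index(proportions: np.ndarray) -> float:
    """Simpson's diversity index 1 − Σp² of a cluster-proportion vector."""
    p = np.asarray(proportions, dtype=float)
    return float(1.0 - np.sum(p**2))


def spatial_heterogeneity(
    data: MSIDataset, K: int = 6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cluster a section at K (default 6) and summarize heterogeneity.

    Returns (labels, cluster_proportions, Simpson index).
    """
    if K < 2:
        raise ValidationError("K must be >= 2")
    norm = data if data.normalized else normalize_pixels(data)
    seg = bisecting_kmeans(norm.intensities, K, seed=seed)
    _, counts = np.unique(seg.labels, return_counts=True)
    props = counts / counts.sum()
    return seg.labels, props, simpson_index(props)
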