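"""Microwell single-cell secretion signal processing.

The chain mirrors how antibody-barcode microwell assays are processed once
per-well intensities have been extracted from the scanned images:

1. :func:`background_normalize` — subtract, per analyte, the local
   background estimated from zero-cell wells (a moving Gaussian fit along
   the array's row-major order; the fitted location is subtracted).
2. :func:`compute_thresholds` — the 99th percentile of the normalized
   zero-cell wells defines each analyte's secretion threshold.
3. :func:`arcsinh_transform` — inverse hyperbolic sine with cofactor
   0.8 x threshold, compressing bright secretors while staying linear
   (and defined) around and below zero.
4. :func:`call_secretion` — positive calls (strictly above threshold) on
   single-cell wells, then co-secretion fractions, odds ratios, and
   consensus ensemble clustering of the transformed profiles.

Every stage records its parameters so a processed chip is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans

WELL_COLUMNS = ("well_id", "row", "col", "cell_count")


@dataclass
class SecretionChip:
    """A microwell chip: one row per well with array coordinates, live-cell
    count and per-analyte intensity (a.f.u.). ``normalized`` marks whether
    the intensities are background-subtracted."""

    wells: pd.DataFrame
    analytes: list[str]
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"chip table missing columns: {missing}")
        missing = [a for a in self.analytes if a not in self.wells.columns]
        if missing:
            raise ValueError(f"chip table missing analyte columns: {missing}")
        vals = self.wells[self.analytes].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite intensity values in chip table")
        if (self.wells["cell_count"] < 0).any():
            raise ValueError("negative cell counts in chip table")

    @property
    def zero_cell_mask(self) -> np.ndarray:
        return (self.wells["cell_count"] == 0).to_numpy()

    def intensities(self) -> pd.DataFrame:
        df = self.wells[self.analytes].copy()
        df.index = self.wells["well_id"].to_numpy()
        return df


def background_normalize(chip: SecretionChip, window: int = 50) -> SecretionChip:
    """Subtract the local zero-cell background from every well.

    For each well, the ``window`` zero-cell wells nearest in row-major
    array order are selected (a contiguous run of the ordered zero-cell
    wells, centred on the well's position) and a Gaussian is fitted to
    their intensities per analyte; the fitted location (mean) is
    subtracted. Zero-cell wells thereby centre near 0, which calibrates
    the percentile thresholds downstream.
    """
    if chip.normalized:
        raise ValueError("chip is already normalized")
    if window < 1:
        raise ValueError("window must be >= 1")
    order = np.argsort(
        (chip.wells["row"] * (chip.wells["col"].max() + 1) + chip.wells["col"]).to_numpy(),
        kind="stable",
    )
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))

    zero = chip.zero_cell_mask
    n_zero = int(zero.sum())
    if n_zero < window:
        raise ValueError(
            f"need at least window={window} zero-cell wells, found {n_zero}"
        )
    zero_ranks = np.sort(rank[zero])
    raw = chip.wells[chip.analytes].to_numpy(float)
    zero_vals = raw[np.argsort(rank)][zero_ranks]  # zero wells in row-major order

    # contiguous window of zero-cell wells centred on each well's position;
    # accumulating deviations from a reference keeps a constant background
    # exactly zero after subtraction
    pos = np.searchsorted(zero_ranks, rank)
    start = np.clip(pos - window // 2, 0, n_zero - window)
    ref = zero_vals[0]
    csum = np.vstack([np.zeros(len(chip.analytes)),
                      np.cumsum(zero_vals - ref, axis=0)])
    local_mean = ref + (csum[start + window] - csum[start]) / window

    wells = chip.wells.copy()
    wells[chip.analytes] = raw - local_mean
    meta = dict(chip.meta)
    meta.update({"background_window": window, "background_statistic": "gaussian_location"})
    return SecretionChip(wells=wells, analytes=list(chip.analytes),
                         normalized=True, meta=meta)


def compute_thresholds(chip: SecretionChip, percentile: float = 99.0) -> pd.Series:
    """Per-analyte secretion threshold: the given percentile (linear
    interpolation between order statistics) of normalized zero-cell wells."""
    if not chip.normalized:
        raise ValueError("normalize the chip before computing thresholds")
    zero = chip.zero_cell_mask
    if not zero.any():
        raise ValueError("no zero-cell wells to compute thresholds from")
    vals = chip.wells.loc[zero, chip.analytes].to_numpy(float)
    thr = np.percentile(vals, percentile, axis=0)  # linear interpolation
    return pd.Series(thr, index=list(chip.analytes), name="threshold")


def arcsinh_transform(values, threshold):
    """asinh(x / (0.8 * threshold)) — monotone, defined for negative x."""
    threshold = np.asarray(threshold, dtype=float)
    if np.any(threshold <= 0):
        raise ValueError("threshold must be > 0 for the arcsinh transform")
    return np.arcsinh(np.asarray(values, dtype=float) / (0.8 * threshold))


@dataclass
class SecretionCalls:
    """Per single-cell well, per analyte: normalized intensity, arcsinh
    transform, and positive call (strictly above the analyte threshold)."""

    normalized: pd.DataFrame
    transformed: pd.DataFrame
    positive: pd.DataFrame
    thresholds: pd.Series

    @property
    def analytes(self) -> list[str]:
        return list(self.normalized.columns)


def call_secretion(chip: SecretionChip, thresholds: pd.Series) -> SecretionCalls:
    """Positive secretion calls on single-cell wells (cell_count == 1)."""
    if not chip.normalized:
        raise ValueError("normalize the chip before calling secretion")
    single = (chip.wells["cell_count"] == 1).to_numpy()
    sub = chip.wells.loc[single]
    norm = sub[chip.analytes].copy()
    norm.index = sub["well_id"].to_numpy()
    thr = thresholds.reindex(chip.analytes)
    if thr.isna().any():
        raise ValueError("thresholds missing for some analytes")
    transformed = pd.DataFrame(
        arcsinh_transform(norm.to_numpy(), thr.to_numpy()),
        index=norm.index, columns=norm.columns,
    )
    positive = norm.gt(thr, axis=1)
    return SecretionCalls(normalized=norm, transformed=transformed,
                          positive=positive, thresholds=thr)


def call_and_quantify(
    calls: SecretionCalls, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Single/double-positive fractions for analyte pairs.

    Columns ``pos_neg, neg_pos, pos_pos, neg_neg`` are the fractions of
    single-cell wells that are (first+ second-), (first- second+), double
    positive and double negative; each row sums to 1.
    """
    rows = {}
    n = len(calls.positive)
    for a, b in pairs:
        pa = calls.positive[a].to_numpy()
        pb = calls.positive[b].to_numpy()
        rows[f"{a}|{b}"] = {
            "pos_neg": float((pa & ~pb).sum()) / n,
            "neg_pos": float((~pa & pb).sum()) / n,
            "pos_pos": float((pa & pb).sum()) / n,
            "neg_neg": float((~pa & ~pb).sum()) / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def secretion_odds_ratios(calls: SecretionCalls, features: Sequence[str] | None = None,
                          mask_p: float = 0.05):
    """Pairwise log2 odds ratios between positive secretion calls
    (delegates to :func:`costim.orthogonality.pairwise_odds_ratios`)."""
    from .orthogonality import BinaryMatrix, pairwise_odds_ratios

    binary = BinaryMatrix(values=calls.positive, thresholds=calls.thresholds,
                          provenance="secretion")
    return pairwise_odds_ratios(binary, features=features, mask_p=mask_p)


@dataclass(frozen=True)
class SweepConfig:
    """Base-clustering sweep for the consensus ensemble.

    The default sweep (k-means plus agglomerative with average/complete
    linkage under euclidean/cosine distances, across ``k_values``) is
    deterministic given the seed. Affinity propagation, spectral and
    Birch members are deliberately not part of the default sweep.
    """

    k_values: tuple[int, ...] = tuple(range(2, 13))
    linkages: tuple[str, ...] = ("average", "complete")
    metrics: tuple[str, ...] = ("euclidean", "cosine")
    include_kmeans: bool = True
    cut_threshold: float = 0.5
    min_cluster_size: int = 3


@dataclass
class ConsensusClustering:
    """Result of the ensemble: base partitions (with the generating
    parameters as names), the well x well co-occurrence matrix, consensus
    labels (-1 = unassigned after the <min_cluster_size discard rule),
    and the discarded cluster sizes."""

    base_partitions: list[tuple[str, np.ndarray]]
    co_occurrence: np.ndarray
    labels: pd.Series
    discarded: list[int]


class ConsensusClusterer(BaseEstimator, ClusterMixin):
    """Consensus ensemble clustering over a sweep of base clusterings.

    Each base partition votes on whether two observations belong
    together; the co-occurrence matrix (fraction of partitions placing a
    pair together) is linked by average-linkage agglomerative clustering
    on distance 1 - co-occurrence, cut at ``cut_threshold``. Consensus
    clusters smaller than ``min_cluster_size`` are discarded and their
    members labeled -1.

    Attributes (after :meth:`fit`): ``labels_``, ``co_occurrence_``,
    ``base_partitions_``, ``discarded_``.
    """

    def __init__(self, k_values=tuple(range(2, 13)), linkages=("average", "complete"),
                 metrics=("euclidean", "cosine"), include_kmeans=True,
                 cut_threshold=0.5, min_cluster_size=3, random_state=0):
        self.k_values = k_values
        self.linkages = linkages
        self.metrics = metrics
        self.include_kmeans = include_kmeans
        self.cut_threshold = cut_threshold
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least 2 features")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 observations")
        if np.all(X == X[0]):
            # identical profiles: one cluster, trivially unanimous
            n = X.shape[0]
            labels = np.zeros(n, dtype=int)
            self.base_partitions_ = [("degenerate:identical-rows", labels.copy())]
            self.co_occurrence_ = np.ones((n, n))
            self.labels_ = labels
            self.discarded_ = []
            self.n_features_in_ = X.shape[1]
            return self
        partitions: list[tuple[str, np.ndarray]] = []
        for k in self.k_values:
            if k >= X.shape[0]:
                continue
            if self.include_kmeans:
                km = KMeans(n_clusters=k, n_init=10, random_state=self.random_state)
                partitions.append((f"kmeans:k={k}", km.fit_predict(X)))
            for linkage in self.linkages:
                for metric in self.metrics:
                    agg = AgglomerativeClustering(
                        n_clusters=k, linkage=linkage, metric=metric
                    )
                    partitions.append(
                        (f"agglomerative:{linkage}:{metric}:k={k}", agg.fit_predict(X))
                    )
        if not partitions:
            raise ValueError("empty base-clustering sweep")

        n = X.shape[0]
        cooc = np.zeros((n, n), dtype=float)
        for _, labels in partitions:
            cooc += labels[:, None] == labels[None, :]
        cooc /= len(partitions)

        dist = 1.0 - cooc
        np.fill_diagonal(dist, 0.0)
        consensus = AgglomerativeClustering(
            n_clusters=None, distance_threshold=self.cut_threshold,
            metric="precomputed", linkage="average",
        ).fit_predict(dist)

        # discard tiny clusters, relabel survivors by first appearance
        labels = np.full(n, -1, dtype=int)
        discarded: list[int] = []
        next_label = 0
        seen: dict[int, int] = {}
        sizes = pd.Series(consensus).value_counts()
        for i, c in enumerate(consensus):
            if sizes[c] < self.min_cluster_size:
                continue
            if c not in seen:
                seen[c] = next_label
                next_label += 1
            labels[i] = seen[c]
        discarded = sorted(int(sizes[c]) for c in sizes.index
                           if sizes[c] < self.min_cluster_size)

        self.base_partitions_ = partitions
        self.co_occurrence_ = cooc
        self.labels_ = labels
        self.discarded_ = discarded
        self.n_features_in_ = X.shape[1]
        return self


def consensus_cluster(
    X: pd.DataFrame, config: SweepConfig | None = None, seed: int = 0
) -> ConsensusClustering:
    """Run the consensus ensemble on a wells x analytes matrix
    (typically the arcsinh-transformed single-cell profiles)."""
    config = config or SweepConfig()
    est = ConsensusClusterer(
        k_values=config.k_values, linkages=config.linkages, metrics=config.metrics,
        include_kmeans=config.include_kmeans, cut_threshold=config.cut_threshold,
        min_cluster_size=config.min_cluster_size, random_state=seed,
    ).fit(X.to_numpy(float) if isinstance(X, pd.DataFrame) else X)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(est.labels_))
    return ConsensusClustering(
        base_partitions=est.base_partitions_,
        co_occurrence=est.co_occurrence_,
        labels=pd.Series(est.labels_, index=index, name="consensus"),
        discarded=est.discarded_,
    )


def run_pipeline(
    chip: SecretionChip,
    window: int = 50,
    percentile: float = 99.0,
    pairs: Sequence[tuple[str, str]] | None = None,
    cluster_config: SweepConfig | None = None,
    seed: int = 0,
):
    """Full chain: normalize -> threshold -> transform/call -> odds ratios
    and consensus clustering. Returns a dict of stage outputs."""
    normalized = background_normalize(chip, window=window)
    thresholds = compute_thresholds(normalized, percentile=percentile)
    calls = call_secretion(normalized, thresholds)
    out = {
        "normalized": normalized,
        "thresholds": thresholds,
        "calls": calls,
        "odds_ratios": secretion_odds_ratios(calls),
        "clustering": consensus_cluster(calls.transformed, cluster_config, seed=seed),
    }
    if pairs:
        out["fractions"] = call_and_quantify(calls, pairs)
    return out
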