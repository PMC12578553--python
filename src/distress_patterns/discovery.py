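"""Two-stage UMAP -> HDBSCAN pattern discovery.

Stage 1 clusters the 16 questionnaire *items* (each item represented as the
vector of its z-scored values across patients) into symptom clusters, then
assigns each item the weight 1/|its cluster| so every symptom cluster
carries identical total weight.  Stage 2 embeds the reweighted *patients*
and clusters them density-based, keeping a noise label for patients that
belong to no pattern, merging undersized clusters into their nearest
neighbouring cluster, and naming each final pattern by its most elevated
items.

Reproducibility note: umap-learn's spectral initialisation of disconnected
neighbour graphs draws from the global NumPy RNG, so every embedding call
here seeds ``numpy.random`` explicitly and the item stage uses a seeded
random initialisation; given a fixed pipeline seed the whole procedure is
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .scales import ITEM_COLUMNS, validate_items

logger = logging.getLogger("distress_patterns")

NOISE = -1

#: Cohort size at which the patient-stage density parameters were chosen.
REFERENCE_N = 11_376
REFERENCE_MIN_PTS = 95
REFERENCE_MIN_SIZE = 200


@dataclass(frozen=True)
class UMAPParams:
    n_neighbors: int
    n_components: int = 2
    min_dist: float = 0.01
    n_epochs: int = 500
    metric: str = "euclidean"
    init: str = "spectral"
    seed: int = 42

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")


@dataclass(frozen=True)
class HDBSCANParams:
    """Density parameters.  ``min_pts`` maps onto both the minimum cluster
    size and the core-point neighbour count (DBSCAN* semantics); either can
    be overridden independently."""

    min_pts: int = 2
    min_cluster_size: int | None = None
    min_samples: int | None = None

    def __post_init__(self):
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")

    @property
    def effective_min_cluster_size(self):
        return self.min_cluster_size or self.min_pts

    @property
    def effective_min_samples(self):
        return self.min_samples or self.min_pts


# Stage defaults exactly as selected for the reference cohort.
STAGE1_UMAP = UMAPParams(n_neighbors=2, init="random")
STAGE1_HDBSCAN = HDBSCANParams(min_pts=2)
STAGE2_UMAP = UMAPParams(n_neighbors=30)
STAGE2_HDBSCAN = HDBSCANParams(min_pts=REFERENCE_MIN_PTS)


def scaled_min_pts(n: int) -> int:
    """Proportional fallback for cohorts much smaller than the reference."""
    return max(5, round(REFERENCE_MIN_PTS * n / REFERENCE_N))


def scaled_min_size(n: int) -> int:
    return max(10, round(REFERENCE_MIN_SIZE * n / REFERENCE_N))


@dataclass
class DiscoveryConfig:
    stage1_umap: UMAPParams = STAGE1_UMAP
    stage1_hdbscan: HDBSCANParams = STAGE1_HDBSCAN
    stage2_umap: UMAPParams = STAGE2_UMAP
    stage2_hdbscan: HDBSCANParams = STAGE2_HDBSCAN
    min_pattern_size: int = REFERENCE_MIN_SIZE
    naming_margin: float = 0.5
    auto_scale: bool = False  # scale min_pts/min_size proportionally with n

    def for_n(self, n: int) -> "DiscoveryConfig":
        """Resolve auto-scaling against an actual cohort size."""
        if not self.auto_scale:
            return self
        return DiscoveryConfig(
            stage1_umap=self.stage1_umap,
            stage1_hdbscan=self.stage1_hdbscan,
            stage2_umap=self.stage2_umap,
            stage2_hdbscan=HDBSCANParams(min_pts=scaled_min_pts(n)),
            min_pattern_size=scaled_min_size(n),
            naming_margin=self.naming_margin,
            auto_scale=False,
        )


# ---------------------------------------------------------------------------
# Deterministic UMAP wrapper
# ---------------------------------------------------------------------------

def _fit_umap(data: np.ndarray, params: UMAPParams):
    """Fit UMAP deterministically (global RNG seeded, single-threaded)."""
    import umap

    np.random.seed(params.seed)  # spectral init of disconnected graphs uses it
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value")
        warnings.filterwarnings("ignore", message="Graph is not fully connected")
        model = umap.UMAP(
            n_neighbors=params.n_neighbors,
            n_components=params.n_components,
            min_dist=params.min_dist,
            n_epochs=params.n_epochs,
            metric=params.metric,
            init=params.init,
            random_state=params.seed,
        )
        embedding = model.fit_transform(np.asarray(data, dtype=np.float32))
    return model, np.asarray(embedding, dtype=np.float64)


def _run_hdbscan(embedding: np.ndarray, params: HDBSCANParams):
    clusterer = HDBSCAN(
        min_cluster_size=params.effective_min_cluster_size,
        min_samples=params.effective_min_samples,
        copy=True, store_centers="centroid",
    )
    labels = clusterer.fit_predict(embedding)
    return clusterer, labels


# ---------------------------------------------------------------------------
# Stage 1: items
# ---------------------------------------------------------------------------

def embed_items(items: pd.DataFrame, params: UMAPParams = STAGE1_UMAP) -> pd.DataFrame:
    """Embed the 16 items; rows of the result are items, columns UMAP axes.

    Each item is the vector of its z-scored scores across patients, so the
    item-item geometry is driven by inter-item correlation.
    """
    items = validate_items(items)
    if len(items) < params.n_neighbors:
        raise ValueError("need at least n_neighbors patients")
    std = items.std(axis=0, ddof=0)
    constant = std.index[std == 0].tolist()
    if constant:
        raise ValueError(f"constant (zero-variance) items: {constant}")
    z = (items - items.mean(axis=0)) / std
    _, emb = _fit_umap(z.to_numpy().T, params)
    return pd.DataFrame(emb, index=list(items.columns),
                        columns=[f"umap{i+1}" for i in range(params.n_components)])


@dataclass
class SymptomClusterMap:
    """Item -> symptom-cluster assignment (every item assigned, no noise)."""

    assignments: pd.Series  # index: item name, value: cluster id 0..C-1

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def members(self, cluster: int):
        return self.assignments.index[self.assignments == cluster].tolist()


def cluster_items(item_embedding: pd.DataFrame,
                  params: HDBSCANParams = STAGE1_HDBSCAN) -> SymptomClusterMap:
    """Density-cluster the embedded items.

    Items the algorithm marks as noise are reassigned to the nearest cluster
    by embedding distance -- every item must carry a weight downstream.
    """
    emb = item_embedding.to_numpy()
    if len(emb) < 2 * params.effective_min_cluster_size:
        raise ValueError("too few items for the requested min_pts")
    _, labels = _run_hdbscan(emb, params)
    if (labels == NOISE).all():
        raise ValueError(
            "all items labelled noise; decrease min_pts or inspect the embedding")
    labels = labels.copy()
    for i in np.where(labels == NOISE)[0]:
        dist = np.linalg.norm(emb - emb[i], axis=1)
        dist[labels == NOISE] = np.inf
        labels[i] = labels[int(np.argmin(dist))]
    # contiguous ids ordered by first appearance
    order = {old: new for new, old in enumerate(pd.unique(labels))}
    labels = np.array([order[v] for v in labels])
    return SymptomClusterMap(pd.Series(labels, index=item_embedding.index, name="symptom_cluster"))


@dataclass
class ItemWeights:
    weights: pd.Series  # index: item name

    def __post_init__(self):
        if (self.weights <= 0).any():
            raise ValueError("item weights must be positive")


def compute_item_weights(cluster_map: SymptomClusterMap) -> ItemWeights:
    """w(item) = 1 / |cluster(item)|, so each symptom cluster's weights sum
    to exactly 1 (equal importance across clusters)."""
    sizes = cluster_map.sizes
    if (sizes == 0).any():
        raise ValueError("empty symptom cluster")
    w = cluster_map.assignments.map(lambda c: 1.0 / sizes[c])
    return ItemWeights(w.rename("weight"))


def reweight(items: pd.DataFrame, weights: ItemWeights) -> pd.DataFrame:
    """Column-wise multiplication of item scores by their weights."""
    missing = [c for c in items.columns if c not in weights.weights.index]
    if missing:
        raise ValueError(f"missing weights for items: {missing}")
    return items * weights.weights[items.columns]


# ---------------------------------------------------------------------------
# Stage 2: patients
# ---------------------------------------------------------------------------

@dataclass
class PatternAssignment:
    labels: pd.Series        # per-patient pattern id, noise = -1
    embedding: pd.DataFrame  # per-patient stage-2 coordinates

    @property
    def n_patterns(self) -> int:
        return int(self.labels.max()) + 1 if (self.labels >= 0).any() else 0

    @property
    def noise_fraction(self) -> float:
        return float((self.labels == NOISE).mean())

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels >= 0].value_counts().sort_index()


def cluster_patients(weighted: pd.DataFrame,
                     umap_params: UMAPParams = STAGE2_UMAP,
                     hdbscan_params: HDBSCANParams = STAGE2_HDBSCAN):
    """Embed reweighted patients and density-cluster them.

    Returns ``(assignment, umap_model)``; the fitted embedding model is kept
    so an independent cohort can later be projected through it.
    """
    n = len(weighted)
    if n <= hdbscan_params.effective_min_cluster_size:
        raise ValueError(
            f"n={n} <= min_pts={hdbscan_params.effective_min_cluster_size}; "
            f"use auto_scale or a smaller min_pts (e.g. {scaled_min_pts(n)})")
    model, emb = _fit_umap(weighted.to_numpy(), umap_params)
    _, labels = _run_hdbscan(emb, hdbscan_params)
    assignment = PatternAssignment(
        pd.Series(labels, index=weighted.index, name="pattern"),
        pd.DataFrame(emb, index=weighted.index,
                     columns=[f"umap{i+1}" for i in range(umap_params.n_components)]))
    return assignment, model


def merge_small_clusters(assignment: PatternAssignment,
                         min_size: int = REFERENCE_MIN_SIZE) -> PatternAssignment:
    """Iteratively merge each undersized cluster into its neighbouring
    cluster (nearest centroid in the stage-2 embedding); noise untouched.

    Terminates in at most (initial cluster count) iterations; surviving
    clusters only ever grow.
    """
    labels = assignment.labels.to_numpy().copy()
    emb = assignment.embedding.to_numpy()
    while True:
        ids, counts = np.unique(labels[labels >= 0], return_counts=True)
        if len(ids) == 0:
            break
        if len(ids) == 1:
            if counts[0] < min_size:
                logger.warning("single cluster of size %d below min_size %d; kept",
                               counts[0], min_size)
            break
        if counts.min() >= min_size:
            break
        small = ids[int(np.argmin(counts))]
        centroids = {k: emb[labels == k].mean(axis=0) for k in ids}
        others = [k for k in ids if k != small]
        target = min(others, key=lambda k: float(np.linalg.norm(centroids[k] - centroids[small])))
        logger.info("merging cluster %d (n=%d) into %d", small, counts.min(), target)
        labels[labels == small] = target
    ids = np.unique(labels[labels >= 0])
    remap = {k: i for i, k in enumerate(ids)}
    labels = np.array([remap.get(v, NOISE) for v in labels])
    return PatternAssignment(
        pd.Series(labels, index=assignment.labels.index, name="pattern"),
        assignment.embedding)


# ---------------------------------------------------------------------------
# Profiles and naming
# ---------------------------------------------------------------------------

from .cohort import NORMAL_PATTERN  # single canonical name  # noqa: E402


@dataclass
class PatternProfile:
    pattern: int
    name: str
    size: int
    item_means: pd.Series  # 16 raw (unweighted) mean scores


def build_profiles(assignment: PatternAssignment, items: pd.DataFrame,
                   naming_margin: float = 0.5) -> list:
    """Per-pattern mean of each raw item + automatic naming.

    A pattern is named by the items whose mean exceeds the cohort-wide item
    mean by at least ``naming_margin``; the pattern with no such item and
    the lowest total mean is the normal-functioning group.
    """
    if assignment.n_patterns < 1:
        raise ValueError("no non-noise clusters to profile")
    cohort_means = items.mean(axis=0)
    profiles = []
    for k in sorted(assignment.sizes.index):
        member_items = items.loc[assignment.labels == k]
        means = member_items.mean(axis=0)
        elevated = means.index[(means - cohort_means) >= naming_margin].tolist()
        name = " + ".join(elevated) if elevated else ""
        profiles.append(PatternProfile(int(k), name, len(member_items), means))
    unnamed = [p for p in profiles if not p.name]
    if unnamed:
        lowest = min(unnamed, key=lambda p: p.item_means.sum())
        lowest.name = NORMAL_PATTERN
        for p in unnamed:
            if p is not lowest:
                p.name = f"unlabelled pattern {p.pattern}"
    return profiles


def profiles_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"pattern": p.pattern, "name": p.name, "size": p.size}
        row.update(p.item_means.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("pattern")


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    item_embedding: pd.DataFrame
    symptom_clusters: SymptomClusterMap
    item_weights: ItemWeights
    pre_merge: PatternAssignment
    assignment: PatternAssignment
    profiles: list
    umap_model: object
    config: DiscoveryConfig

    @property
    def n_patterns(self) -> int:
        return self.assignment.n_patterns

    @property
    def noise_fraction(self) -> float:
        return self.assignment.noise_fraction

    def pattern_names(self) -> dict:
        return {p.pattern: p.name for p in self.profiles}


def run_discovery(items: pd.DataFrame,
                  config: DiscoveryConfig | None = None) -> DiscoveryResult:
    """Execute the full pipeline: embed items -> cluster items -> weights ->
    reweight -> embed+cluster patients -> merge undersized -> profiles."""
    config = (config or DiscoveryConfig()).for_n(len(items))
    items = validate_items(items)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"discovery stage {name!r} failed: {exc}") from exc

    logger.info("stage 1: embedding %d items over %d patients", items.shape[1], len(items))
    item_emb = _stage("embed_items", embed_items, items, config.stage1_umap)
    cluster_map = _stage("cluster_items", cluster_items, item_emb, config.stage1_hdbscan)
    logger.info("stage 1: %d symptom clusters, sizes %s",
                cluster_map.n_clusters, cluster_map.sizes.tolist())
    weights = _stage("compute_item_weights", compute_item_weights, cluster_map)
    weighted = _stage("reweight", reweight, items, weights)
    pre, model = _stage("cluster_patients", cluster_patients, weighted,
                        config.stage2_umap, config.stage2_hdbscan)
    logger.info("stage 2: %d raw clusters, noise %.2f%%",
                pre.n_patterns, 100 * pre.noise_fraction)
    merged = _stage("merge_small_clusters", merge_small_clusters, pre,
                    config.min_pattern_size)
    profiles = _stage("build_profiles", build_profiles, items=items,
                      assignment=merged, naming_margin=config.naming_margin)
    logger.info("final: %d patterns, noise %.2f%%", merged.n_patterns,
                100 * merged.noise_fraction)
    return DiscoveryResult(item_emb, cluster_map, weights, pre, merged,
                           profiles, model, config)
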