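"""Applying a fitted discovery pipeline to an independent cohort.

The fitted artefacts (symptom clusters, item weights, the stage-2 embedding
model, training labels) are frozen; new patients are projected through the
fitted embedding and inherit the pattern label of their nearest embedded
training patient (nearest-neighbour membership prediction — the clusterer
itself has no transform).  Noise labels propagate, so an atypical new
patient can remain unassigned.  A consistency report then pairs discovered
patterns across cohorts by maximising total profile similarity (assignment
problem on Pearson correlation of the 16 item means).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.neighbors import NearestNeighbors

from .scales import ITEM_COLUMNS, validate_items
from .discovery import (
    NOISE, DiscoveryResult, DiscoveryConfig, PatternAssignment,
    build_profiles, profiles_frame, reweight, run_discovery,
)


@dataclass
class FittedPipeline:
    symptom_clusters: "pd.Series"
    item_weights: "pd.Series"
    umap_model: object
    training_embedding: pd.DataFrame
    training_labels: pd.Series
    profiles: pd.DataFrame
    config: DiscoveryConfig

    @classmethod
    def from_result(cls, result: DiscoveryResult) -> "FittedPipeline":
        return cls(
            symptom_clusters=result.symptom_clusters.assignments.copy(),
            item_weights=result.item_weights.weights.copy(),
            umap_model=result.umap_model,
            training_embedding=result.assignment.embedding.copy(),
            training_labels=result.assignment.labels.copy(),
            profiles=profiles_frame(result.profiles),
            config=result.config,
        )

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "FittedPipeline":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a FittedPipeline")
        return obj


def transform_assign(fitted: FittedPipeline, items: pd.DataFrame) -> PatternAssignment:
    """Project new patients through the fitted pipeline and assign patterns.

    Stage-1 artefacts (weights) are reused unchanged; the new patients are
    embedded with the fitted UMAP transform and labelled by their nearest
    embedded training patient (noise permitted).
    """
    if len(items) == 0:
        raise ValueError("empty item table")
    items = validate_items(items)
    missing = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise ValueError(f"item schema mismatch; missing {missing}")
    from .discovery import ItemWeights
    weighted = reweight(items, ItemWeights(fitted.item_weights))
    np.random.seed(getattr(fitted.config.stage2_umap, "seed", 42))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value")
        emb = np.asarray(fitted.umap_model.transform(
            weighted.to_numpy(dtype=np.float32)), dtype=np.float64)
    nn = NearestNeighbors(n_neighbors=1).fit(fitted.training_embedding.to_numpy())
    _, idx = nn.kneighbors(emb)
    labels = fitted.training_labels.to_numpy()[idx[:, 0]]
    return PatternAssignment(
        pd.Series(labels, index=items.index, name="pattern"),
        pd.DataFrame(emb, index=items.index,
                     columns=list(fitted.training_embedding.columns)))


def refit_assign(items: pd.DataFrame, config: DiscoveryConfig | None = None) -> DiscoveryResult:
    """Alternative transfer mode: re-run discovery from scratch on the new
    cohort (tests whether the same structure re-emerges independently)."""
    return run_discovery(items, config)


# ---------------------------------------------------------------------------
# Consistency of pattern characteristics across cohorts
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    pairs: pd.DataFrame        # exploration/validation pattern pairing + similarities
    mean_pearson: float
    unmatched_a: list
    unmatched_b: list

    def __post_init__(self):
        r = self.pairs["pearson_r"]
        if ((r < -1 - 1e-9) | (r > 1 + 1e-9)).any():
            raise ValueError("correlation outside [-1, 1]")


def _profile_matrix(profiles: pd.DataFrame) -> np.ndarray:
    return profiles[list(ITEM_COLUMNS)].to_numpy(dtype=float)


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    bn = b / np.linalg.norm(b, axis=1, keepdims=True)
    return an @ bn.T


def profile_consistency(profiles_a: pd.DataFrame,
                        profiles_b: pd.DataFrame) -> ConsistencyReport:
    """One-to-one pairing of patterns across two cohorts maximising total
    Pearson correlation of the 16-item mean profiles (assignment problem);
    cosine similarity and per-cohort size fractions reported alongside."""
    if len(profiles_a) == 0 or len(profiles_b) == 0:
        raise ValueError("profile sets must be non-empty")
    A, B = _profile_matrix(profiles_a), _profile_matrix(profiles_b)
    R = _pearson_matrix(A, B)
    C = _cosine_matrix(A, B)
    rows_i, cols_j = linear_sum_assignment(-R)
    size_a = profiles_a["size"].to_numpy(dtype=float)
    size_b = profiles_b["size"].to_numpy(dtype=float)
    rows = []
    for i, j in zip(rows_i, cols_j):
        rows.append({
            "pattern_a": profiles_a.index[i], "name_a": profiles_a["name"].iloc[i],
            "pattern_b": profiles_b.index[j], "name_b": profiles_b["name"].iloc[j],
            "pearson_r": float(R[i, j]), "cosine": float(C[i, j]),
            "frac_a": float(size_a[i] / size_a.sum()),
            "frac_b": float(size_b[j] / size_b.sum()),
        })
    pairs = pd.DataFrame(rows)
    unmatched_a = [profiles_a.index[i] for i in range(len(profiles_a)) if i not in set(rows_i)]
    unmatched_b = [profiles_b.index[j] for j in range(len(profiles_b)) if j not in set(cols_j)]
    return ConsistencyReport(pairs, float(pairs["pearson_r"].mean()),
                             unmatched_a, unmatched_b)


def validation_profiles(assignment: PatternAssignment, items: pd.DataFrame,
                        naming_margin: float = 0.5) -> pd.DataFrame:
    """Raw-item mean profiles of a transferred assignment."""
    return profiles_frame(build_profiles(assignment, validate_items(items),
                                         naming_margin))
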