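"""Cluster-validity metrics, traditional baselines and grid search.

Silhouette and Dunn's index are computed with noise-labelled points removed
first, so density-based results remain comparable with K-means/hierarchical
baselines that have no noise concept.  For the main pipeline the metrics
are evaluated on the UMAP embedding (the space the clusterer actually saw);
baselines are evaluated on the representation they clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform, cdist
from sklearn.cluster import KMeans, AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .discovery import (
    NOISE, DiscoveryConfig, UMAPParams, HDBSCANParams, run_discovery,
)


def _strip_noise(points, labels):
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    keep = labels != NOISE
    return points[keep], labels[keep]


def silhouette(points, labels) -> float:
    """Mean silhouette (b - a) / max(a, b); noise excluded, singletons 0."""
    pts, lab = _strip_noise(points, labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette requires >= 2 non-noise clusters")
    return float(silhouette_score(pts, lab))


def dunn_index(points, labels) -> float:
    """Minimum inter-cluster distance over maximum intra-cluster diameter."""
    pts, lab = _strip_noise(points, labels)
    ids = np.unique(lab)
    if len(ids) < 2:
        raise ValueError("Dunn's index requires >= 2 non-noise clusters")
    groups = [pts[lab == k] for k in ids]
    diameters = [pdist(g).max() if len(g) > 1 else 0.0 for g in groups]
    max_diam = max(diameters)
    if max_diam == 0:
        raise ValueError("all cluster diameters are zero; Dunn's index undefined")
    min_inter = min(
        cdist(a, b).min() for a, b in itertools.combinations(groups, 2))
    return float(min_inter / max_diam)


@dataclass
class QualityReport:
    method: str
    params: dict
    k: int
    silhouette: float
    dunn: float
    noise_frac: float
    space: str

    def as_row(self) -> dict:
        row = {"method": self.method, "k": self.k, "silhouette": self.silhouette,
               "dunn": self.dunn, "noise_frac": self.noise_frac, "space": self.space}
        row.update({f"param_{k}": v for k, v in self.params.items()})
        return row


def evaluate_assignment(points, labels, method="umap_hdbscan", params=None,
                        space="embedding") -> QualityReport:
    labels = np.asarray(labels)
    k = len(np.unique(labels[labels != NOISE]))
    return QualityReport(
        method=method, params=params or {}, k=k,
        silhouette=silhouette(points, labels),
        dunn=dunn_index(points, labels),
        noise_frac=float((labels == NOISE).mean()),
        space=space)


def baseline_compare(matrix: pd.DataFrame, k_range, seed: int = 0,
                     pipeline_report: QualityReport | None = None) -> pd.DataFrame:
    """Fit K-means and agglomerative clustering over ``k_range`` on the given
    representation and tabulate both validity metrics per fit.

    Degenerate k (k < 2 or k >= n) are skipped with a warning.  If a report
    for the main pipeline is supplied it is included as the first row.
    """
    X = np.asarray(matrix, dtype=float)
    rows = []
    if pipeline_report is not None:
        rows.append(pipeline_report.as_row())
    for k in k_range:
        if k < 2 or k >= len(X):
            warnings.warn(f"skipping degenerate k={k}")
            continue
        for method, fit in (
            ("kmeans", KMeans(n_clusters=k, n_init=10, random_state=seed)),
            ("hierarchical", AgglomerativeClustering(n_clusters=k)),
        ):
            labels = fit.fit_predict(X)
            try:
                rows.append(evaluate_assignment(
                    X, labels, method=method, params={"k": k},
                    space="feature").as_row())
            except ValueError as exc:
                warnings.warn(f"{method} k={k}: {exc}")
    return pd.DataFrame(rows)


@dataclass
class ParamGrid:
    """Candidate lists for the patient-stage hyperparameters."""

    n_neighbors: list = field(default_factory=lambda: [30])
    min_dist: list = field(default_factory=lambda: [0.01])
    min_pts: list = field(default_factory=lambda: [95])

    def points(self):
        out = [
            {"n_neighbors": nn, "min_dist": md, "min_pts": mp}
            for nn in self.n_neighbors
            for md in self.min_dist
            for mp in self.min_pts
        ]
        if not out:
            raise ValueError("empty parameter grid")
        return out


def grid_search(items: pd.DataFrame, grid: ParamGrid,
                objective: str = "silhouette",
                base_config: DiscoveryConfig | None = None):
    """Run the full pipeline at every grid point and pick the best objective.

    ``objective`` is "silhouette", "dunn" or "combo" (mean of both after
    rank-normalisation).  Ties break toward smaller min_pts, then smaller
    n_neighbors.  Returns ``(best_params, trace)`` where the trace has one
    row per grid point (failures recorded with NaN metrics).
    """
    if objective not in ("silhouette", "dunn", "combo"):
        raise ValueError(f"unknown objective {objective!r}")
    base = base_config or DiscoveryConfig()
    records = []
    for point in grid.points():
        cfg = DiscoveryConfig(
            stage1_umap=base.stage1_umap,
            stage1_hdbscan=base.stage1_hdbscan,
            stage2_umap=UMAPParams(
                n_neighbors=point["n_neighbors"], min_dist=point["min_dist"],
                n_components=base.stage2_umap.n_components,
                n_epochs=base.stage2_umap.n_epochs,
                seed=base.stage2_umap.seed),
            stage2_hdbscan=HDBSCANParams(min_pts=point["min_pts"]),
            min_pattern_size=base.min_pattern_size,
            auto_scale=False,
        )
        rec = dict(point)
        try:
            result = run_discovery(items, cfg)
            rep = evaluate_assignment(result.assignment.embedding,
                                      result.assignment.labels)
            rec.update(silhouette=rep.silhouette, dunn=rep.dunn, k=rep.k,
                       noise_frac=rep.noise_frac, error="")
        except Exception as exc:  # recorded, not fatal: other points continue
            rec.update(silhouette=np.nan, dunn=np.nan, k=0, noise_frac=np.nan,
                       error=str(exc))
        records.append(rec)
    trace = pd.DataFrame(records)
    if trace["silhouette"].isna().all():
        diag = "; ".join(f"{r['n_neighbors']}/{r['min_pts']}: {r['error']}"
                         for r in records)
        raise RuntimeError(f"all grid points failed: {diag}")
    if objective == "combo":
        score = (trace["silhouette"].rank() + trace["dunn"].rank()) / 2
    else:
        score = trace[objective]
    # ties toward smaller min_pts then n_neighbors
    order = trace.assign(_score=score).sort_values(
        ["_score", "min_pts", "n_neighbors"],
        ascending=[False, True, True], kind="mergesort")
    best = order.iloc[0][["n_neighbors", "min_dist", "min_pts"]].to_dict()
    best = {"n_neighbors": int(best["n_neighbors"]),
            "min_dist": float(best["min_dist"]),
            "min_pts": int(best["min_pts"])}
    return best, trace
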