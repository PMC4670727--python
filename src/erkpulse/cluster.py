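"""K-means clustering of pooled single-cell ERK trajectories.

Trajectories are clustered as raw vectors on a common time grid with
squared Euclidean distance and no further standardization — amplitude
differences between cells are informative (sustained responders have
larger first peaks) and must not be scaled away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .metrics import peak_amplitude
from .simulate import Trajectory

__all__ = ["ClusteringResult", "kmeans_trajectories", "cluster_incidence",
           "cluster_peak_amplitudes", "trajectories_to_matrix"]


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray          # cluster index per cell
    centroids: np.ndarray            # (k, n_time) representative trajectories
    within_cluster_ss: float
    time_grid: np.ndarray
    cell_ids: list


def trajectories_to_matrix(trajectories: list[Trajectory]) -> tuple[np.ndarray, np.ndarray, list]:
    """Stack trajectories on their shared time grid; truncate to common support."""
    if not trajectories:
        raise ValueError("no trajectories to cluster")
    n = min(len(tr.t) for tr in trajectories)
    t0 = trajectories[0].t[:n]
    for tr in trajectories:
        if not np.allclose(tr.t[:n], t0, rtol=1e-9, atol=1e-9):
            raise ValueError("trajectories are not on a common time grid")
    X = np.vstack([tr.erk[:n] for tr in trajectories])
    ids = [tr.meta.get("cell_id", f"cell_{i:04d}") for i, tr in enumerate(trajectories)]
    return X, t0, ids


def kmeans_trajectories(trajectories: list[Trajectory], k: int = 5,
                        n_restarts: int = 50, seed: int = 0) -> ClusteringResult:
    """Best-of-restarts k-means (k-means++ seeding, squared Euclidean).

    Deterministic for a given seed; the returned solution minimizes the
    within-cluster sum of squares over ``n_restarts`` initializations.
    """
    X, t, ids = trajectories_to_matrix(trajectories)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of trajectories ({len(X)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                init="k-means++", algorithm="lloyd")
    labels = km.fit_predict(X)
    return ClusteringResult(k=k, assignments=labels, centroids=km.cluster_centers_,
                            within_cluster_ss=float(km.inertia_),
                            time_grid=t, cell_ids=ids)


def cluster_incidence(result: ClusteringResult, condition_labels: list) -> pd.DataFrame:
    """Per-condition fraction of cells in each cluster (rows sum to 1)."""
    if len(condition_labels) != len(result.assignments):
        raise ValueError("one condition label required per cell")
    df = pd.DataFrame({"condition": condition_labels, "cluster": result.assignments})
    counts = df.groupby(["condition", "cluster"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=range(result.k), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def cluster_peak_amplitudes(result: ClusteringResult, trajectories: list[Trajectory],
                            stim_start: float) -> pd.DataFrame:
    """First-peak amplitude distribution per cluster (with quartiles)."""
    amps = np.array([peak_amplitude(tr, stim_start) for tr in trajectories])
    rows = []
    for c in range(result.k):
        a = amps[result.assignments == c]
        if len(a) == 0:
            rows.append({"cluster": c, "n": 0, "q25": np.nan, "median": np.nan,
                         "q75": np.nan, "mean": np.nan})
        else:
            rows.append({"cluster": c, "n": len(a),
                         "q25": float(np.percentile(a, 25)),
                         "median": float(np.median(a)),
                         "q75": float(np.percentile(a, 75)),
                         "mean": float(np.mean(a))})
    return pd.DataFrame(rows).set_index("cluster")
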