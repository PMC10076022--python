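"""Metabolic subtype discovery on the scaled enrichment matrix.

Samples are points in pathway-score space; the base partitioner is k-means
with Euclidean distance. Robustness of a candidate k is judged by consensus
clustering (repeated k-means on random subsamples aggregated into a
sample x sample co-assignment matrix) and its PAC (proportion of ambiguous
clustering: off-diagonal consensus entries that are neither ~0 nor ~1),
and the cluster number is chosen by a majority vote of three indices:
minimal PAC, maximal mean silhouette and maximal Calinski-Harabasz.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .enrich import EnrichmentMatrix

__all__ = [
    "ClusterModel",
    "ConsensusResult",
    "kmeans_cluster",
    "consensus_cluster",
    "select_k",
    "silhouette_widths",
]


@dataclass
class ClusterModel:
    k: int
    assignments: dict[str, int]          # sample -> cluster in 1..k
    centers: np.ndarray                  # k x P
    inertia: float

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[s] for s in samples])

    def to_dict(self) -> dict[str, Any]:
        return {
            "k": self.k,
            "assignments": dict(self.assignments),
            "centers": self.centers.tolist(),
            "inertia": self.inertia,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ClusterModel":
        return cls(
            k=d["k"], assignments={k: int(v) for k, v in d["assignments"].items()},
            centers=np.asarray(d["centers"], dtype=float), inertia=d["inertia"],
        )


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus: dict[int, np.ndarray]     # k -> sample x sample, NaN = never co-sampled
    pac: dict[int, float]
    mean_silhouette: dict[int, float]
    models: dict[int, ClusterModel]
    chosen_k: int
    index_votes: dict[str, int] = field(default_factory=dict)
    vote_split: bool = False
    sample_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "k_values": list(self.k_values),
            "pac": {str(k): v for k, v in self.pac.items()},
            "mean_silhouette": {str(k): v for k, v in self.mean_silhouette.items()},
            "chosen_k": self.chosen_k,
            "index_votes": dict(self.index_votes),
            "vote_split": self.vote_split,
            "assignments": dict(self.models[self.chosen_k].assignments),
        }


def _sample_points(E: EnrichmentMatrix) -> np.ndarray:
    if not E.scaled:
        warnings.warn(
            "enrichment matrix is not scaled; clustering distances will be "
            "dominated by high-variance pathways",
            UserWarning, stacklevel=3,
        )
    return E.scores.T.copy()                      # samples x pathways


def kmeans_cluster(
    E: EnrichmentMatrix, k: int, seed: int = 0, n_init: int = 25
) -> ClusterModel:
    """Best-of-``n_init`` Euclidean k-means on samples; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > E.n_samples:
        raise ValueError("k cannot exceed the number of samples")
    X = _sample_points(E)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    assignments = {s: int(l) + 1 for s, l in zip(E.sample_ids, km.labels_)}
    return ClusterModel(k=k, assignments=assignments,
                        centers=km.cluster_centers_, inertia=float(km.inertia_))


def _pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.mean((vals > lower) & (vals < upper)))


def consensus_cluster(
    E: EnrichmentMatrix,
    k_range: Sequence[int],
    iters: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled k-means consensus matrices and PAC for each candidate k.

    Each iteration draws ceil(subsample * n) samples without replacement,
    partitions them with single-init k-means, and tallies co-assignments;
    the consensus entry of a sample pair is its co-assignment count divided
    by its co-selection count (NaN if never co-selected). ``chosen_k`` here
    is the PAC minimizer; :func:`select_k` adds the other votes.
    """
    if iters < 50:
        raise ValueError("iters must be >= 50")
    if not 0.0 < subsample < 1.0:
        raise ValueError("subsample must be in (0, 1)")
    X = _sample_points(E)
    n = X.shape[0]
    size = math.ceil(subsample * n)
    if size < 2:
        raise ValueError("subsample too small: fewer than 2 samples per draw")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > size for k in ks):
        raise ValueError("every k must satisfy 2 <= k <= subsample size")

    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    sil: dict[int, float] = {}
    models: dict[int, ClusterModel] = {}
    for k in ks:
        together = np.zeros((n, n))
        co_selected = np.zeros((n, n))
        for _ in range(iters):
            idx = rng.choice(n, size=size, replace=False)
            labels = KMeans(
                n_clusters=k, n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit_predict(X[idx])
            co_selected[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                members = idx[labels == c]
                together[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_selected > 0, together / co_selected, np.nan)
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        pac[k] = _pac(M)
        model = kmeans_cluster(E, k, seed=seed)
        models[k] = model
        _, sil[k] = silhouette_widths(E, model.assignments)
    chosen = min(ks, key=lambda k: (pac[k], k))
    return ConsensusResult(
        k_values=ks, consensus=consensus, pac=pac, mean_silhouette=sil,
        models=models, chosen_k=chosen, sample_ids=list(E.sample_ids),
    )


def select_k(
    E: EnrichmentMatrix,
    k_range: Sequence[int],
    seed: int = 0,
    iters: int = 1000,
    subsample: float = 0.8,
) -> ConsensusResult:
    """Majority vote over minimal PAC, maximal mean silhouette and maximal
    Calinski-Harabasz; ties and three-way splits resolve to the smallest
    voted k (with a flag)."""
    res = consensus_cluster(E, k_range, iters=iters, subsample=subsample, seed=seed)
    X = _sample_points(E)
    ch = {
        k: calinski_harabasz_score(X, res.models[k].labels_for(E.sample_ids))
        for k in res.k_values
    }
    votes = {
        "pac": min(res.k_values, key=lambda k: (res.pac[k], k)),
        "silhouette": max(res.k_values, key=lambda k: (res.mean_silhouette[k], -k)),
        "calinski_harabasz": max(res.k_values, key=lambda k: (ch[k], -k)),
    }
    counts = Counter(votes.values())
    top, top_count = counts.most_common(1)[0]
    if top_count == 1:
        res.chosen_k = min(votes.values())
        res.vote_split = True
        warnings.warn(
            f"cluster-number votes split {votes}; choosing smallest voted k",
            UserWarning, stacklevel=2,
        )
    else:
        # majority; among equally supported ks prefer the smallest
        best = sorted(k for k, c in counts.items() if c == top_count)
        res.chosen_k = best[0]
        res.vote_split = False
    res.index_votes = votes
    return res


def silhouette_widths(
    E: EnrichmentMatrix, assignments: Mapping[str, int]
) -> tuple[pd.Series, float]:
    """Per-sample silhouette widths (Euclidean) and their mean.

    Singleton clusters receive width 0 by convention; a single overall
    cluster is an error.
    """
    labels = np.array([assignments[s] for s in E.sample_ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    X = _sample_points(E)
    widths = silhouette_samples(X, labels)
    singleton = np.isin(labels, uniq[counts == 1])
    widths = np.where(singleton | ~np.isfinite(widths), 0.0, widths)
    series = pd.Series(widths, index=E.sample_ids, name="silhouette")
    return series, float(series.mean())
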