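"""Soft clustering of per-gene stage-mean profiles into expression trends.

Each gene is reduced to its standardized stage-mean profile (mean per
ordered stage, then z-scored across stages), and profiles are grouped by
fuzzy c-means: minimize sum_g sum_k u_gk^m ||x_g - v_k||^2 subject to
membership rows summing to 1, by the classic alternating updates. The
number of trends is chosen from the minimum inter-centroid distance curve
(Dmin): adding a centroid beyond the true number of trends forces two
centroids into one trend and collapses Dmin to a persistently lower level,
which is where the elbow sits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import kmeans_plusplus

from .io import ExpressionMatrix, StageDesign

__all__ = [
    "TrendModel",
    "DminSelection",
    "stage_profiles",
    "fuzzy_cmeans",
    "select_c",
]

_ZERO_DIST = 1e-12


def _memberships(d2: np.ndarray, expo: float) -> np.ndarray:
    """FCM membership update; distances are scaled by the row minimum before
    exponentiation so small fuzzifiers (large exponents) cannot overflow."""
    ratio = d2 / d2.min(axis=1, keepdims=True)
    inv = ratio ** (-expo)
    return inv / inv.sum(axis=1, keepdims=True)


@dataclass
class TrendModel:
    centers: np.ndarray            # c x S
    memberships: np.ndarray        # genes x c, rows sum to 1
    fuzzifier: float
    c: int
    gene_ids: list[str]
    objective_history: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def hard_assignments(self) -> pd.Series:
        return pd.Series(
            np.argmax(self.memberships, axis=1), index=self.gene_ids, name="trend"
        )

    @property
    def objective(self) -> float:
        return self.objective_history[-1]

    def to_dict(self) -> dict[str, Any]:
        return {
            "c": self.c,
            "fuzzifier": self.fuzzifier,
            "centers": self.centers.tolist(),
            "memberships": self.memberships.tolist(),
            "gene_ids": list(self.gene_ids),
            "objective": self.objective,
            "converged": self.converged,
        }


@dataclass
class DminSelection:
    chosen_c: int
    dmin_by_c: dict[int, float]
    relative_drops: dict[int, float]
    low_confidence: bool

    def __int__(self) -> int:
        return self.chosen_c

    def to_dict(self) -> dict[str, Any]:
        return {
            "chosen_c": self.chosen_c,
            "dmin_by_c": dict(self.dmin_by_c),
            "relative_drops": dict(self.relative_drops),
            "low_confidence": self.low_confidence,
        }


def stage_profiles(expr: ExpressionMatrix, design: StageDesign) -> pd.DataFrame:
    """Genes x stages matrix of standardized stage means.

    Per gene: mean per ordered stage, then centered and scaled to unit SD
    (ddof=1) across stages. Genes constant across stages carry no trend and
    are dropped with a warning.
    """
    cols = {}
    for stage in design.stage_order:
        samples = design.samples_for(stage)
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = expr.data[samples].mean(axis=1)
    prof = pd.DataFrame(cols)[list(design.stage_order)]
    sd = prof.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} genes constant across stages",
            UserWarning, stacklevel=2,
        )
        prof, sd = prof.loc[~flat], sd[~flat]
    return prof.sub(prof.mean(axis=1), axis=0).div(sd, axis=0)


def fuzzy_cmeans(
    profiles: pd.DataFrame | np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> TrendModel:
    """Fuzzy c-means on profile rows; deterministic given ``seed``.

    Centers are initialized by k-means++ sampling of the profiles. Each
    iteration alternates the membership and center updates of the FCM
    objective and verifies that the objective is non-increasing; iteration
    stops when the largest center movement falls below ``tol``.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c < 2:
        raise ValueError("c must be >= 2")
    if isinstance(profiles, pd.DataFrame):
        gene_ids = [str(i) for i in profiles.index]
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        gene_ids = [str(i) for i in range(X.shape[0])]
    if c > X.shape[0]:
        raise ValueError("c cannot exceed the number of profiles")

    centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    expo = 1.0 / (m - 1.0)
    prev_obj = np.inf
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        d2 = np.maximum(cdist(X, centers, metric="sqeuclidean"), _ZERO_DIST)
        u = _memberships(d2, expo)
        um = u**m
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        obj = float((um * np.maximum(
            cdist(X, new_centers, metric="sqeuclidean"), _ZERO_DIST
        )).sum())
        if obj > prev_obj * (1 + 1e-9) + 1e-12:
            raise RuntimeError("FCM objective increased; numerical failure")
        history.append(obj)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        prev_obj = obj
        if shift < tol:
            converged = True
            break
    d2 = np.maximum(cdist(X, centers, metric="sqeuclidean"), _ZERO_DIST)
    u = _memberships(d2, expo)
    return TrendModel(
        centers=centers, memberships=u, fuzzifier=m, c=c, gene_ids=gene_ids,
        objective_history=history, converged=converged,
    )


def select_c(
    profiles: pd.DataFrame | np.ndarray,
    c_range: Sequence[int],
    m: float = 2.0,
    seed: int = 0,
) -> DminSelection:
    """Choose the trend count from the Dmin (minimum inter-centroid distance)
    curve.

    Dmin stays on the scale of inter-trend distances while every centroid can
    occupy its own trend and collapses once two centroids must share one, so
    the curve shows a persistent level change at the true count: the elbow is
    the boundary maximizing the ratio of the pre-elbow Dmin minimum to the
    post-elbow Dmin maximum. On structureless profiles Dmin merely wiggles
    around one level (ratios near 1); if the best ratio does not reach 2 —
    the post-elbow level does not even halve — the structure is considered
    weak and the smallest c is returned with a low-confidence flag.
    """
    cs = sorted(set(int(c) for c in c_range))
    if not cs:
        raise ValueError("empty c_range")
    dmin: dict[int, float] = {}
    for c in cs:
        model = fuzzy_cmeans(profiles, c, m=m, seed=seed)
        dmin[c] = float(pdist(model.centers).min()) if c > 1 else np.inf
    drops: dict[int, float] = {}
    for a, b in zip(cs[:-1], cs[1:]):
        drops[a] = (dmin[a] - dmin[b]) / dmin[a] if dmin[a] > 0 else 0.0
    if len(cs) == 1:
        return DminSelection(cs[0], dmin, drops, low_confidence=False)

    ratios: dict[int, float] = {}
    for i, c in enumerate(cs[:-1]):
        pre = min(dmin[x] for x in cs[: i + 1])
        post = max(dmin[x] for x in cs[i + 1:])
        ratios[c] = pre / post if post > 0 else float("inf")
    best_c = max(ratios, key=lambda c: (ratios[c], -c))
    if ratios[best_c] < 2.0:
        warnings.warn(
            "Dmin curve shows no persistent level change "
            f"(best pre/post ratio {ratios[best_c]:.2f}) - returning smallest c",
            UserWarning, stacklevel=2,
        )
        return DminSelection(cs[0], dmin, drops, low_confidence=True)
    return DminSelection(best_c, dmin, drops, low_confidence=False)
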