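"""Nearest-shrunken-centroids classification of pathway-score profiles.

The classifier follows the published shrunken-centroid formulation: per
feature i and class k the standardized centroid contrast

    d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)),  m_k = sqrt(1/n_k - 1/n)

is soft-thresholded, d'_ik = sign(d_ik) max(|d_ik| - Delta, 0), shrinking
class centroids toward the overall centroid and silencing uninformative
features; Delta is picked by stratified cross-validation (ties toward the
most parsimonious, i.e. largest, Delta). Prediction minimizes the
dispersion-standardized discriminant

    delta_k(x) = sum_i (x_i - x'_ik)^2 / (s_i + s0)^2 - 2 log pi_k.

For projecting an external cohort onto clusters discovered in a reference
cohort, the batch-alignment surrogate standardizes every cohort per gene
(each dataset by its own per-gene mean/SD, with the training cohort's stats
recorded as the reference transformation) before per-sample enrichment
scoring, so additive platform offsets cancel; enrichment scores are then
mapped into the training score space using the training cohort's
per-pathway scaling parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .enrich import EnrichmentMatrix, ssgsea_scores
from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "NSCModel",
    "ProjectionConfig",
    "fit_nsc",
    "predict_nsc",
    "train_projection",
    "project_cohort",
]

_DENOM_FLOOR = 1e-12


@dataclass
class NSCModel:
    feature_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray        # P
    class_centroids: np.ndarray         # P x K
    pooled_sd: np.ndarray               # P (within-class, pooled)
    s0: float
    priors: np.ndarray                  # K, sums to 1
    m_k: np.ndarray                     # K
    threshold: float
    d: np.ndarray                       # P x K standardized contrasts
    cv_errors: dict[float, float] = field(default_factory=dict)

    @property
    def d_shrunk(self) -> np.ndarray:
        return np.sign(self.d) * np.maximum(np.abs(self.d) - self.threshold, 0.0)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        denom = self.pooled_sd + self.s0
        return self.overall_centroid[:, None] + self.m_k[None, :] * denom[:, None] * self.d_shrunk

    @property
    def active_features(self) -> list[str]:
        live = np.any(self.d_shrunk != 0.0, axis=1)
        return [f for f, on in zip(self.feature_ids, live) if on]

    def to_dict(self) -> dict[str, Any]:
        return {
            "feature_ids": list(self.feature_ids),
            "classes": list(self.classes),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "priors": self.priors.tolist(),
            "m_k": self.m_k.tolist(),
            "threshold": self.threshold,
            "d": self.d.tolist(),
            "cv_errors": {str(k): v for k, v in self.cv_errors.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NSCModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            classes=list(d["classes"]),
            overall_centroid=np.asarray(d["overall_centroid"], dtype=float),
            class_centroids=np.asarray(d["class_centroids"], dtype=float),
            pooled_sd=np.asarray(d["pooled_sd"], dtype=float),
            s0=float(d["s0"]),
            priors=np.asarray(d["priors"], dtype=float),
            m_k=np.asarray(d["m_k"], dtype=float),
            threshold=float(d["threshold"]),
            d=np.asarray(d["d"], dtype=float),
            cv_errors={float(k): v for k, v in d.get("cv_errors", {}).items()},
        )


@dataclass
class ProjectionConfig:
    """Alignment mode plus the reference (training-cohort) transformation."""

    alignment: str = "reference_standardize"   # or "none"
    gene_ids: list[str] = field(default_factory=list)
    gene_mean: np.ndarray | None = None
    gene_sd: np.ndarray | None = None
    pathway_ids: list[str] = field(default_factory=list)
    pathway_mean: np.ndarray | None = None
    pathway_sd: np.ndarray | None = None
    ssgsea_alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.alignment not in ("none", "reference_standardize"):
            raise ValueError(f"unknown alignment mode {self.alignment!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "alignment": self.alignment,
            "gene_ids": list(self.gene_ids),
            "gene_mean": None if self.gene_mean is None else self.gene_mean.tolist(),
            "gene_sd": None if self.gene_sd is None else self.gene_sd.tolist(),
            "pathway_ids": list(self.pathway_ids),
            "pathway_mean": None if self.pathway_mean is None else self.pathway_mean.tolist(),
            "pathway_sd": None if self.pathway_sd is None else self.pathway_sd.tolist(),
            "ssgsea_alpha": self.ssgsea_alpha,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ProjectionConfig":
        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            alignment=d["alignment"], gene_ids=list(d["gene_ids"]),
            gene_mean=arr(d["gene_mean"]), gene_sd=arr(d["gene_sd"]),
            pathway_ids=list(d["pathway_ids"]),
            pathway_mean=arr(d["pathway_mean"]), pathway_sd=arr(d["pathway_sd"]),
            ssgsea_alpha=float(d["ssgsea_alpha"]),
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _nsc_stats(
    X: np.ndarray, y: np.ndarray, classes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    """(overall, class centroids, pooled sd, s0, priors, m_k, d)."""
    n = X.shape[1]
    K = len(classes)
    overall = X.mean(axis=1)
    cents = np.empty((X.shape[0], K))
    n_k = np.empty(K)
    ss = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        cols = y == c
        n_k[j] = cols.sum()
        cents[:, j] = X[:, cols].mean(axis=1)
        ss += ((X[:, cols] - cents[:, j][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    priors = n_k / n
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    denom = np.maximum(m_k[None, :] * (s + s0)[:, None], _DENOM_FLOOR)
    d = (cents - overall[:, None]) / denom
    return overall, cents, s, s0, priors, m_k, d


def _discriminants(
    X: np.ndarray,
    overall: np.ndarray,
    s: np.ndarray,
    s0: float,
    priors: np.ndarray,
    m_k: np.ndarray,
    d: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """delta_k(x) for every sample; shape n x K."""
    d_sh = np.sign(d) * np.maximum(np.abs(d) - threshold, 0.0)
    denom = np.maximum(s + s0, _DENOM_FLOOR)
    cents = overall[:, None] + m_k[None, :] * denom[:, None] * d_sh
    Z = X / denom[:, None]
    C = cents / denom[:, None]
    # ||z - c_k||^2 expanded for all samples at once
    dist = (
        (Z**2).sum(axis=0)[:, None]
        - 2.0 * Z.T @ C
        + (C**2).sum(axis=0)[None, :]
    )
    return dist - 2.0 * np.log(priors)[None, :]


def fit_nsc(
    E: EnrichmentMatrix,
    labels: Mapping[str, str],
    thresholds: Sequence[float] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> NSCModel:
    """Fit the shrunken-centroid model; Delta chosen by stratified CV error.

    The default grid is 30 evenly spaced thresholds from 0 to max |d_ik|.
    CV ties resolve toward the largest (most parsimonious) Delta.
    """
    X = E.scores
    y = np.array([str(labels[s]) for s in E.sample_ids])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = {c: n for c, n in counts.items() if n < 2}
    if small:
        raise ValueError(f"classes with < 2 samples: {small}")
    if min(counts.values()) < cv_folds:
        raise ValueError(
            f"every class needs >= cv_folds={cv_folds} samples, got {counts}"
        )

    overall, cents, s, s0, priors, m_k, d = _nsc_stats(X, y, classes)
    if thresholds is None:
        thresholds = list(np.linspace(0.0, float(np.abs(d).max()), 30))
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("empty threshold grid")

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(thresholds))
    for train_idx, val_idx in skf.split(X.T, y):
        st = _nsc_stats(X[:, train_idx], y[train_idx], classes)
        for t, thr in enumerate(thresholds):
            delta = _discriminants(X[:, val_idx], st[0], st[2], st[3],
                                   st[4], st[5], st[6], thr)
            pred = np.asarray(classes)[np.argmin(delta, axis=1)]
            errors[t] += (pred != y[val_idx]).sum()
    errors /= len(y)
    best = max(
        (t for t in range(len(thresholds))),
        key=lambda t: (-errors[t], thresholds[t]),
    )
    return NSCModel(
        feature_ids=list(E.pathway_ids), classes=classes,
        overall_centroid=overall, class_centroids=cents, pooled_sd=s, s0=s0,
        priors=priors, m_k=m_k, threshold=thresholds[best], d=d,
        cv_errors={thr: float(e) for thr, e in zip(thresholds, errors)},
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_nsc(
    model: NSCModel, E_new: EnrichmentMatrix, min_overlap: float = 0.8
) -> pd.DataFrame:
    """Classify samples of a new score matrix.

    Requires at least ``min_overlap`` of model features present; missing
    features are imputed at the overall centroid (with a warning). Returns a
    DataFrame with the predicted class, per-class softmax(-delta/2)
    posterior (a heuristic confidence, not a calibrated probability) and the
    raw discriminant scores.
    """
    pos = {p: i for i, p in enumerate(E_new.pathway_ids)}
    present = [f for f in model.feature_ids if f in pos]
    missing = [f for f in model.feature_ids if f not in pos]
    if len(present) < min_overlap * len(model.feature_ids):
        raise ValueError(
            f"feature overlap {len(present)}/{len(model.feature_ids)} below "
            f"{min_overlap:.0%}; missing: {missing}"
        )
    n = E_new.n_samples
    X = np.empty((len(model.feature_ids), n))
    for i, f in enumerate(model.feature_ids):
        if f in pos:
            X[i] = E_new.scores[pos[f]]
        else:
            X[i] = model.overall_centroid[i]
    if missing:
        warnings.warn(
            f"{len(missing)} model features absent; imputed at overall "
            f"centroid: {missing[:5]}",
            UserWarning, stacklevel=2,
        )
    delta = _discriminants(
        X, model.overall_centroid, model.pooled_sd, model.s0,
        model.priors, model.m_k, model.d, model.threshold,
    )
    # discriminant differences below numerical noise are ties; resolve to the
    # first class in sorted order
    near_min = delta <= delta.min(axis=1, keepdims=True) + 1e-9
    pred = np.asarray(model.classes)[near_min.argmax(axis=1)]
    logits = -0.5 * (delta - delta.min(axis=1, keepdims=True))
    post = np.exp(logits)
    post /= post.sum(axis=1, keepdims=True)
    out = pd.DataFrame({"predicted": pred}, index=E_new.sample_ids)
    for j, c in enumerate(model.classes):
        out[f"posterior_{c}"] = post[:, j]
    for j, c in enumerate(model.classes):
        out[f"delta_{c}"] = delta[:, j]
    return out


# ---------------------------------------------------------------------------
# cross-cohort projection
# ---------------------------------------------------------------------------


def _standardize_by(
    expr: ExpressionMatrix, mean: np.ndarray, sd: np.ndarray
) -> ExpressionMatrix:
    sd = np.where(sd == 0, 1.0, sd)
    df = expr.data.sub(mean, axis=0).div(sd, axis=0)
    return ExpressionMatrix(df)


def train_projection(
    train_expr: ExpressionMatrix,
    sets: GeneSetCollection,
    labels: Mapping[str, str],
    alignment: str = "reference_standardize",
    alpha: float = 0.25,
    thresholds: Sequence[float] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[NSCModel, ProjectionConfig, EnrichmentMatrix]:
    """Fit the full reference pipeline: (align ->) score -> scale -> NSC.

    Returns the model, the projection configuration holding the reference
    transformation (per-gene stats and per-pathway scaling parameters), and
    the scaled training score matrix.
    """
    gene_mean = train_expr.data.mean(axis=1).to_numpy()
    gene_sd = train_expr.data.std(axis=1, ddof=1).to_numpy()
    if alignment == "reference_standardize":
        expr_used = _standardize_by(train_expr, gene_mean, gene_sd)
    else:
        expr_used = train_expr
    raw = ssgsea_scores(expr_used, sets, alpha=alpha)
    pw_mean = raw.scores.mean(axis=1)
    pw_sd = raw.scores.std(axis=1, ddof=1)
    pw_sd_safe = np.where(pw_sd == 0, 1.0, pw_sd)
    scaled = EnrichmentMatrix(
        list(raw.pathway_ids), list(raw.sample_ids),
        (raw.scores - pw_mean[:, None]) / pw_sd_safe[:, None],
        alpha=alpha, scaled=True,
    )
    model = fit_nsc(scaled, labels, thresholds=thresholds,
                    cv_folds=cv_folds, seed=seed)
    cfg = ProjectionConfig(
        alignment=alignment,
        gene_ids=list(train_expr.gene_ids), gene_mean=gene_mean, gene_sd=gene_sd,
        pathway_ids=list(raw.pathway_ids), pathway_mean=pw_mean, pathway_sd=pw_sd_safe,
        ssgsea_alpha=alpha,
    )
    return model, cfg, scaled


def project_cohort(
    expr_new: ExpressionMatrix,
    sets: GeneSetCollection,
    model: NSCModel,
    cfg: ProjectionConfig,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Project an external cohort onto the trained clusters.

    Pipeline: restrict to the reference gene universe; optional per-gene
    standardization of the new cohort (its own per-gene mean/SD — the same
    transformation the reference cohort underwent, so additive platform
    offsets cancel); per-sample enrichment scores at the training alpha;
    mapping into the training score space with the training per-pathway
    scaling parameters; shrunken-centroid prediction. Pathways with more
    than half their genes missing are dropped with a warning (the
    classifier's feature-overlap rule still applies).
    """
    common = [g for g in cfg.gene_ids if g in expr_new.data.index]
    if not common:
        raise ValueError("no overlap with the reference gene universe")
    lost = len(cfg.gene_ids) - len(common)
    if lost:
        warnings.warn(
            f"{lost} reference genes absent from the new cohort",
            UserWarning, stacklevel=2,
        )
    expr = expr_new.subset(genes=common)

    kept_sets, dropped = [], []
    for name in sets.names:
        genes = sets.genes(name)
        present = sum(g in expr.data.index for g in genes)
        if present <= 0.5 * len(genes):
            dropped.append(name)
        else:
            kept_sets.append(name)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} pathways with > 50% genes missing: "
            f"{dropped[:5]}",
            UserWarning, stacklevel=2,
        )
    usable = sets.subset(kept_sets)

    if cfg.alignment == "reference_standardize":
        mean = expr.data.mean(axis=1).to_numpy()
        sd = expr.data.std(axis=1, ddof=1).to_numpy()
        expr = _standardize_by(expr, mean, sd)

    raw = ssgsea_scores(expr, usable, alpha=cfg.ssgsea_alpha)
    pw_pos = {p: i for i, p in enumerate(cfg.pathway_ids)}
    rows, pathways = [], []
    for i, p in enumerate(raw.pathway_ids):
        if p in pw_pos:
            j = pw_pos[p]
            rows.append((raw.scores[i] - cfg.pathway_mean[j]) / cfg.pathway_sd[j])
            pathways.append(p)
    scaled = EnrichmentMatrix(
        pathways, list(raw.sample_ids), np.vstack(rows),
        alpha=cfg.ssgsea_alpha, scaled=True,
    )
    predictions = predict_nsc(model, scaled)
    report = {
        "alignment": cfg.alignment,
        "n_samples": expr_new.n_samples,
        "n_genes_used": len(common),
        "pathways_dropped": dropped,
        "pathways_scored": pathways,
        "class_counts": predictions["predicted"].value_counts().to_dict(),
    }
    return predictions, report
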