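"""Per-sample pathway enrichment, preranked enrichment, differential genes.

Per-sample scores follow the ssGSEA formulation: within each sample genes
are ranked by expression (descending, average ranks for ties) and the score
of a gene set is the integral of the difference between the weighted
cumulative in-set fraction (weights |rank statistic|^alpha) and the
unweighted cumulative out-of-set fraction, accumulated down the ranked
list. This is a fully rank-based stand-in for kernel-density GSVA scores;
downstream clustering consumes the z-scored score matrix, where the two
agree qualitatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection, StageDesign
from .stats import bh_adjust, welch_t

__all__ = [
    "EnrichmentMatrix",
    "PrerankedResult",
    "differential_genes",
    "ssgsea_scores",
    "scale_scores",
    "preranked_es",
    "preranked_gsea",
    "read_enrichment",
    "sets_containing",
]


def sets_containing(
    collection: GeneSetCollection, genes: Sequence[str]
) -> GeneSetCollection:
    """Sets holding at least one of ``genes`` (e.g. the pathways a tipping-point
    module maps to); scores are still computed over each set's full gene list."""
    wanted = set(genes)
    names = [n for n in collection.names if wanted & set(collection.genes(n))]
    if not names:
        raise ValueError("no set contains any of the given genes")
    return collection.subset(names)


@dataclass
class EnrichmentMatrix:
    """Pathway x sample enrichment scores."""

    pathway_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    alpha: float = 0.25
    scaled: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pathway_ids), len(self.sample_ids)):
            raise ValueError("scores shape does not match pathway/sample ids")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("duplicate pathway ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.pathway_ids, name="pathway"),
            columns=self.sample_ids,
        )

    def subset_samples(self, samples: Sequence[str]) -> "EnrichmentMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return EnrichmentMatrix(
            list(self.pathway_ids), list(samples), self.scores[:, idx],
            alpha=self.alpha, scaled=self.scaled,
        )


def read_enrichment(
    path: str, alpha: float = 0.25, scaled: bool = False, delimiter: str = "\t"
) -> EnrichmentMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return EnrichmentMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns],
        df.to_numpy(dtype=float), alpha=alpha, scaled=scaled,
    )


@dataclass
class PrerankedResult:
    pathway: str
    es: float
    p_value: float
    direction: str
    q_value: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return {"pathway": self.pathway, "es": self.es, "p_value": self.p_value,
                "direction": self.direction, "q_value": self.q_value}


# ---------------------------------------------------------------------------
# differential genes (plain Welch + BH pre-filter)
# ---------------------------------------------------------------------------


def differential_genes(
    expr: ExpressionMatrix,
    design: StageDesign,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Genes differential (BH-adjusted p < alpha) in >= 1 pairwise comparison.

    Welch two-sample t-tests per gene for every unordered pair of stages,
    BH adjustment within each pair. Returns the selected gene list and the
    long-format statistics table.
    """
    stages = design.stage_order
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    blocks = {}
    for st in stages:
        samples = design.require_min_samples(st, 2)
        blocks[st] = expr.data[samples].to_numpy(dtype=float)
    genes = np.asarray(expr.gene_ids, dtype=object)
    rows = []
    selected: set[str] = set()
    for i, a in enumerate(stages):
        for b in stages[i + 1:]:
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = welch_t(blocks[a], blocks[b], axis=1)
            p = np.where(np.isnan(p), 1.0, p)
            q = bh_adjust(p)
            hit = q < alpha
            selected |= set(genes[hit])
            rows.append(pd.DataFrame({
                "gene": genes, "pair": f"{a} vs {b}", "t": t, "p_value": p,
                "q_value": q, "selected": hit,
            }))
    table = pd.concat(rows, ignore_index=True)
    return sorted(selected), table


# ---------------------------------------------------------------------------
# ssGSEA-style per-sample scores
# ---------------------------------------------------------------------------


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    min_genes: int = 2,
) -> EnrichmentMatrix:
    """Single-sample running-sum enrichment scores, pathways x samples.

    Per sample, genes are walked in descending expression order (ties walked
    in row order with average-rank weights); the set score is
    sum_i [ cum_in_weight(i)/total_in_weight - cum_out_count(i)/(N - m) ]
    with weights |N + 1 - rank|^alpha. With ``normalize`` the whole matrix is
    divided by (max - min) of the raw scores. Sets with fewer than
    ``min_genes`` present genes are skipped with a warning.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X = expr.values
    n_genes, n_samples = X.shape
    ranks = rankdata(-X, axis=0, method="average")
    stat = n_genes + 1.0 - ranks                       # top gene ~ N
    order = np.argsort(-X, axis=0, kind="stable")
    w_ord = np.take_along_axis(stat, order, axis=0) ** alpha

    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    kept: list[str] = []
    scores: list[np.ndarray] = []
    for name in sets.names:
        present = [gene_pos[g] for g in sets.genes(name) if g in gene_pos]
        m = len(present)
        if m < min_genes:
            warnings.warn(
                f"set {name!r}: {m} genes present (< {min_genes}); skipped",
                UserWarning, stacklevel=2,
            )
            continue
        if m >= n_genes:
            warnings.warn(f"set {name!r} covers the whole universe; skipped",
                          UserWarning, stacklevel=2)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[present] = True
        mask_ord = mask[order]                         # N x S
        w_in = np.where(mask_ord, w_ord, 0.0)
        cum_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
        cum_out = np.cumsum(~mask_ord, axis=0) / float(n_genes - m)
        scores.append((cum_in - cum_out).sum(axis=0))
        kept.append(name)
    if not kept:
        raise ValueError("no gene set had enough genes present")
    S = np.vstack(scores)
    if normalize:
        span = S.max() - S.min()
        if span > 0:
            S = S / span
    return EnrichmentMatrix(kept, expr.sample_ids, S, alpha=alpha, scaled=False)


def scale_scores(E: EnrichmentMatrix, mode: str = "per_pathway") -> EnrichmentMatrix:
    """Z-score the enrichment matrix along pathways (rows) or samples (columns).

    ``per_pathway`` (default) standardizes each pathway across samples so
    clustering distances weight pathways comparably; ``per_sample``
    standardizes each sample's profile. Zero-variance slices are left at 0
    with a warning. Idempotent (SD uses ddof=1).
    """
    if mode not in ("per_pathway", "per_sample"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    axis = 1 if mode == "per_pathway" else 0
    S = E.scores
    if S.shape[axis] < 2:
        raise ValueError("need >= 2 entries along the scaled axis")
    mean = S.mean(axis=axis, keepdims=True)
    sd = S.std(axis=axis, ddof=1, keepdims=True)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance {'rows' if axis == 1 else 'columns'} "
            "left at 0 after centering",
            UserWarning, stacklevel=2,
        )
    sd = np.where(flat, 1.0, sd)
    return EnrichmentMatrix(
        list(E.pathway_ids), list(E.sample_ids), (S - mean) / sd,
        alpha=E.alpha, scaled=True,
    )


# ---------------------------------------------------------------------------
# preranked enrichment (classic weighted KS)
# ---------------------------------------------------------------------------


def _running_es(stats_sorted: np.ndarray, in_set: np.ndarray) -> float:
    """Signed maximal running-sum deviation (weight |stat|^1)."""
    n = stats_sorted.size
    m = int(in_set.sum())
    w = np.abs(stats_sorted) * in_set
    total = w.sum()
    if total == 0:                                   # all-zero stats: flat weights
        w = in_set.astype(float)
        total = float(m)
    steps = w / total - (~in_set) / float(n - m)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])


def preranked_es(
    ranking: Mapping[str, float] | pd.Series,
    set_genes: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    pathway: str = "",
) -> PrerankedResult:
    """Preranked enrichment of one gene set against a ranking statistic.

    Classic weighted Kolmogorov-Smirnov enrichment score (maximal running-sum
    deviation, weight |stat|); the null permutes gene labels (random sets of
    the same size); two-sided p on |ES|.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranking = pd.Series(ranking, dtype=float)
    genes = ranking.index
    members = set(set_genes) & set(genes)
    if not members:
        raise ValueError(f"set {pathway or '<unnamed>'} has no genes in the ranking")
    if len(members) >= len(genes):
        raise ValueError("gene set covers the entire ranking")
    order = np.lexsort((np.asarray(genes, dtype=object), -ranking.to_numpy()))
    stats_sorted = ranking.to_numpy()[order]
    names_sorted = genes.to_numpy()[order]
    in_set = np.isin(names_sorted, list(members))
    es = _running_es(stats_sorted, in_set)

    rng = np.random.default_rng(seed)
    m = int(in_set.sum())
    n = stats_sorted.size
    extreme = 0
    for _ in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=m, replace=False)] = True
        if abs(_running_es(stats_sorted, perm_mask)) >= abs(es) - 1e-12:
            extreme += 1
    p = (1 + extreme) / (1 + n_perm)
    return PrerankedResult(
        pathway=pathway, es=es, p_value=float(p),
        direction="up" if es >= 0 else "down",
    )


def preranked_gsea(
    ranking: Mapping[str, float] | pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked enrichment for every set in the collection, BH across sets."""
    rng = np.random.default_rng(seed)
    rows = []
    for name in collection.names:
        try:
            res = preranked_es(
                ranking, collection.genes(name), n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)), pathway=name,
            )
        except ValueError as exc:
            warnings.warn(f"set {name!r} skipped: {exc}", UserWarning, stacklevel=2)
            continue
        rows.append({"pathway": name, "es": res.es, "p_value": res.p_value,
                     "direction": res.direction})
    table = pd.DataFrame(rows).set_index("pathway")
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table
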