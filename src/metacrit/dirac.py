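"""Differential rank conservation (DIRAC) and global expression divergence.

DIRAC asks how rigidly a pathway's genes keep their relative expression
ordering across the samples of a phenotype. For an m-gene pathway the
majority ordering over all m(m-1)/2 gene pairs forms a rank template; each
sample's matching score is the fraction of template pairs it satisfies, and
the rank conservation index (RCI) of a phenotype is the mean matching score
of its samples against their own template. An RCI of 1.0 means the ordering
is essentially fixed; values near 0.5 mean the ordering is scrambled.
Differential conservation between two phenotypes is tested by permuting the
phenotype labels.

The module also provides the global divergence between two expression
profiles, the root-mean-square deviation on log2 scale

    RMSD(x, y) = sqrt( sum_i (log2 x_i - log2 y_i)^2 / n ),

and its within/between-group summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust

__all__ = [
    "PairOrderTemplate",
    "RCIResult",
    "DivergenceSummary",
    "rank_template",
    "matching_score",
    "rci",
    "differential_rci",
    "dirac_table",
    "rmsd_divergence",
    "divergence_summary",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PairOrderTemplate:
    """Majority gene-pair ordering of one pathway in one phenotype.

    ``ordered_pairs`` holds one (a, b) per unordered gene pair, meaning
    "a ranks above b in the majority of the phenotype's samples"; exact
    majority ties orient toward the lexicographically smaller gene first.
    """

    pathway: str
    phenotype: str
    ordered_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        genes = sorted({g for pair in self.ordered_pairs for g in pair})
        m = len(genes)
        if len(self.ordered_pairs) != m * (m - 1) // 2:
            raise ValueError("template must cover every unordered gene pair once")


@dataclass
class RCIResult:
    pathway: str
    rci_by_group: dict[str, float]
    matching_scores: dict[str, list[float]]
    p_value: float | None = None
    q_value: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "pathway": self.pathway,
            "rci_by_group": dict(self.rci_by_group),
            "matching_scores": {k: list(v) for k, v in self.matching_scores.items()},
            "p_value": self.p_value,
            "q_value": self.q_value,
        }


@dataclass
class DivergenceSummary:
    within_group_mean: dict[str, float]
    between_group_mean: float
    percentages: dict[str, float]
    between_pair: tuple[str, str]
    degenerate: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "within_group_mean": dict(self.within_group_mean),
            "between_group_mean": self.between_group_mean,
            "percentages": dict(self.percentages),
            "between_pair": list(self.between_pair),
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------------
# vectorized core
# ---------------------------------------------------------------------------


def _pathway_block(
    expr: ExpressionMatrix, pathway_genes: Sequence[str], pathway: str
) -> tuple[list[str], pd.DataFrame]:
    present = sorted(g for g in set(pathway_genes) if g in expr.data.index)
    if len(present) < 2:
        raise ValueError(
            f"pathway {pathway or '<unnamed>'}: fewer than 2 genes present"
        )
    return present, expr.data.loc[present]


def _pair_indicators(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Strict-ordering indicators for all gene pairs (genes pre-sorted).

    Returns (i_idx, j_idx, fwd, rev): fwd[p, s] = 1 iff gene i_p > gene j_p
    strictly in sample s; within-sample ties are neither.
    """
    m = X.shape[0]
    i_idx, j_idx = np.triu_indices(m, k=1)
    fwd = X[i_idx] > X[j_idx]
    rev = X[j_idx] > X[i_idx]
    return i_idx, j_idx, fwd, rev


def _majority(fwd: np.ndarray, rev: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per pair: True if forward (lexicographic) orientation is kept.

    Forward wins on a strict majority of strict forward orderings; reverse
    needs its own strict majority; everything else (exact ties, tie-heavy
    pairs) defaults to forward, i.e. lexicographically smaller gene first.
    """
    n = cols.size
    cf = fwd[:, cols].sum(axis=1)
    cr = rev[:, cols].sum(axis=1)
    return ~((cr * 2 > n) & ~(cf * 2 > n))


def rank_template(
    expr: ExpressionMatrix,
    samples: Sequence[str],
    pathway_genes: Sequence[str],
    pathway: str = "",
    phenotype: str = "",
) -> PairOrderTemplate:
    """Majority-ordering template over the given samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("rank_template needs at least one sample")
    present, block = _pathway_block(expr, pathway_genes, pathway)
    X = block[samples].to_numpy(dtype=float)
    i_idx, j_idx, fwd, rev = _pair_indicators(X)
    keep_fwd = _majority(fwd, rev, np.arange(len(samples)))
    pairs = [
        (present[i], present[j]) if kf else (present[j], present[i])
        for i, j, kf in zip(i_idx, j_idx, keep_fwd)
    ]
    return PairOrderTemplate(pathway=pathway, phenotype=phenotype, ordered_pairs=pairs)


def matching_score(
    sample_values: Mapping[str, float] | pd.Series,
    template: PairOrderTemplate,
) -> float:
    """Fraction of template pairs the sample satisfies (ties unsatisfied)."""
    values = pd.Series(sample_values)
    missing = [g for pair in template.ordered_pairs for g in pair
               if g not in values.index]
    if missing:
        raise ValueError(f"sample lacks template genes: {sorted(set(missing))[:5]}")
    hits = sum(values[a] > values[b] for a, b in template.ordered_pairs)
    return hits / len(template.ordered_pairs)


def _group_scores(
    fwd: np.ndarray, rev: np.ndarray, cols: np.ndarray
) -> tuple[float, np.ndarray]:
    """(RCI, per-sample matching scores) of a group against its own template."""
    keep_fwd = _majority(fwd, rev, cols)
    chosen = np.where(keep_fwd[:, None], fwd[:, cols], rev[:, cols])
    scores = chosen.mean(axis=0)
    return float(scores.mean()), scores


def rci(
    expr: ExpressionMatrix,
    groups: Mapping[str, Sequence[str]],
    pathway_genes: Sequence[str],
    pathway: str = "",
) -> RCIResult:
    """Per-phenotype RCI: each group scored against its own majority template."""
    present, block = _pathway_block(expr, pathway_genes, pathway)
    rci_by_group: dict[str, float] = {}
    matching: dict[str, list[float]] = {}
    for group, samples in groups.items():
        samples = list(samples)
        if len(samples) < 2:
            raise ValueError(f"group {group!r} needs >= 2 samples")
        X = block[samples].to_numpy(dtype=float)
        _, _, fwd, rev = _pair_indicators(X)
        value, scores = _group_scores(fwd, rev, np.arange(len(samples)))
        rci_by_group[group] = value
        matching[group] = list(scores)
    return RCIResult(pathway=pathway, rci_by_group=rci_by_group,
                     matching_scores=matching)


def differential_rci(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pathway_genes: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    pathway: str = "",
    alternative: str = "two-sided",
) -> RCIResult:
    """Permutation test for differential rank conservation between two groups.

    The statistic is RCI_a - RCI_b; the null is formed by permuting group
    labels across the pooled samples. ``alternative`` is "two-sided" (|delta|),
    "greater" (a more conserved) or "less" (a less conserved).
    p = (1 + #{extreme permutations}) / (1 + n_perm).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    present, block = _pathway_block(expr, pathway_genes, pathway)
    pooled = group_a + group_b
    X = block[pooled].to_numpy(dtype=float)
    _, _, fwd, rev = _pair_indicators(X)
    n_a = len(group_a)
    n = len(pooled)

    rci_a, scores_a = _group_scores(fwd, rev, np.arange(n_a))
    rci_b, scores_b = _group_scores(fwd, rev, np.arange(n_a, n))
    delta_obs = rci_a - rci_b

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        ra, _ = _group_scores(fwd, rev, perm[:n_a])
        rb, _ = _group_scores(fwd, rev, perm[n_a:])
        deltas[t] = ra - rb
    if alternative == "two-sided":
        extreme = np.abs(deltas) >= abs(delta_obs) - 1e-12
    elif alternative == "greater":
        extreme = deltas >= delta_obs - 1e-12
    else:
        extreme = deltas <= delta_obs + 1e-12
    p = (1 + int(extreme.sum())) / (1 + n_perm)
    return RCIResult(
        pathway=pathway,
        rci_by_group={"a": rci_a, "b": rci_b},
        matching_scores={"a": list(scores_a), "b": list(scores_b)},
        p_value=float(p),
    )


def dirac_table(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Differential RCI for every pathway, BH-adjusted across pathways."""
    rows: list[dict[str, Any]] = []
    rng = np.random.default_rng(seed)
    for name in collection.names:
        genes = collection.genes(name)
        present = [g for g in genes if g in expr.data.index]
        if len(present) < 2:
            warnings.warn(f"pathway {name!r}: fewer than 2 genes present; skipped",
                          UserWarning, stacklevel=2)
            continue
        res = differential_rci(
            expr, group_a, group_b, present, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)), pathway=name,
            alternative=alternative,
        )
        rows.append(
            {
                "pathway": name,
                "rci_a": res.rci_by_group["a"],
                "rci_b": res.rci_by_group["b"],
                "delta": res.rci_by_group["a"] - res.rci_by_group["b"],
                "p_value": res.p_value,
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# global divergence
# ---------------------------------------------------------------------------


def rmsd_divergence(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    log2_transform: bool = True,
) -> float:
    """Root-mean-square log2 divergence between two expression profiles.

    With ``log2_transform`` the inputs are linear-scale (> 0) and logged here;
    pass False for profiles that are already on log2 scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("profiles must be equal-length non-empty vectors")
    if log2_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log2 requested but profiles contain values <= 0")
        x, y = np.log2(x), np.log2(y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def divergence_summary(
    expr: ExpressionMatrix,
    groups: Mapping[str, Sequence[str]],
    between: tuple[str, str] | None = None,
    log2_transform: bool = False,
) -> DivergenceSummary:
    """Mean pairwise RMSD within each group and between two designated groups,
    each expressed as a percentage of the between-group mean.

    ``log2_transform`` defaults to False because package expression matrices
    are already log2 scale. Groups of size < 2 omit their within-mean with a
    warning; an all-identical cohort yields zero means and is flagged
    degenerate (percentages reported as 0).
    """
    if len(groups) < 2:
        raise ValueError("divergence_summary needs >= 2 groups")
    if between is None:
        between = tuple(list(groups)[:2])  # type: ignore[assignment]
    g_a, g_b = between
    for g in between:
        if g not in groups:
            raise KeyError(f"designated group {g!r} not in groups")

    def profile_block(samples: Sequence[str]) -> np.ndarray:
        X = expr.data[list(samples)].to_numpy(dtype=float).T  # samples x genes
        if log2_transform:
            if np.any(X <= 0):
                raise ValueError("log2 requested but matrix contains values <= 0")
            X = np.log2(X)
        return X

    n_genes = expr.n_genes
    within: dict[str, float] = {}
    for group, samples in groups.items():
        if len(samples) < 2:
            warnings.warn(f"group {group!r} has < 2 samples; within-mean omitted",
                          UserWarning, stacklevel=2)
            continue
        X = profile_block(samples)
        within[group] = float(np.mean(pdist(X) / np.sqrt(n_genes)))

    Xa, Xb = profile_block(groups[g_a]), profile_block(groups[g_b])
    diffs = Xa[:, None, :] - Xb[None, :, :]
    between_mean = float(np.mean(np.sqrt(np.sum(diffs**2, axis=2) / n_genes)))

    degenerate = between_mean == 0.0
    if degenerate:
        warnings.warn("between-group mean divergence is 0; percentages undefined",
                      UserWarning, stacklevel=2)
        pct = {g: 0.0 for g in within}
        pct["between"] = 0.0
    else:
        pct = {g: 100.0 * v / between_mean for g, v in within.items()}
        pct["between"] = 100.0
    return DivergenceSummary(
        within_group_mean=within,
        between_group_mean=between_mean,
        percentages=pct,
        between_pair=(g_a, g_b),
        degenerate=degenerate,
    )
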