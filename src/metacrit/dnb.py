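"""Dynamic network biomarker (DNB) scan and criticality index.

A DNB is a gene module that signals an approaching critical transition: at
the tipping-point stage its members (i) fluctuate widely (rising SD),
(ii) become strongly mutually correlated, and (iii) decouple from the rest
of the network. The criticality index summarizes all three:

    CI = SD_avg * PCC_in / PCC_out

with SD_avg the average member SD at the stage, PCC_in the average absolute
pairwise Pearson correlation among members, and PCC_out the average absolute
correlation between members and all non-members. The scan proceeds per
non-reference stage: an SD-fold filter against the reference (normal) stage,
complete-linkage clustering of the surviving genes on 1 - |r| distance,
harvesting of every dendrogram cluster of sufficient size as a candidate
module, index computation for each candidate at the stage and at the
reference, and selection of the highest-CI candidate that satisfies the
three criteria. Within-stage per-gene standardization precedes correlation
(Pearson correlation is invariant to it; SDs are always taken on the
original scale, where they carry the signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, StageDesign

__all__ = [
    "EPS",
    "CriteriaConfig",
    "DNBCandidate",
    "DNBReport",
    "fisher_z",
    "stage_standardize",
    "sd_filter",
    "cluster_candidates",
    "module_indices",
    "scan_stages",
    "export_module_edges",
]

#: guard against division by a vanishing PCC_out (all-orthogonal background)
EPS = 1e-8


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z transform atanh(r) = 0.5 ln((1+r)/(1-r)); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def stage_standardize(expr: ExpressionMatrix, design: StageDesign) -> ExpressionMatrix:
    """Per-gene z-scoring within each stage (zero-SD genes left at 0).

    This is the normalization applied ahead of the correlation steps; Pearson
    correlations are invariant to it, so the scan itself operates on raw
    values, but the standardized matrix is exposed for inspection.
    """
    df = expr.data.copy()
    for stage in design.stage_order:
        samples = [s for s in design.samples_for(stage) if s in df.columns]
        if not samples:
            continue
        block = df[samples].to_numpy()
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        df[samples] = (block - mean) / sd
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class CriteriaConfig:
    """How 'significantly increased/decreased' is operationalized.

    ``ratio`` mode (default, deterministic): a candidate satisfies the three
    criteria iff sd_avg >= fold * sd_avg_ref, pcc_in >= tau_in * pcc_in_ref
    and pcc_out <= tau_out * pcc_out_ref. ``bootstrap`` mode resamples stage
    and reference samples B times and requires each inequality to hold in at
    least 1 - alpha of the replicates (one-sided level alpha).
    """

    mode: str = "ratio"
    tau_in: float = 1.5
    tau_out: float = 0.75
    bootstrap_b: int = 200
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ratio", "bootstrap"):
            raise ValueError(f"unknown criteria mode {self.mode!r}")


@dataclass
class DNBCandidate:
    stage: str
    members: list[str]
    sd_avg: float
    pcc_in: float
    pcc_out: float
    ci: float
    sd_avg_ref: float
    pcc_in_ref: float
    pcc_out_ref: float
    criteria_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def satisfies_criteria(self) -> bool:
        return all(self.criteria_flags.get(k, False)
                   for k in ("sd_up", "pcc_in_up", "pcc_out_down"))

    def to_dict(self) -> dict[str, Any]:
        return {
            "stage": self.stage,
            "members": list(self.members),
            "sd_avg": self.sd_avg,
            "pcc_in": self.pcc_in,
            "pcc_out": self.pcc_out,
            "ci": self.ci,
            "sd_avg_ref": self.sd_avg_ref,
            "pcc_in_ref": self.pcc_in_ref,
            "pcc_out_ref": self.pcc_out_ref,
            "criteria_flags": dict(self.criteria_flags),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DNBCandidate":
        return cls(
            stage=d["stage"], members=list(d["members"]), sd_avg=d["sd_avg"],
            pcc_in=d["pcc_in"], pcc_out=d["pcc_out"], ci=d["ci"],
            sd_avg_ref=d["sd_avg_ref"], pcc_in_ref=d["pcc_in_ref"],
            pcc_out_ref=d["pcc_out_ref"],
            criteria_flags=dict(d["criteria_flags"]),
        )


@dataclass
class DNBReport:
    candidates: list[DNBCandidate]
    selected_stage: str | None
    dnb_members: list[str]
    ci_curve: dict[str, float | None]

    @property
    def satisfying_candidates(self) -> list[DNBCandidate]:
        return [c for c in self.candidates if c.satisfies_criteria]

    def to_dict(self) -> dict[str, Any]:
        return {
            "selected_stage": self.selected_stage,
            "dnb_members": list(self.dnb_members),
            "ci_curve": dict(self.ci_curve),
            "candidates": [c.to_dict() for c in self.candidates],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DNBReport":
        return cls(
            candidates=[DNBCandidate.from_dict(c) for c in d["candidates"]],
            selected_stage=d["selected_stage"],
            dnb_members=list(d["dnb_members"]),
            ci_curve=dict(d["ci_curve"]),
        )


# ---------------------------------------------------------------------------
# scan steps
# ---------------------------------------------------------------------------


def _stage_values(
    expr: ExpressionMatrix, design: StageDesign, stage: str, min_samples: int
) -> np.ndarray:
    samples = design.require_min_samples(stage, min_samples)
    return expr.data[samples].to_numpy(dtype=float)


def _abs_corr(X: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation; zero-variance rows contribute |r| = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.abs(np.atleast_2d(C))
    C[np.isnan(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def sd_filter(
    expr: ExpressionMatrix,
    design: StageDesign,
    stage: str,
    fold: float = 2.0,
) -> list[str]:
    """Genes whose SD at ``stage`` is at least ``fold`` times the reference SD.

    The boundary is inclusive. Genes with zero reference SD pass whenever
    their stage SD is positive and are flagged with a warning.
    """
    if stage == design.reference_stage:
        raise ValueError("sd_filter compares a tumor stage against the reference")
    if fold <= 0:
        raise ValueError("fold must be positive")
    X = _stage_values(expr, design, stage, min_samples=3)
    R = _stage_values(expr, design, design.reference_stage, min_samples=3)
    sd_stage = X.std(axis=1, ddof=1)
    sd_ref = R.std(axis=1, ddof=1)
    zero_ref = sd_ref == 0
    keep = np.where(zero_ref, sd_stage > 0, sd_stage >= fold * sd_ref)
    genes = np.asarray(expr.gene_ids, dtype=object)
    flagged = genes[zero_ref & keep]
    if flagged.size:
        warnings.warn(
            f"{flagged.size} genes with zero reference SD passed the filter: "
            f"{list(flagged[:5])}",
            UserWarning,
            stacklevel=2,
        )
    return list(genes[keep])


def cluster_candidates(
    expr: ExpressionMatrix,
    design: StageDesign,
    stage: str,
    genes: Sequence[str],
    min_size: int = 5,
) -> list[list[str]]:
    """Candidate modules from complete-linkage clustering on 1 - |r| distance.

    Every cluster appearing at any cut height of the dendrogram (i.e. every
    internal node, including the root) with at least ``min_size`` members
    becomes a candidate; duplicates are removed. Fewer than ``min_size``
    input genes yield an empty list with a warning.
    """
    genes = list(genes)
    if len(genes) < min_size:
        warnings.warn(
            f"only {len(genes)} genes passed the SD filter at stage {stage!r} "
            f"(min_size={min_size}); no candidates",
            UserWarning,
            stacklevel=2,
        )
        return []
    X = expr.subset(genes=genes).data[
        design.require_min_samples(stage, 3)
    ].to_numpy(dtype=float)
    D = np.clip(1.0 - _abs_corr(X), 0.0, None)
    Z = linkage(squareform(D, checks=False), method="complete")
    _, nodes = to_tree(Z, rd=True)
    seen: set[frozenset[int]] = set()
    out: list[list[str]] = []
    for node in nodes:
        if node.get_count() < min_size:
            continue
        leaves = frozenset(node.pre_order(lambda leaf: leaf.id))
        if leaves in seen:
            continue
        seen.add(leaves)
        out.append(sorted(genes[i] for i in leaves))
    out.sort(key=lambda m: (len(m), m))
    return out


def _gauge_sds(sds: np.ndarray, ref_sds: np.ndarray | None) -> np.ndarray:
    """Express per-gene SDs in units of the gene's reference-stage SD.

    The gauging makes the average-SD term of the index comparable across
    genes of very different baseline variance: what matters for criticality
    is how much a gene's fluctuation has risen relative to its own normal
    baseline, not its raw variance. Genes with zero reference SD keep their
    raw SD (nothing to gauge against).
    """
    if ref_sds is None:
        return sds
    return np.where(ref_sds > 0, sds / np.where(ref_sds > 0, ref_sds, 1.0), sds)


def _indices_from_stats(
    C: np.ndarray,
    sds: np.ndarray,
    member_idx: np.ndarray,
    eps: float = EPS,
    ref_sds: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """(sd_avg, pcc_in, pcc_out, ci) from a precomputed |corr| matrix."""
    m = member_idx.size
    n = C.shape[0]
    block = C[np.ix_(member_idx, member_idx)]
    sum_in = block.sum() - m                      # remove unit diagonal
    pcc_in = sum_in / (m * (m - 1))
    cross = C[member_idx, :].sum() - block.sum()
    pcc_out = cross / (m * (n - m))
    sd_avg = float(_gauge_sds(sds, ref_sds)[member_idx].mean())
    ci = sd_avg * pcc_in / max(pcc_out, eps)
    return sd_avg, float(pcc_in), float(pcc_out), float(ci)


def module_indices(
    expr: ExpressionMatrix,
    design: StageDesign,
    stage: str,
    members: Sequence[str],
    universe: Sequence[str] | None = None,
    eps: float = EPS,
    sd_scale: str = "reference",
) -> DNBCandidate:
    """The four DNB indices of a module at a stage, plus the same indices at
    the reference stage for the identical gene set.

    ``sd_scale`` controls the units of the average-SD term: "reference"
    (default) divides each gene's stage SD by its reference-stage SD (the
    per-gene normalization of the scan, so the term measures the rise in
    fluctuation over baseline), "raw" uses the SDs as-is.
    """
    if sd_scale not in ("reference", "raw"):
        raise ValueError(f"unknown sd_scale {sd_scale!r}")
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members")
    universe = list(universe) if universe is not None else expr.gene_ids
    missing = set(members) - set(universe)
    if missing:
        raise ValueError(f"members outside universe: {sorted(missing)[:5]}")
    if len(universe) <= len(members):
        raise ValueError("universe must contain non-member genes")
    sub = expr.subset(genes=universe)
    member_idx = np.array([universe.index(g) for g in members])

    ref_X = _stage_values(sub, design, design.reference_stage, min_samples=2)
    ref_sds = ref_X.std(axis=1, ddof=1)
    gauge = ref_sds if sd_scale == "reference" else None

    def at(stage_label: str) -> tuple[float, float, float, float]:
        X = _stage_values(sub, design, stage_label, min_samples=2)
        return _indices_from_stats(_abs_corr(X), X.std(axis=1, ddof=1),
                                   member_idx, eps, ref_sds=gauge)

    sd_avg, pcc_in, pcc_out, ci = at(stage)
    sd_ref, pin_ref, pout_ref, _ = at(design.reference_stage)
    return DNBCandidate(
        stage=stage, members=sorted(members),
        sd_avg=sd_avg, pcc_in=pcc_in, pcc_out=pcc_out, ci=ci,
        sd_avg_ref=sd_ref, pcc_in_ref=pin_ref, pcc_out_ref=pout_ref,
    )


def _ratio_flags(c: DNBCandidate, fold: float, cfg: CriteriaConfig,
                 eps: float = EPS) -> dict[str, bool]:
    return {
        "sd_up": c.sd_avg >= fold * c.sd_avg_ref,
        "pcc_in_up": c.pcc_in >= cfg.tau_in * c.pcc_in_ref,
        "pcc_out_down": c.pcc_out <= cfg.tau_out * max(c.pcc_out_ref, eps),
    }


def _bootstrap_flags(
    X_stage: np.ndarray,
    X_ref: np.ndarray,
    member_idx: np.ndarray,
    fold: float,
    cfg: CriteriaConfig,
    rng: np.random.Generator,
    ref_gauge: np.ndarray | None = None,
) -> dict[str, bool]:
    """One-sided bootstrap over stage/reference samples for the 3 criteria."""

    def resample_indices(X: np.ndarray) -> tuple[float, float, float]:
        idx = rng.integers(0, X.shape[1], size=X.shape[1])
        Xb = X[:, idx]
        sds = _gauge_sds(Xb.std(axis=1, ddof=1), ref_gauge)
        sd_avg = float(sds[member_idx].mean())
        mean = Xb.mean(axis=1, keepdims=True)
        denom = sds.copy()
        denom[denom == 0] = 1.0
        Zb = (Xb - mean) / denom[:, None]
        m = member_idx.size
        cross_all = np.abs(Zb[member_idx] @ Zb.T / (Xb.shape[1] - 1))
        block = cross_all[:, member_idx]
        pcc_in = (block.sum() - np.trace(block)) / (m * (m - 1))
        pcc_out = (cross_all.sum() - block.sum()) / (m * (Xb.shape[0] - m))
        return sd_avg, float(pcc_in), float(pcc_out)

    hits = np.zeros(3)
    for _ in range(cfg.bootstrap_b):
        sd_s, pin_s, pout_s = resample_indices(X_stage)
        sd_r, pin_r, pout_r = resample_indices(X_ref)
        hits[0] += sd_s >= fold * sd_r
        hits[1] += pin_s > pin_r
        hits[2] += pout_s < pout_r
    frac = hits / cfg.bootstrap_b
    return {
        "sd_up": frac[0] >= 1.0 - cfg.alpha,
        "pcc_in_up": frac[1] >= 1.0 - cfg.alpha,
        "pcc_out_down": frac[2] >= 1.0 - cfg.alpha,
    }


def scan_stages(
    expr: ExpressionMatrix,
    design: StageDesign,
    fold: float = 2.0,
    min_size: int = 5,
    criteria: CriteriaConfig | None = None,
    eps: float = EPS,
    sd_scale: str = "reference",
    ci_rel_tol: float = 0.15,
) -> DNBReport:
    """Run the full five-step scan over every non-reference stage.

    Returns a report with all evaluated candidates, the per-stage CI curve
    (best candidate CI; None where no candidate formed), and the winning
    module: the criteria-satisfying candidate with the globally highest CI.
    Because the index is estimated from a few dozen samples, CI differences
    within ``ci_rel_tol`` (relative) of the maximum are treated as ties —
    for a minimum-size module at typical stage sizes the relative sampling
    error of CI is roughly 8-9%, so the default band is a one-sided ~95%
    allowance — and ties break toward the larger module, then the
    lexicographically smallest member list (nested sub-modules should not
    displace their parent module on estimation noise). No candidate
    anywhere => ``selected_stage`` is None.
    """
    cfg = criteria or CriteriaConfig()
    rng = np.random.default_rng(cfg.seed)
    universe = expr.gene_ids
    gene_pos = {g: i for i, g in enumerate(universe)}

    ref_cache: dict[str, np.ndarray] = {}

    def ref_stats() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if "C" not in ref_cache:
            X = _stage_values(expr, design, design.reference_stage, 3)
            ref_cache["X"] = X
            ref_cache["C"] = _abs_corr(X)
            ref_cache["sd"] = X.std(axis=1, ddof=1)
        return ref_cache["C"], ref_cache["sd"], ref_cache["X"]

    all_candidates: list[DNBCandidate] = []
    ci_curve: dict[str, float | None] = {}
    for stage in design.non_reference_stages:
        passed = sd_filter(expr, design, stage, fold=fold)
        member_lists = cluster_candidates(expr, design, stage, passed, min_size)
        if not member_lists:
            ci_curve[stage] = None
            continue
        X_stage = _stage_values(expr, design, stage, 3)
        C_stage = _abs_corr(X_stage)
        sd_stage = X_stage.std(axis=1, ddof=1)
        C_ref, sd_ref, X_ref = ref_stats()
        gauge = sd_ref if sd_scale == "reference" else None
        best_ci: float | None = None
        for members in member_lists:
            idx = np.array([gene_pos[g] for g in members])
            sd_avg, pcc_in, pcc_out, ci = _indices_from_stats(
                C_stage, sd_stage, idx, eps, ref_sds=gauge
            )
            sd_r, pin_r, pout_r, _ = _indices_from_stats(
                C_ref, sd_ref, idx, eps, ref_sds=gauge
            )
            cand = DNBCandidate(
                stage=stage, members=members,
                sd_avg=sd_avg, pcc_in=pcc_in, pcc_out=pcc_out, ci=ci,
                sd_avg_ref=sd_r, pcc_in_ref=pin_r, pcc_out_ref=pout_r,
            )
            if cfg.mode == "ratio":
                cand.criteria_flags = _ratio_flags(cand, fold, cfg, eps)
            else:
                cand.criteria_flags = _bootstrap_flags(
                    X_stage, X_ref, idx, fold, cfg, rng, ref_gauge=gauge
                )
            all_candidates.append(cand)
            best_ci = ci if best_ci is None else max(best_ci, ci)
        ci_curve[stage] = best_ci

    satisfying = [c for c in all_candidates if c.satisfies_criteria]
    if satisfying:
        # highest CI; near-ties (within ci_rel_tol) -> larger module ->
        # lexicographically smallest member list
        top = max(c.ci for c in satisfying)
        near = [c for c in satisfying if c.ci >= (1.0 - ci_rel_tol) * top]
        winner = sorted(
            near, key=lambda c: (-len(c.members), tuple(c.members), -c.ci)
        )[0]
        selected_stage, dnb_members = winner.stage, list(winner.members)
    else:
        selected_stage, dnb_members = None, []
    return DNBReport(all_candidates, selected_stage, dnb_members, ci_curve)


def export_module_edges(
    expr: ExpressionMatrix,
    design: StageDesign,
    stage: str,
    members: Sequence[str],
    path: str | Path,
) -> None:
    """Write the module's |r|-weighted edge list (gene_a, gene_b, abs_r) as TSV
    for external network visualization."""
    members = sorted(members)
    X = expr.subset(genes=members).data[
        design.require_min_samples(stage, 2)
    ].to_numpy(dtype=float)
    C = _abs_corr(X)
    with open(Path(path), "w") as fh:
        fh.write("gene_a\tgene_b\tabs_r\n")
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                fh.write(f"{members[i]}\t{members[j]}\t{C[i, j]:.6g}\n")
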