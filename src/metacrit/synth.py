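"""Synthetic staged cohorts with planted structure and full ground truth.

Two generators cover every downstream stage of the pipeline:

* :func:`simulate_staged_expression` emulates a multi-stage tumor cohort
  (e.g. Normal, Stage I-III) in which a designated gene module becomes a
  dynamic network biomarker at one critical stage: its per-gene standard
  deviation is inflated and its members acquire strong mutual correlation
  through a shared latent factor while decoupling from the background
  co-expression network. Optional trend genes follow six fixed stage-mean
  patterns for trend-clustering tests.

* :func:`simulate_cluster_cohort` emulates a tumor cohort whose samples fall
  into k metabolic clusters differing by mean shifts on disjoint signature
  pathways, with an optional gene-specific batch shift that simulates a
  second cohort measured on another platform.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` children, so every fixture is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, StageDesign

__all__ = [
    "TREND_PATTERNS",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_staged_expression",
    "simulate_cluster_cohort",
    "make_disjoint_pathways",
]

#: the six stage-mean trend shapes, as functions of the ordered stage index
TREND_PATTERNS = (
    "monotone_up",
    "monotone_down",
    "up_then_flat",
    "down_then_flat",
    "late_up",
    "late_down",
)


def _trend_profile(pattern: str, n_stages: int) -> np.ndarray:
    """Unit-amplitude stage-mean profile for one trend pattern."""
    i = np.arange(n_stages, dtype=float)
    if n_stages < 2:
        raise ValueError("trend profiles need >= 2 stages")
    up = i / (n_stages - 1)
    half = max(1, (n_stages - 1) // 2)
    up_flat = np.minimum(i / half, 1.0)
    late_up = (i == n_stages - 1).astype(float)
    profiles = {
        "monotone_up": up,
        "monotone_down": 1.0 - up,
        "up_then_flat": up_flat,
        "down_then_flat": 1.0 - up_flat,
        "late_up": late_up,
        "late_down": 1.0 - late_up,
    }
    return profiles[pattern]


@dataclass
class SimulationConfig:
    """Study conditions for the staged-cohort generator.

    ``sd_inflation`` multiplies the per-gene SD of module members at the
    critical stage; ``rho_in`` is their target pairwise correlation there,
    induced by a single shared latent factor (exchangeable structure);
    ``rho_baseline`` is the background co-expression level shared by all
    non-module genes through one weak cohort-wide factor. ``n_trend_genes``
    genes per pattern (six patterns) receive stage-mean offsets of
    ``trend_amplitude`` log2 units.
    """

    n_genes: int = 2000
    stage_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "Normal": 60, "Stage I": 60, "Stage II": 60, "Stage III": 60,
        }
    )
    critical_stage: str = "Stage II"
    dnb_size: int = 30
    sd_inflation: float = 3.0
    rho_in: float = 0.7
    rho_baseline: float = 0.2
    n_trend_genes: int = 0
    trend_amplitude: float = 2.0
    stage_drift: float = 0.0
    reference_stage: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dnb_size >= self.n_genes:
            raise ValueError("dnb_size must be smaller than n_genes")
        if self.critical_stage not in self.stage_sizes:
            raise ValueError(
                f"critical_stage {self.critical_stage!r} not among stages"
            )
        if any(n < 3 for n in self.stage_sizes.values()):
            raise ValueError("every stage needs >= 3 samples")
        if not (0.0 <= self.rho_in < 1.0 and 0.0 <= self.rho_baseline < 1.0):
            raise ValueError("correlations must lie in [0, 1)")
        if self.sd_inflation < 1.0:
            raise ValueError("sd_inflation must be >= 1")
        if self.n_trend_genes * len(TREND_PATTERNS) + self.dnb_size > self.n_genes:
            raise ValueError("not enough genes for trends plus the module")

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.stage_sizes)

    @property
    def reference(self) -> str:
        return self.reference_stage or next(iter(self.stage_sizes))


@dataclass
class SyntheticTruth:
    """Everything a test needs to score a downstream result."""

    dnb_members: list[str] = field(default_factory=list)
    critical_stage: str | None = None
    trend_assignments: dict[str, str] = field(default_factory=dict)
    cluster_labels: dict[str, str] = field(default_factory=dict)
    pathway_sets: GeneSetCollection | None = None


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    design: StageDesign
    truth: SyntheticTruth
    annotations: pd.DataFrame | None = None


def _rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_staged_expression(config: SimulationConfig) -> SyntheticDataset:
    """Generate a staged cohort with a planted tipping-point module.

    Background genes are independent Normal(mu_g, sigma_g) within stage with
    mu_g ~ U(4, 12) and sigma_g ~ U(0.3, 0.8) (log2 scale), weakly coupled
    through one cohort-wide factor so that pairwise correlation is
    ~= ``rho_baseline``. Module genes behave as background except at the
    critical stage, where each value is
    sigma_g * sd_inflation * (sqrt(rho_in) z_s + sqrt(1 - rho_in) eps)
    around mu_g, with one latent z per sample. Deterministic given the seed.
    """
    cfg = config
    rng = _rngs(cfg.seed, ("genes", "assign", "factors", "noise", "trend"))
    stages = cfg.stages
    n_stages = len(stages)
    total = sum(cfg.stage_sizes.values())

    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    mu = rng["genes"].uniform(4.0, 12.0, size=cfg.n_genes)
    sigma = rng["genes"].uniform(0.3, 0.8, size=cfg.n_genes)

    # plant trends first, then the module among the remaining genes
    order = rng["assign"].permutation(cfg.n_genes)
    trend_assign: dict[str, str] = {}
    cursor = 0
    for pattern in TREND_PATTERNS:
        for _ in range(cfg.n_trend_genes):
            trend_assign[gene_ids[order[cursor]]] = pattern
            cursor += 1
    dnb_idx = np.sort(order[cursor: cursor + cfg.dnb_size])
    dnb_members = [gene_ids[i] for i in dnb_idx]

    sample_ids: list[str] = []
    sample_stage: dict[str, str] = {}
    for stage in stages:
        tag = stage.replace(" ", "-")
        for j in range(cfg.stage_sizes[stage]):
            sid = f"{tag}_{j:03d}"
            sample_ids.append(sid)
            sample_stage[sid] = stage

    values = np.empty((cfg.n_genes, total))
    rho_b, rho_in = cfg.rho_baseline, cfg.rho_in
    col = 0
    trend_rows = {g: p for g, p in trend_assign.items()}
    for s_idx, stage in enumerate(stages):
        n_s = cfg.stage_sizes[stage]
        w = rng["factors"].standard_normal(n_s)            # background factor
        eps = rng["noise"].standard_normal((cfg.n_genes, n_s))
        block = mu[:, None] + sigma[:, None] * (
            np.sqrt(rho_b) * w[None, :] + np.sqrt(1.0 - rho_b) * eps
        )
        if cfg.stage_drift:
            block += cfg.stage_drift * s_idx
        if stage == cfg.critical_stage and cfg.dnb_size:
            z = rng["factors"].standard_normal(n_s)        # module latent
            eps_m = rng["noise"].standard_normal((cfg.dnb_size, n_s))
            block[dnb_idx] = mu[dnb_idx, None] + (
                sigma[dnb_idx, None] * cfg.sd_inflation
                * (np.sqrt(rho_in) * z[None, :] + np.sqrt(1.0 - rho_in) * eps_m)
            )
            if cfg.stage_drift:
                block[dnb_idx] += cfg.stage_drift * s_idx
        values[:, col: col + n_s] = block
        col += n_s

    # stage-mean offsets for trend genes
    if trend_rows:
        profiles = {
            p: cfg.trend_amplitude * _trend_profile(p, n_stages)
            for p in TREND_PATTERNS
        }
        stage_of_col = np.array(
            [stages.index(sample_stage[s]) for s in sample_ids]
        )
        for g, pattern in trend_rows.items():
            values[gene_ids.index(g)] += profiles[pattern][stage_of_col]

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    design = StageDesign(sample_stage, stages, cfg.reference)
    annotations = pd.DataFrame(
        {
            "cohort": "SIM",
            "group": [
                "normal" if sample_stage[s] == cfg.reference else "tumor"
                for s in sample_ids
            ],
            "stage": [sample_stage[s] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        dnb_members=dnb_members,
        critical_stage=cfg.critical_stage,
        trend_assignments=trend_assign,
    )
    return SyntheticDataset(expr, design, truth, annotations)


def make_disjoint_pathways(
    n_sets: int = 8,
    set_size: int = 25,
    prefix: str = "PW",
    start_gene: int = 0,
) -> GeneSetCollection:
    """Disjoint synthetic pathways over a fresh gene universe (deterministic)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    idx = start_gene
    for k in range(n_sets):
        genes = [f"g{idx + j:04d}" for j in range(set_size)]
        idx += set_size
        sets[f"{prefix}{k + 1}"] = (f"synthetic pathway {k + 1}", genes)
    return GeneSetCollection(sets)


def simulate_cluster_cohort(
    n_samples: int,
    n_clusters: int,
    pathway_sets: GeneSetCollection,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    batch_shift: float = 0.0,
    seed: int = 0,
    n_extra_genes: int = 300,
    cohort: str = "A",
    gene_param_seed: int | None = None,
) -> SyntheticDataset:
    """Generate a cohort with k planted clusters separated on signature pathways.

    The first ``n_clusters`` sets of ``pathway_sets`` act as cluster
    signatures and must be pairwise disjoint. Samples are assigned
    round-robin; cluster k's signature genes are shifted by
    ``effect_size * noise_sd`` (the pooled per-gene SD) in cluster-k samples.
    A non-zero ``batch_shift`` adds a gene-specific offset drawn from
    N(batch_shift, (1.5 * batch_shift)^2) — platform effects vary strongly
    from gene to gene (probe/primer affinity), so the dispersion is of the
    same order as the mean shift — simulating measurement of this cohort on
    a different platform; per-gene baselines mu_g are reproducible across
    cohorts via ``gene_param_seed``.
    """
    names = pathway_sets.names
    if n_clusters > len(names):
        raise ValueError("need at least one pathway set per cluster")
    signatures = [pathway_sets.genes(n) for n in names[:n_clusters]]
    seen: set[str] = set()
    for sig in signatures:
        overlap = seen & set(sig)
        if overlap:
            raise ValueError(f"signature sets overlap: {sorted(overlap)[:5]}")
        seen |= set(sig)

    pathway_genes = pathway_sets.all_genes()
    extra = [f"x{j:04d}" for j in range(n_extra_genes)]
    gene_ids = pathway_genes + extra
    n_genes = len(gene_ids)

    gene_rng = np.random.default_rng(
        np.random.SeedSequence(gene_param_seed if gene_param_seed is not None else seed)
        .spawn(1)[0]
    )
    mu = gene_rng.uniform(4.0, 12.0, size=n_genes)

    rng = _rngs(seed, ("noise", "batch", "surv"))
    sample_ids = [f"{cohort}_{j:03d}" for j in range(n_samples)]
    clusters = [f"C{(j % n_clusters) + 1}" for j in range(n_samples)]

    values = mu[:, None] + noise_sd * rng["noise"].standard_normal((n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for k, sig in enumerate(signatures):
        rows = [gene_pos[g] for g in sig]
        cols = [j for j, c in enumerate(clusters) if c == f"C{k + 1}"]
        values[np.ix_(rows, cols)] += effect_size * noise_sd
    if batch_shift:
        shift = rng["batch"].normal(batch_shift, 1.5 * abs(batch_shift), size=n_genes)
        values += shift[:, None]

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    design = StageDesign({s: "Tumor" for s in sample_ids}, ("Tumor",), "Tumor")

    # exponential survival filler with cluster-dependent scale (annotation only)
    scale = {f"C{k + 1}": 20.0 * (k + 1) for k in range(n_clusters)}
    surv_time = np.array(
        [rng["surv"].exponential(scale[c]) for c in clusters]
    )
    surv_event = rng["surv"].integers(0, 2, size=n_samples)
    annotations = pd.DataFrame(
        {
            "cohort": cohort,
            "group": "tumor",
            "stage": "Tumor",
            "cluster": clusters,
            "surv_time": surv_time,
            "surv_event": surv_event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        cluster_labels=dict(zip(sample_ids, clusters)),
        pathway_sets=pathway_sets,
    )
    return SyntheticDataset(expr, design, truth, annotations)
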