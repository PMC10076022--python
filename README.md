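# metacrit

Dynamic metabolic subtyping of staged tumor expression cohorts: find the
tipping-point stage of disease progression and its dynamic network
biomarker (DNB) module, quantify pathway-level deregulation by differential
rank conservation (DIRAC), score per-sample pathway enrichment, discover
metabolic subtypes by consensus k-means, and project external cohorts onto
those subtypes with a nearest-shrunken-centroids classifier.

The package is aimed at computational biologists working with bulk (or
pseudo-bulked single-cell) log2 expression matrices annotated with ordered
disease stages — for example hepatocellular carcinoma cohorts staged
Normal / I / II / III — together with pathway gene sets in GMT format
(e.g. KEGG metabolic pathways). A synthetic-data module generates staged
cohorts with a planted DNB module and planted cluster structure, so the
entire pipeline runs and is tested without any external download.

## The statistics at the core

**Criticality index (tipping-point detection).** A DNB module is a gene set
whose behavior signals an imminent critical transition at one stage:
member SDs rise, members become strongly mutually correlated, and the
module decouples from the rest of the network. For candidate module *M*
at a stage,

```
CI = SD_avg(M) · PCC_in(M) / PCC_out(M)
```

with `SD_avg` the average member SD (gauged per gene by its reference-stage
SD), `PCC_in` the mean absolute pairwise Pearson correlation among members,
and `PCC_out` the mean absolute correlation between members and all other
genes. The scan filters genes whose stage SD is ≥ 2× the reference SD,
clusters them (complete linkage on 1 − |r|), harvests every dendrogram
cluster of size ≥ 5 as a candidate, and selects the highest-CI candidate
that satisfies all three DNB criteria; the stage of that module is the
tipping point.

**Rank conservation index (DIRAC).** For an m-gene pathway, the majority
ordering over all m(m−1)/2 gene pairs in a phenotype forms a rank
template; a sample's matching score is the fraction of template pairs it
satisfies, and RCI is the phenotype's mean matching score against its own
template (1.0 = rigidly conserved ordering, ≈ 0.5 = random). Differential
conservation between phenotypes is tested by label permutation with BH
control across pathways.

**Global divergence.** Between two expression profiles,
`RMSD(x, y) = sqrt( Σᵢ (log2 xᵢ − log2 yᵢ)² / n )`, summarized within and
between phenotypes as percentages of the between-group mean.

**Per-sample enrichment.** ssGSEA-style running sums: genes ranked per
sample (descending, average ranks for ties), set score = integral of the
weighted in-set cumulative fraction minus the out-of-set cumulative
fraction, weight |rank statistic|^α (α = 0.25).

**Subtype discovery.** k-means over samples in z-scaled pathway-score
space, k ∈ 2..8; stability by consensus clustering (subsampled k-means,
co-assignment matrices, PAC = share of ambiguous consensus entries) and
cluster number by majority vote of minimal PAC, maximal silhouette and
maximal Calinski–Harabasz.

**Cross-cohort projection.** Nearest shrunken centroids:
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))` soft-thresholded by a
cross-validated Δ, discriminant
`δ_k(x) = Σᵢ (xᵢ − x̄'_ik)² / (sᵢ + s0)² − 2 log π_k`. Before scoring, each
cohort is standardized per gene (its own mean/SD; the training cohort's
stats define the reference score space), which cancels additive platform
offsets.

## Worked example

```bash
python examples/01_tipping_point_scan.py
```

```
CI curve (best candidate per stage):
  Stage I    -
  Stage II    23.64 <- selected
  Stage III  -

selected stage: Stage II (planted: Stage II)
module size: 30 genes; Jaccard overlap with planted module: 1.00
```

The scan found criteria-satisfying candidates only at Stage II — the stage
where the generator planted the module — and recovered all 30 planted
genes. Subtype discovery on a planted 4-cluster cohort
(`examples/03_subtype_discovery.py`) prints the PAC curve

```
  k=2: PAC=0.759   k=3: PAC=0.638   k=4: PAC=0.000   k=5: PAC=0.135 ...
index votes: {'pac': 4, 'silhouette': 4, 'calinski_harabasz': 4} -> chosen k = 4
adjusted Rand index vs planted clusters: 1.00
```

PAC collapsing to 0 exactly at k = 4 with unanimous index votes is the
signature of genuine cluster structure. The other examples cover DIRAC
(`02`), cross-cohort projection with and without batch alignment (`04`,
accuracy 1.00 aligned vs 0.74 unaligned on a +5 log2-unit platform shift)
and stage-trend clustering (`05`).

Every capability is also reachable from the `metacrit` command line
(`simulate`, `dnb-scan`, `trends`, `dirac`, `enrich`, `cluster`,
`classify train/predict`, and `run --config run.yaml` for the full
pipeline with a manifest).

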