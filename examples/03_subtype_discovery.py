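"""Discover metabolic subtypes by consensus k-means on pathway scores.

Simulates a 120-sample tumor cohort with four planted clusters, each
up-regulating one disjoint signature pathway; scores every sample against
eight pathways (ssGSEA-style), z-scales per pathway, and selects the
cluster number by consensus clustering (PAC), silhouette and
Calinski-Harabasz votes.
"""

import warnings

from sklearn.metrics import adjusted_rand_score

from metacrit import (
    kmeans_cluster,
    make_disjoint_pathways,
    scale_scores,
    select_k,
    silhouette_widths,
    simulate_cluster_cohort,
    ssgsea_scores,
)

warnings.filterwarnings("ignore", category=UserWarning)

sets = make_disjoint_pathways(n_sets=8, set_size=25)
sim = simulate_cluster_cohort(120, 4, sets, effect_size=3.0, seed=1)
E = scale_scores(ssgsea_scores(sim.expression, sets))

result = select_k(E, range(2, 9), seed=1, iters=200)
print("PAC by k (lower = more stable consensus):")
for k in result.k_values:
    print(f"  k={k}: PAC={result.pac[k]:.3f}  "
          f"silhouette={result.mean_silhouette[k]:+.3f}")
print(f"\nindex votes: {result.index_votes} -> chosen k = {result.chosen_k}")

model = kmeans_cluster(E, result.chosen_k, seed=1)
truth = [sim.truth.cluster_labels[s] for s in E.sample_ids]
ari = adjusted_rand_score(truth, model.labels_for(E.sample_ids))
_, mean_sil = silhouette_widths(E, model.assignments)
print(f"adjusted Rand index vs planted clusters: {ari:.2f}; "
      f"mean silhouette: {mean_sil:.2f}")
print("\nPAC dropping to ~0 exactly at the planted k, with silhouette and")
print("Calinski-Harabasz agreeing, is the signature of real cluster structure.")
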