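"""Quantify pathway rank conservation (DIRAC) and global divergence.

Builds a small tumor/normal cohort in which one pathway's gene ordering is
scrambled in tumors, computes each phenotype's rank conservation index
(RCI) per pathway with a permutation test, and summarizes the global RMSD
divergence geometry between and within the phenotypes.
"""

import numpy as np
import pandas as pd

from metacrit import dirac_table, divergence_summary
from metacrit.io import ExpressionMatrix, GeneSetCollection

rng = np.random.default_rng(0)
n_norm, n_tum, m = 30, 30, 6
base = np.sort(rng.normal(8, 2, size=m))[::-1]

# conserved pathway: same ordering in both groups (plus noise)
conserved = base[:, None] + 0.4 * rng.standard_normal((m, n_norm + n_tum))
# deregulated pathway: ordering scrambled per tumor sample
dereg_norm = base[:, None] + 0.4 * rng.standard_normal((m, n_norm))
dereg_tum = np.column_stack(
    [rng.permutation(base) + 0.4 * rng.standard_normal(m) for _ in range(n_tum)]
)
values = np.vstack([conserved, np.hstack([dereg_norm, dereg_tum])])
genes = [f"c{i}" for i in range(m)] + [f"d{i}" for i in range(m)]
samples = [f"N{j}" for j in range(n_norm)] + [f"T{j}" for j in range(n_tum)]
expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

sets = GeneSetCollection({
    "conserved_pathway": ("", [f"c{i}" for i in range(m)]),
    "deregulated_pathway": ("", [f"d{i}" for i in range(m)]),
})
normals = [s for s in samples if s.startswith("N")]
tumors = [s for s in samples if s.startswith("T")]

table = dirac_table(expr, sets, tumors, normals, n_perm=500, seed=1)
print("pathway-level rank conservation (RCI: 1 = rigid ordering, ~0.5 = random):")
print(table.round(3).to_string())
print("\nThe deregulated pathway loses rank conservation in tumors"
      " (low rci_a, small q); the conserved one does not.")

summary = divergence_summary(expr, {"tumor": tumors, "normal": normals})
print("\nglobal RMSD divergence (% of tumor-vs-normal mean):")
for label, pct in summary.percentages.items():
    print(f"  {label:8s} {pct:6.1f}%")
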