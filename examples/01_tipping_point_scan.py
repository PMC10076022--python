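"""Detect the tipping-point stage of a staged tumor cohort.

Simulates a four-stage cohort (Normal, Stage I-III, 60 samples each, 2,000
genes) in which a 30-gene module triples its per-gene SD and becomes
strongly intercorrelated at Stage II, then scans every tumor stage for
criteria-satisfying modules and reports the criticality index (CI) curve.
"""

import warnings

from metacrit import SimulationConfig, scan_stages, simulate_staged_expression

warnings.filterwarnings("ignore", category=UserWarning)

sim = simulate_staged_expression(SimulationConfig(seed=0))
report = scan_stages(sim.expression, sim.design)

print("CI curve (best candidate per stage):")
for stage, ci in report.ci_curve.items():
    marker = " <- selected" if stage == report.selected_stage else ""
    print(f"  {stage:10s} {'-' if ci is None else f'{ci:6.2f}'}{marker}")

truth = set(sim.truth.dnb_members)
found = set(report.dnb_members)
print(f"\nselected stage: {report.selected_stage} "
      f"(planted: {sim.truth.critical_stage})")
print(f"module size: {len(found)} genes; "
      f"Jaccard overlap with planted module: "
      f"{len(truth & found) / len(truth | found):.2f}")
print("\nA high CI at exactly one stage is the tipping-point signal: the")
print("module's fluctuation (SD) rises, internal |r| strengthens and its")
print("correlation to the rest of the transcriptome weakens there.")
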