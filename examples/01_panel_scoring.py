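"""Score a cohort with the four packaged immune prognosis formulas.

Each panel score is a weighted sum of transcript-variant FPKM values:
score(sample) = sum_v coefficient(v) * FPKM(v, sample).
"""

from pcnsl_immune import SimulationConfig, compute_all_scores, load_panels, simulate_cohort

panels = load_panels("pcnsl2019")
print("Packaged panels:", {name: f"{len(p)} variants" for name, p in panels.items()})
print(f"Example coefficients: Th1/CD4-001 = {panels['Th1'].weights['CD4-001']}, "
      f"Inhibitory/PDCD1-002 = {panels['Inhibitory'].weights['PDCD1-002']}")

# a 31-patient synthetic cohort shaped like a real PCNSL series
cohort, _ = simulate_cohort(SimulationConfig(seed=0))
scores = compute_all_scores(cohort, panels)

print(f"\nScores for the first 5 of {cohort.n_samples} patients:")
header = "sample  " + "  ".join(f"{name:>11}" for name in scores)
print(header)
for sample in cohort.sample_ids[:5]:
    row = "  ".join(f"{scores[name].scores[sample]:11.3f}" for name in scores)
    print(f"{sample}  {row}")

print("\nHigher scores mean stronger expression of that immune program; the")
print("median of each column is the split point used for survival analysis.")
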