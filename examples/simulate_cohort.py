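"""Simulate a synthetic molt-cycle cohort and inspect its structure.

Generates the default study design: 12 target genes + 4 housekeeping genes,
3 replicate pools of 3 copepods per sampling day (days 1-10 plus the
combined 11-12 and 13-14 groups), with per-individual apolysis timing.
"""

from moltmark import CohortDesign, default_paper_profiles, simulate_cohort

design = CohortDesign()
matrix, truth = simulate_cohort(design, default_paper_profiles(), seed=1)

print(f"samples: {matrix.n_samples}  genes: {len(matrix.genes)} "
      f"({len(matrix.target_genes)} targets + {len(matrix.housekeeping_genes)} references)")
print(f"planted discriminator pair: {truth.planted_pair[0]}/{truth.planted_pair[1]}")

torso = matrix.values.groupby(matrix.samples["day"])["Torso-like"].mean()
print("\nTorso-like daily mean log2 expression:")
for day, val in torso.items():
    print(f"  day {day:>4g}: {val:7.2f}")

# The mean trajectory declines gently, then jumps by ~10 log2 units
# (about a thousand-fold) between days 7 and 10 - the late-stage surge the
# ratio screen exploits.
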