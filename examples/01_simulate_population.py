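"""Simulate a small-Ne cattle-like population and summarize its LD structure.

Builds a haplotype pool with the three-phase demography (large ancestral
population, recent bottleneck at Ne=30, expansion to the slaughter
population), samples a genotyped cohort, and prints the distance-binned
adjacent-pair r² — the classic LD-decay table.
"""

import numpy as np

from snpladder import ldstats
from snpladder import simdata as sd

cfg = sd.SimConfig(
    n_chromosomes=5,
    chrom_length_bp=80_000_000,
    n_markers_total=5000,
    effective_size=30,
    seed=7,
)
panel, mmap = sd.simulate_haplotypes(cfg)
freq = panel.allele1_freq()
maf = np.minimum(freq, 1 - freq)
print(f"simulated {len(mmap)} markers on {cfg.n_chromosomes} chromosomes")
print(f"fraction of markers with MAF > 0.01: {(maf > 0.01).mean():.3f}")

cohort = sd.sample_genotypes(panel, 400, seed=8)
summary = ldstats.adjacent_r2(cohort, mmap)
print(
    f"\nadjacent-pair LD over {summary.n_pairs} pairs: "
    f"mean r² = {summary.mean_r2:.3f}, mean distance = {summary.mean_d_mb:.3f} Mb"
)
print("\ndistance-binned means (r² should fall as distance grows):")
print(ldstats.bin_summary(summary).to_string(index=False))
# Interpretation: a small effective size keeps r² elevated even at several
# hundred kb, which is what makes sparse equally-spaced panels usable.
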