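"""Two-way and three-way information-gain analysis with permutation testing.

Scans every pair among a shortlist of SNPs for synergistic information about
the disease outcome, expressed as a percentage of the phenotype entropy, and
assigns each pair a label-shuffle permutation p-value.
"""

from epigain import (
    PermutationConfig,
    SimConfig,
    info_gain_3,
    pairwise_scan,
    parity3_penetrance,
    simulate,
    xor_penetrance,
)

g, phen, truth = simulate(SimConfig(
    n_cases=472, n_controls=472, n_snps=10,
    models=[xor_penetrance(h=0.4, loci=(2, 7))],
    functional_maf=0.5, seed=5,
))

results = pairwise_scan(g, phen, PermutationConfig(n_permutations=1000, seed=1))
print("top 3 pairs by information gain:")
for r in results[:3]:
    print(f"  {r.snp_ids[0]} x {r.snp_ids[1]}: gain {r.gain_pct:.2f}% of H(D), "
          f"p = {r.p_value:.3f} (add-one p = {r.p_value_add1:.3f})")
print("-> the planted pair explains a large share of the outcome entropy; "
      "null pairs sit near 0% with large p-values.")

# three-way synergy on a parity trio: all lower-order terms vanish
g3, phen3, _ = simulate(SimConfig(
    n_cases=1000, n_controls=1000, n_snps=3,
    models=[parity3_penetrance(h=0.5, loci=(0, 1, 2))],
    functional_maf=0.5, seed=8,
))
r3 = info_gain_3(g3.genotypes[:, 0], g3.genotypes[:, 1], g3.genotypes[:, 2],
                 phen3, cfg=PermutationConfig(1000, seed=2))
print(f"parity trio: mains ~ {max(abs(m) for m in r3.main_effects):.4f} bits, "
      f"pair gains ~ {max(abs(p) for p in r3.pair_gains):.4f} bits, "
      f"three-way gain {r3.gain_pct:.1f}% of H(D), p = {r3.p_value:.3f}")
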