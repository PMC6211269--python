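"""Simulate a balanced case-control cohort with a planted epistatic pair.

Builds a 472/472 cohort of 200 SNPs in which two loci interact through a
pure-epistasis XOR penetrance (no marginal effects at MAF 0.5), then shows
that single-SNP association finds nothing at the functional loci.
"""

import numpy as np

from epigain import SimConfig, simulate, single_snp_association, xor_penetrance

cfg = SimConfig(
    n_snps=200,                                 # 472 cases / 472 controls default
    models=[xor_penetrance(h=0.4, loci=(5, 17))],
    functional_maf=0.5,
    seed=42,
)
g, phen, truth = simulate(cfg)
print(f"cohort: {g.n_samples} samples x {g.n_snps} SNPs, "
      f"{int(phen.labels.sum())} cases")
print(f"planted interacting loci: {truth.functional_loci}")

pvals = single_snp_association(g, phen)
for locus in truth.functional_loci:
    print(f"single-SNP chi-square p at locus {locus}: {pvals[locus]:.3f}")
print(f"median p across null SNPs: {np.median(pvals):.3f}")
print("-> the functional loci look like noise marginally; their signal is "
      "purely in the pair.")
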