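"""Quality control on a cohort with injected missingness.

Runs the standard per-sample and per-marker filter chain (missingness, MAF,
Hardy-Weinberg, LD pruning) followed by mode imputation, and prints what each
filter removed.
"""

from epigain import QCParams, SimConfig, inject_missing, run_qc, simulate

g, phen, _ = simulate(SimConfig(n_cases=250, n_controls=250, n_snps=300,
                                ld_block_spec=[(6, 0.95)], seed=11))
g = inject_missing(g, rate=0.002, seed=1)

clean, phen, report = run_qc(g, phen, QCParams())
print(f"input : {report.n_samples_in} samples x {report.n_snps_in} SNPs")
print(f"output: {report.n_samples_out} samples x {report.n_snps_out} SNPs")
print(f"samples removed (missingness/heterozygosity): "
      f"{report.samples_removed_missing}/{report.samples_removed_het}")
print(f"SNPs removed  missing={report.snps_removed_missing}  "
      f"maf={report.snps_removed_maf}  hwe={report.snps_removed_hwe}  "
      f"ld={report.snps_removed_ld}")
print("-> the planted 6-SNP LD block collapses to its first member; "
      "the cleaned matrix has no missing calls.")
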