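# epigain

Detecting epistatic (gene–gene) interactions in case–control GWAS data:
quality control → TuRF interaction-sensitive filtering → dual tree-ensemble
SNP ranking with consensus selection → information-theoretic two- and
three-way interaction analysis with permutation testing. The package ships a
penetrance-model cohort simulator with planted epistatic effects, so the
whole pipeline can be exercised and validated end-to-end on synthetic data.

## The problem

Single-marker association tests miss SNP pairs whose effect on disease is
*purely* interactive: each locus looks like noise on its own, yet the pair
jointly determines risk. `epigain` quantifies such interactions in bits of
information. With disease status `D` and SNPs `A`, `B`, `C`:

- main effect: `I(A;D)` (mutual information),
- two-way gain: `IG(A;B;D) = I(AB;D) − I(A;D) − I(B;D)`,
- three-way gain: `IG(A;B;C;D) = I(ABC;D) − Σ mains − Σ pairwise gains`,

so the joint information `I(ABC;D)` decomposes exactly into mains, pairwise
gains, and the three-way term. Gains are reported as a percentage of the
phenotype entropy `H(D)` and tested by label-permutation (1000 permutations
by default). Upstream, TuRF (iterated ReliefF) filters the panel down to
interaction-relevant SNPs, and a random forest plus a gradient boosting
machine — run under repeated stratified cross-validation behind a common
adapter contract — provide a consensus importance ranking.

## Worked example

Simulate a 472/472 case–control cohort with a planted two-locus XOR
interaction (`h = 0.4`, MAF 0.5 → exactly zero marginal effects), then scan
pairs (`examples/01_simulate_cohort.py`, `examples/05_interaction_analysis.py`):

```python
from epigain import (PermutationConfig, SimConfig, pairwise_scan,
                     simulate, xor_penetrance)

g, phen, truth = simulate(SimConfig(
    n_cases=472, n_controls=472, n_snps=10,
    models=[xor_penetrance(h=0.4, loci=(2, 7))],
    functional_maf=0.5, seed=5,
))
for r in pairwise_scan(g, phen, PermutationConfig(1000, seed=1))[:3]:
    print(r.snp_ids, f"{r.gain_pct:.2f}% of H(D)", f"p={r.p_value:.3f}")
```

Output:

```
top 3 pairs by information gain:
  snp00002 x snp00007: gain 48.46% of H(D), p = 0.000 (add-one p = 0.001)
  snp00000 x snp00001: gain 0.94% of H(D), p = 0.018 (add-one p = 0.019)
  snp00007 x snp00009: gain 0.83% of H(D), p = 0.045 (add-one p = 0.046)
```

The planted pair (loci 2 and 7) explains nearly half the outcome entropy
while every null pair sits near 0%. Marginally, the same loci are invisible —
their single-SNP chi-square p-values in this cohort are 0.464 and 0.834,
indistinguishable from the null median of 0.540.

TuRF sees them clearly (`examples/03_turf_filtering.py`, 200-SNP panel):

```
TuRF rank of functional locus 5: 1 of 200
TuRF rank of functional locus 17: 2 of 200
mean+3SD threshold selects 2 SNPs: ['snp00005', 'snp00017']
```

and the dual-ensemble diagonal consensus shortlists them too
(`examples/04_ensemble_consensus.py`):

```
rf: CV accuracy 0.488, AUC 0.484
gbm: CV accuracy 0.531, AUC 0.553
Spearman correlation of the two importance scorings: 0.85
consensus top-5% selection (10 SNPs): ['snp00005', 'snp00017', ...]
contains the planted pair: True
```

(Note the near-chance CV accuracy: a pure interaction with zero marginal
effect is barely learnable at n = 800, yet the importance rankings still
surface the pair.)

Three-way: on a parity trio (`h = 0.5`, n = 2000) all mains and pairwise
gains vanish while the three-way gain is essentially all of `H(D)`:

```
parity trio: mains ~ 0.0001 bits, pair gains ~ 0.0013 bits,
three-way gain 99.7% of H(D), p = 0.000
```

The full pipeline (QC → TuRF → rank → interact) runs from a single YAML
config via `run_pipeline` / `epigain pipeline`, writing per-stage TSV
artifacts and a manifest with SHA-256 checksums.

## Layout

- `src/epigain/` — library: `genotype` (I/O), `qc`, `simulate`, `relief`
  (ReliefF/TuRF), `ensemble`, `infogain`, `pipeline`, `cli`
- `examples/` — five narrative scripts covering each stage
- `docs/methods.md` — model, parameter rationale, generator realism,
  numerical conventions, limitations
- `scripts/acceptance.py` — recomputes the table above from a seed
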