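# Methods note

`epigain` is a pipeline for detecting epistatic (gene–gene) interactions in
case–control GWAS data: quality control → interaction-sensitive TuRF
filtering → dual tree-ensemble ranking with consensus selection →
information-theoretic two- and three-way interaction analysis with
permutation testing. This note records the model, the parameter choices and
their rationale, the realism and limits of the synthetic-data generator, and
the numerical conventions used throughout.

## Model and assumptions

Genotypes are biallelic SNPs coded as minor-allele dosages {0, 1, 2}
(missing = −1 before imputation); phenotypes are binary case/control labels.
The analysis is retrospective case–control: all probabilities are estimated
from the sampled cohort, and significance is assessed by permuting labels,
which conditions on both margins.

Interaction strength is measured in bits with plug-in (maximum-likelihood)
entropies:

- mutual information `I(A;D) = H(A) + H(D) − H(A,D)`;
- two-way information gain `IG(A;B;D) = I(AB;D) − I(A;D) − I(B;D)`;
- three-way information gain
  `IG(A;B;C;D) = I(ABC;D) − Σ mains − Σ pairwise IGs`,
  so that `I(ABC;D)` decomposes exactly into 3 mains + 3 pairwise gains +
  the three-way term.

Gains are also reported as a percentage of the phenotype entropy,
`100 · IG / H(D)`, which is the scale-free quantity used for ranking.

## Parameter defaults and rationale

**QC** (`QCParams`): sample missingness ≤ 1%; heterozygosity within ±3
sample-SD of the cohort mean; SNP missingness ≤ 5%; MAF ≥ 5%; remove SNPs
with Hardy–Weinberg 1-df chi-square p < 1e−4; greedy keep-first LD pruning at
r² > 0.6 within a 2000-SNP window; mode imputation last. Filters run in that
order, so each filter sees the survivors of the previous one. These are
conventional GWAS thresholds; the HWE direction follows the standard
convention of removing markers that *violate* equilibrium (small p).

**TuRF** (`ReliefParams`): ReliefF with k = 10 nearest hits/misses per
class, every sample used as a reference, Manhattan distance on dosages and a
0/1 mismatch diff; 10 TuRF iterations each removing
`max(1, floor(0.10 · remaining))` of the worst-scoring SNPs, followed by a
mean + 3 SD selection threshold (strictly greater, sample SD). Removed SNPs
keep a rank-preserving score below all survivors, so the final table is a
full ranking. ReliefF is used because neighbour-based weights respond to
interactions that single-marker tests cannot see.

**Ensemble ranking**: two tree ensembles behind a common `LearnerAdapter`
contract — a bagged random forest (Gini impurity importances) and a gradient
boosting machine (impurity-improvement importances, `min_samples_leaf` 10,
subsample 0.5) — evaluated by repeated stratified k-fold cross-validation.
Grid search (`tune`) selects parameters by mean CV accuracy with pooled AUC
as tie-break; the full grids are mtry {100, 200, 300, 500, 1000} × ntree
{500, 1000, 2000} for the forest and n_trees {100, 500, 1000, 2000} × depth
{1, 2, 10} × shrinkage {0.001, 0.01, 0.1} for the GBM. Importances are
averaged over all fold × repeat models and min–max normalised per method.
Consensus selection offers two rules: the *diagonal* rule (select SNPs with
normalised_rf + normalised_gbm ≥ t, a line across the joint score scatter)
and a top-k intersection rule. The diagonal rule is the primary one.

At desk scale (n = 800, 200 SNPs, the size used by the test-suite recovery
studies) the fixed configuration is ntree = 200, mtry = 50 (25% of
candidates), GBM depth 10 / shrinkage 0.1, 5-fold CV × 2 repeats (10 models
averaged), diagonal consensus with t set to the k-th largest sum for a top-5%
selection. These were sized once as scaled-down analogues of the full grids
and then frozen; they are not tuned per dataset.

**Interaction analysis** (`PermutationConfig`): 1000 label permutations per
test. The primary p-value is the strictly-greater exceedance fraction
`b / N`; an add-one estimate `(b + 1) / (N + 1)` is reported alongside
because the primary estimate can be exactly 0. Permutation nulls are
vectorised (permuted label matrix × one-hot genotype-state matrix), and each
test draws its own seed from a `SeedSequence` spawn so results are
independent of scan order.

## Synthetic-data generator: realism and limits

`simulate` draws genotypes under Hardy–Weinberg equilibrium at MAFs uniform
in a configurable range (default [0.05, 0.5]) and assigns case/control
status by rejection sampling against explicit penetrance tables over the
functional loci, filling fixed case and control quotas (default 472/472).
Built-in models are the two-locus XOR (parity) model and a three-locus
parity model, both `P(case) = 0.5 ± h`: at MAF 0.5 these have *exactly* zero
marginal effects, making them the hardest case for marginal methods and a
clean positive control for interaction methods. Multiple models combine as
independent risks, `P(case) = 1 − Π(1 − p_m)`. LD blocks are planted by
copying a seed column with per-genotype flip probability `1 − sqrt(r²)`, and
missing calls can be injected at a fixed rate.

Limits: markers are unlinked except for explicitly planted blocks; there is
no population structure, covariates, genotyping batch effects, or imputation
uncertainty; penetrance is constant within a genotype class. Quota-filling
rejection sampling reproduces the retrospective case–control joint
distribution but not population prevalence.

Note that pure-parity planted signals are adversarial for impurity-based
tree importances: a functional SNP with zero marginal effect only gains
importance when a tree happens to condition on its partner first. In the
package's own recovery study (XOR, h = 0.4, MAF 0.5, n = 800, 200 SNPs, 20
seeds) TuRF retained both functional SNPs in 20/20 seeds and the pairwise
information-gain scan ranked the pair first in 20/20 seeds, but the
dual-ensemble top-5% consensus contained both in only 15/20 seeds, and
sweeps over mtry, depth and repeats did not raise the forest's side of the
consensus further. Interaction-aware steps (TuRF, information gain) are the
reliable detectors of purely epistatic signal; ensemble consensus adds value
mainly when functional loci also carry some marginal effect.

## Numerical conventions

- Entropies in bits with `0 log 0 = 0`; plug-in estimates, no pseudocounts.
- Mutual information clamped at 0 against floating-point cancellation;
  joint genotype states encoded base-3.
- Chi-square association and HWE tests without continuity correction;
  monomorphic markers get p = 1.
- LD r² is the squared Pearson correlation of dosages over pairwise-complete
  samples; constant or near-empty columns give r² = 0.
- Mode imputation breaks ties toward the smaller genotype code.
- ReliefF neighbour ties break by sample index; importance-ranking ties
  break by SNP order (stable sort).
- Grid-search ties break toward the earlier grid cell; accuracy first, AUC
  second.
- All randomness derives from `numpy.random.SeedSequence([master, *part])`
  so any fold, repeat, grid cell, or permutation test is reproducible in
  isolation; seeds are kept below 2³¹.

## Limitations

Plug-in information estimates are biased upward for sparse contingency
tables (27 genotype states for trios), which is why ranking uses the gain
itself but inference relies on permutation p-values, which are exact-level
under the null regardless of the estimator's bias. The pipeline tests pairs
and trios exhaustively over the filtered shortlist only; genome-wide
exhaustive scans are out of scope. No multiple-testing correction is applied
beyond the permutation p-values themselves; users scanning many pairs should
apply their preferred correction to the reported p-values.
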