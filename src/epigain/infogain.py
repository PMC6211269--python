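"""Information-theoretic two-way and three-way SNP interaction analysis.

Genotypes and disease status are treated as discrete random variables.  The
main effect of SNP A is the mutual information I(A;D) with the disease
outcome D.  The two-way information gain of a SNP pair is the synergy left
after removing both main effects from the joint mutual information,

    IG(A;B;D) = I(AB;D) - I(A;D) - I(B;D),

where AB is the 9-state joint genotype variable; the three-way gain subtracts
all main effects and all pairwise gains from I(ABC;D) (27 joint states).
Gains are reported in bits and as a percentage of the phenotype entropy H(D)
(for a balanced cohort H(D) = 1 bit, so bits x 100 = percent).  Significance
is assessed by a permutation test that reshuffles the disease labels; the
p-value is the fraction of permuted datasets with a strictly greater gain
(an add-one-corrected p-value is carried alongside since 0/N is improper).

All entropies use the plug-in (maximum-likelihood) estimator with the
0 log 0 = 0 convention and no pseudo-counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genotype import MISSING, GenotypeMatrix, Phenotype

__all__ = [
    "PermutationConfig",
    "InteractionResult",
    "entropy",
    "contingency_table",
    "mutual_info",
    "info_gain_2",
    "info_gain_3",
    "permutation_test",
    "pairwise_scan",
    "threeway_scan",
]

_LOG2 = np.log(2.0)


@dataclass
class PermutationConfig:
    """Permutation-test settings: number of shuffles and the seed stream."""

    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")


@dataclass
class InteractionResult:
    """One SNP pair or trio with its information decomposition.

    ``gain`` is the synergistic information gain in bits; ``gain_pct`` the
    same as a percentage of H(D).  ``pair_gains`` is populated for trios only
    (gains of the three contained pairs, in combination order).
    """

    snp_ids: tuple[str, ...]
    main_effects: tuple[float, ...]
    gain: float
    gain_pct: float
    pair_gains: tuple[float, ...] = ()
    joint_mi: float = 0.0
    p_value: float | None = None
    p_value_add1: float | None = None
    n_permutations: int = 0


def entropy(p) -> float:
    """Shannon entropy in bits of a probability vector or count vector."""
    p = np.asarray(p, dtype=float).ravel()
    if (p < 0).any():
        raise ValueError("negative probabilities/counts")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero distribution has no entropy")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / _LOG2)


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Vectorised plug-in entropy (bits) along the last axis of a count array."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / total
        term = np.where(counts > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1) / _LOG2


def _joint_states(cols: list[np.ndarray]) -> np.ndarray:
    """Encode k genotype columns as a single 3^k-state variable."""
    state = np.zeros(cols[0].shape[0], dtype=np.int64)
    for c in cols:
        if (c == MISSING).any():
            raise ValueError("interaction analysis requires imputed genotypes")
        state = state * 3 + c
    return state


def contingency_table(cols: list[np.ndarray], phen: Phenotype) -> np.ndarray:
    """(3^k, 2) count table of joint genotype states by disease status."""
    k = len(cols)
    state = _joint_states(cols)
    y = phen.labels
    n_states = 3**k
    table = np.zeros((n_states, 2), dtype=np.int64)
    np.add.at(table, (state, y), 1)
    return table


def mutual_info(table: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a states x disease count table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    hx = entropy(table.sum(axis=1))
    hd = entropy(table.sum(axis=0))
    hxd = entropy(table.ravel())
    return float(max(0.0, hx + hd - hxd))


def _mi_from_case_counts(case: np.ndarray, total: np.ndarray, hd: float) -> np.ndarray:
    """MI (bits) given per-state case counts; supports a leading batch axis.

    ``case`` has shape (..., S); ``total`` is the fixed per-state count vector.
    I = H(X) + H(D) - H(X, D), with H(X) and H(D) constant under label
    permutation.
    """
    case = np.asarray(case, dtype=float)
    ctrl = total - case  # total broadcasts over any batch axes of case
    joint = np.concatenate([case[..., None], ctrl[..., None]], axis=-1)
    hxd = _entropy_rows(joint.reshape(joint.shape[:-2] + (-1,)))
    hx = _entropy_rows(total)
    return hx + hd - hxd


def _fold_case_counts(case27: np.ndarray, k: int, keep: tuple[int, ...]) -> np.ndarray:
    """Marginalise 3^k per-state case counts onto a subset of loci."""
    shaped = case27.reshape(case27.shape[:-1] + (3,) * k)
    drop = tuple(ax for ax in range(k) if ax not in keep)
    axes = tuple(ax - k for ax in drop)
    folded = shaped.sum(axis=axes) if axes else shaped
    return folded.reshape(case27.shape[:-1] + (3 ** len(keep),))


def _gain_components(cols: list[np.ndarray], phen: Phenotype):
    """Per-state totals/case counts and H(D) for a pair or trio of columns."""
    k = len(cols)
    state = _joint_states(cols)
    y = phen.labels.astype(np.int64)
    n_states = 3**k
    total = np.bincount(state, minlength=n_states).astype(float)
    case = np.bincount(state, weights=y, minlength=n_states)
    hd = entropy(np.array([len(y) - y.sum(), y.sum()]))
    if hd == 0.0:
        raise ValueError("constant phenotype: H(D) = 0, gains undefined")
    return state, total, case, hd


def _ig_from_counts(case: np.ndarray, total: np.ndarray, k: int, hd: float):
    """Information-gain decomposition from 3^k case/total state counts.

    Returns (mains, pair_gains, gain, joint_mi); supports a leading batch
    axis on ``case`` for vectorised permutation nulls.
    """
    joint_mi = _mi_from_case_counts(case, total, hd)
    mains = [
        _mi_from_case_counts(_fold_case_counts(case, k, (i,)),
                             _fold_case_counts(total, k, (i,)), hd)
        for i in range(k)
    ]
    if k == 2:
        gain = joint_mi - mains[0] - mains[1]
        return mains, [], gain, joint_mi
    pair_gains = []
    for i, j in combinations(range(k), 2):
        mi_pair = _mi_from_case_counts(_fold_case_counts(case, k, (i, j)),
                                       _fold_case_counts(total, k, (i, j)), hd)
        pair_gains.append(mi_pair - mains[i] - mains[j])
    gain = joint_mi - sum(pair_gains) - sum(mains)
    return mains, pair_gains, gain, joint_mi


def _interaction(cols, phen, snp_ids, cfg: PermutationConfig | None) -> InteractionResult:
    k = len(cols)
    state, total, case, hd = _gain_components(cols, phen)
    mains, pair_gains, gain, joint_mi = _ig_from_counts(case, total, k, hd)
    res = InteractionResult(
        snp_ids=tuple(snp_ids),
        main_effects=tuple(float(m) for m in mains),
        gain=float(gain),
        gain_pct=float(100.0 * gain / hd),
        pair_gains=tuple(float(p) for p in pair_gains),
        joint_mi=float(joint_mi),
    )
    if cfg is not None and cfg.n_permutations > 0:
        rng = np.random.default_rng(cfg.seed)
        null = _null_gains(state, total, phen.labels, k, hd, cfg.n_permutations, rng)
        greater = int((null > gain).sum())
        res.p_value = greater / cfg.n_permutations
        res.p_value_add1 = (greater + 1) / (cfg.n_permutations + 1)
        res.n_permutations = cfg.n_permutations
    return res


def _null_gains(state, total, labels, k, hd, n_perm, rng) -> np.ndarray:
    """Information gains under label permutation, vectorised over shuffles."""
    n_states = 3**k
    onehot = np.zeros((len(labels), n_states))
    onehot[np.arange(len(labels)), state] = 1.0
    perms = rng.permuted(np.tile(labels.astype(float), (n_perm, 1)), axis=1)
    case = perms @ onehot  # (n_perm, n_states) case counts per shuffle
    _, _, gains, _ = _ig_from_counts(case, total, k, hd)
    return gains


def info_gain_2(gA, gB, phen: Phenotype, snp_ids=("A", "B"),
                cfg: PermutationConfig | None = None) -> InteractionResult:
    """Two-way information gain IG(A;B;D) = I(AB;D) - I(A;D) - I(B;D).

    May be negative (redundant loci).  With a :class:`PermutationConfig`, a
    label-shuffle p-value is attached.
    """
    return _interaction([np.asarray(gA), np.asarray(gB)], phen, snp_ids, cfg)


def info_gain_3(gA, gB, gC, phen: Phenotype, snp_ids=("A", "B", "C"),
                cfg: PermutationConfig | None = None) -> InteractionResult:
    """Three-way gain: I(ABC;D) minus all main effects and pairwise gains."""
    return _interaction([np.asarray(gA), np.asarray(gB), np.asarray(gC)],
                        phen, snp_ids, cfg)


def permutation_test(statistic, phen: Phenotype, cfg: PermutationConfig):
    """Generic label-permutation test for any statistic of the phenotype.

    ``statistic`` is a callable taking a label vector; the observed value uses
    the true labels.  Returns ``(p_value, null_sample)`` where p counts
    strictly greater null values (report p = 0 as "< 1/n_permutations").
    """
    rng = np.random.default_rng(cfg.seed)
    observed = statistic(phen.labels)
    null = np.empty(cfg.n_permutations)
    labels = phen.labels.copy()
    for b in range(cfg.n_permutations):
        null[b] = statistic(rng.permutation(labels))
    p = float((null > observed).sum()) / cfg.n_permutations
    return p, null


def _scan(g: GenotypeMatrix, phen: Phenotype, order: int,
          cfg: PermutationConfig | None) -> list[InteractionResult]:
    if g.n_snps < order:
        raise ValueError(f"need at least {order} SNPs for an order-{order} scan")
    seeds = None
    if cfg is not None and cfg.n_permutations > 0:
        ss = np.random.SeedSequence(cfg.seed)
        n_combos = len(list(combinations(range(g.n_snps), order)))
        seeds = ss.generate_state(n_combos)  # fresh permutation stream per test
    results = []
    for t, combo in enumerate(combinations(range(g.n_snps), order)):
        cols = [g.genotypes[:, i] for i in combo]
        ids = tuple(g.snp_ids[i] for i in combo)
        sub_cfg = None
        if seeds is not None:
            sub_cfg = PermutationConfig(cfg.n_permutations, int(seeds[t]))
        results.append(_interaction(cols, phen, ids, sub_cfg))
    results.sort(key=lambda r: (-r.gain, r.snp_ids))
    return results


def pairwise_scan(g: GenotypeMatrix, phen: Phenotype,
                  cfg: PermutationConfig | None = None) -> list[InteractionResult]:
    """Two-way gains for all SNP pairs, sorted by gain descending."""
    return _scan(g, phen, 2, cfg)


def threeway_scan(g: GenotypeMatrix, phen: Phenotype,
                  cfg: PermutationConfig | None = None) -> list[InteractionResult]:
    """Three-way gains for all SNP trios, sorted by gain descending."""
    return _scan(g, phen, 3, cfg)


def results_to_tsv(results: list[InteractionResult], path) -> None:
    """Write scan results in a table mirroring the interaction report layout."""
    with open(path, "w") as fh:
        fh.write("snp_ids\tgain_bits\tgain_pct\tp_value\tp_value_add1\tn_permutations\n")
        for r in results:
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            p1 = "" if r.p_value_add1 is None else f"{r.p_value_add1:.6g}"
            fh.write(f"{','.join(r.snp_ids)}\t{r.gain:.10g}\t{r.gain_pct:.10g}"
                     f"\t{p}\t{p1}\t{r.n_permutations}\n")
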