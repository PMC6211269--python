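"""Interaction-sensitive SNP filtering: ReliefF, TuRF and the mean+3SD cut.

ReliefF weights each SNP by contrasting it between every sample and its k
nearest neighbours of the same class (hits) and the other class (misses):
an attribute that differs between a sample and its misses but agrees with its
hits is informative even when it has no marginal effect, which is what makes
the method sensitive to epistasis.  TuRF (Tuned ReliefF) iteratively re-runs
ReliefF, discarding a fixed fraction of the lowest-scoring SNPs each round so
that neighbourhoods are recomputed in an increasingly relevant feature space.

Neighbour search uses Manhattan distance on the genotype codes; the weight
update uses the 0/1 genotype mismatch.  All samples serve as reference
instances and neighbour ties break by sample index, so scores are fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .genotype import MISSING, GenotypeMatrix, Phenotype

__all__ = [
    "ReliefParams",
    "ImportanceTable",
    "relieff_scores",
    "turf_scores",
    "mean_sd_threshold",
]


@dataclass
class ReliefParams:
    """ReliefF/TuRF settings.

    k_neighbors        : hits and misses per reference sample (10)
    turf_iterations    : ReliefF rounds in the TuRF wrapper (10)
    turf_drop_fraction : fraction of lowest-scoring SNPs removed per round (0.1)
    sd_multiplier      : selection threshold mean + sd_multiplier * SD (3)
    """

    k_neighbors: int = 10
    turf_iterations: int = 10
    turf_drop_fraction: float = 0.1
    sd_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.turf_drop_fraction < 1.0:
            raise ValueError("turf_drop_fraction must be in (0, 1)")


@dataclass
class ImportanceTable:
    """Per-SNP scores from one ranking method, aligned with snp_ids."""

    snp_ids: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.snp_ids) != self.scores.shape[0]:
            raise ValueError("snp_ids and scores must align")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def ranking(self) -> list[str]:
        """SNP ids sorted by score descending (stable: ties keep input order)."""
        order = np.argsort(-self.scores, kind="stable")
        return [self.snp_ids[i] for i in order]

    def write(self, path) -> None:
        order = np.argsort(-self.scores, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        with open(path, "w") as fh:
            fh.write("snp_id\tscore\trank\tmethod\n")
            for i, sid in enumerate(self.snp_ids):
                fh.write(f"{sid}\t{self.scores[i]:.10g}\t{rank[i]}\t{self.method}\n")


def _check_input(g: GenotypeMatrix, phen: Phenotype) -> None:
    if (g.genotypes == MISSING).any():
        raise ValueError("ReliefF requires an imputed (no-missing) matrix")
    if not phen.both_classes_present():
        raise ValueError("both classes must be present")


def relieff_scores(g: GenotypeMatrix, phen: Phenotype,
                   params: ReliefParams | None = None) -> ImportanceTable:
    """ReliefF attribute weights for every SNP; scores lie in [-1, 1].

    Every sample is a reference instance (m = n).  If a class has too few
    members, k is reduced to class size - 1 with a warning.
    """
    if params is None:
        params = ReliefParams()
    _check_input(g, phen)
    X = g.genotypes.astype(np.float64)
    y = phen.labels
    n, p = X.shape
    min_class = int(min((y == 0).sum(), (y == 1).sum()))
    k = params.k_neighbors
    if min_class <= k:
        k = min_class - 1
        warnings.warn(f"class size too small for k={params.k_neighbors}; using k={k}")
    if k < 1:
        raise ValueError("need at least 2 samples per class for ReliefF")

    dist = cdist(X, X, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    idx = np.arange(n)
    weights = np.zeros(p)
    Xi8 = g.genotypes  # int8 view for mismatch counting
    for i in range(n):
        same = idx[(y == y[i]) & (idx != i)]
        other = idx[y != y[i]]
        # ties break by sample index: lexsort secondary key is the index itself
        hits = same[np.lexsort((same, dist[i, same]))[:k]]
        misses = other[np.lexsort((other, dist[i, other]))[:k]]
        weights -= (Xi8[hits] != Xi8[i]).sum(axis=0)
        weights += (Xi8[misses] != Xi8[i]).sum(axis=0)
    weights /= n * k
    return ImportanceTable(list(g.snp_ids), weights, method="relieff")


def turf_scores(g: GenotypeMatrix, phen: Phenotype,
                params: ReliefParams | None = None) -> ImportanceTable:
    """TuRF: iterated ReliefF with per-round removal of the worst SNPs.

    Survivors keep their final-round ReliefF score.  Removed SNPs receive
    rank-preserving scores strictly below every survivor, ordered first by
    removal round (later rounds rank higher) and within a round by their
    score at removal; per-round ties break by input order.
    """
    if params is None:
        params = ReliefParams()
    _check_input(g, phen)

    surviving = np.arange(g.n_snps)
    removed_rounds: list[tuple[np.ndarray, np.ndarray]] = []  # (indices, scores)
    last_scores = None
    for _ in range(params.turf_iterations):
        sub = g.take_snps(surviving)
        table = relieff_scores(sub, phen, params)
        last_scores = table.scores
        # at least one SNP leaves per round so small panels still shrink
        n_drop = max(1, int(np.floor(params.turf_drop_fraction * surviving.size)))
        if n_drop >= surviving.size:
            warnings.warn("TuRF stopped early: removal would empty the SNP set")
            break
        order = np.argsort(table.scores, kind="stable")  # ties keep input order
        drop_local = order[:n_drop]
        keep_local = np.setdiff1d(np.arange(surviving.size), drop_local)
        removed_rounds.append((surviving[drop_local], table.scores[drop_local]))
        surviving = surviving[keep_local]
        last_scores = table.scores[keep_local]

    final = np.empty(g.n_snps)
    final[surviving] = last_scores
    floor = float(last_scores.min())
    span = max(1e-6, float(np.ptp(last_scores)) or 1.0)
    # removed SNPs: later rounds outrank earlier rounds; within a round order
    # by removal-time score descending, all strictly below every survivor
    offset = 1
    for round_idx, (snp_idx, scores) in enumerate(reversed(removed_rounds)):
        order = np.argsort(-scores, kind="stable")
        for rank_in_round, local in enumerate(order):
            final[snp_idx[local]] = floor - span * 1e-3 * offset
            offset += 1
    return ImportanceTable(list(g.snp_ids), final, method="turf")


def turf_survivors(table: ImportanceTable, g: GenotypeMatrix,
                   params: ReliefParams) -> list[str]:
    """SNP ids surviving all TuRF rounds implied by the params (bookkeeping helper)."""
    n = g.n_snps
    for _ in range(params.turf_iterations):
        n -= int(np.floor(params.turf_drop_fraction * n))
    return table.ranking()[:n]


def mean_sd_threshold(table: ImportanceTable, sd_multiplier: float = 3.0) -> set[str]:
    """SNPs whose score exceeds mean + sd_multiplier * sample-SD of all scores.

    With constant scores (SD = 0) the selection is empty and a warning is
    issued.  Selection is strict (score > threshold).
    """
    s = table.scores
    if s.size < 2:
        raise ValueError("need at least two scores")
    sd = s.std(ddof=1)
    if sd == 0:
        warnings.warn("score SD is zero; mean+SD threshold selects nothing")
        return set()
    cut = s.mean() + sd_multiplier * sd
    return {table.snp_ids[i] for i in np.flatnonzero(s > cut)}
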