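"""Case-control genotype simulation driven by penetrance tables.

Emulates the statistical structure of a balanced GWAS cohort: biallelic SNPs
drawn under Hardy-Weinberg proportions with minor allele frequencies from a
chosen range, optional LD blocks and missingness, and disease status produced
by rejection sampling against user-specified penetrance models over 1-3
functional loci.  Pure-epistasis benchmarks (two-locus XOR, three-locus
parity) are provided as ready-made penetrance constructors: at MAF 0.5 their
lower-order marginal effects vanish exactly, so only the joint genotype
carries disease information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype import MISSING, GenotypeMatrix, Phenotype

__all__ = [
    "PenetranceModel",
    "SimConfig",
    "TruthRecord",
    "SimulationError",
    "xor_penetrance",
    "parity3_penetrance",
    "simulate",
    "inject_missing",
]


class SimulationError(RuntimeError):
    """Raised when a configuration cannot produce the requested cohort."""


@dataclass
class PenetranceModel:
    """Maps each multi-locus genotype combination to P(case | combination).

    ``loci`` are the functional SNP column indices (1-3 of them); ``table``
    has shape ``(3,) * len(loci)`` and entries in [0, 1], indexed by the
    genotype codes of the loci in order.
    """

    loci: tuple[int, ...]
    table: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.loci = tuple(int(i) for i in self.loci)
        if not 1 <= len(self.loci) <= 3:
            raise ValueError("a penetrance model uses 1-3 loci")
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3,) * len(self.loci):
            raise ValueError(f"table must have shape {(3,) * len(self.loci)}")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrances must be in [0, 1]")

    def penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        """P(case) for each row of a (n, n_snps) genotype matrix."""
        idx = tuple(genotypes[:, i] for i in self.loci)
        return self.table[idx]


def xor_penetrance(h: float, loci: tuple[int, int] = (0, 1)) -> PenetranceModel:
    """Two-locus parity (XOR) model: P(case) = 0.5 + h if g1+g2 is odd, else 0.5 - h.

    At MAF 0.5 each locus's marginal penetrance is exactly 0.5, so the pair
    shows no single-SNP association yet jointly determines disease risk —
    the canonical pure-epistasis benchmark.  ``h`` in [0, 0.5].
    """
    if not 0.0 <= h <= 0.5:
        raise ValueError("baseline shift h must be in [0, 0.5]")
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    table = np.where((g1 + g2) % 2 == 1, 0.5 + h, 0.5 - h)
    return PenetranceModel(tuple(loci), table, name="xor")


def parity3_penetrance(h: float, loci: tuple[int, int, int] = (0, 1, 2)) -> PenetranceModel:
    """Three-locus parity model; all one- and two-locus marginals flat at MAF 0.5."""
    if not 0.0 <= h <= 0.5:
        raise ValueError("baseline shift h must be in [0, 0.5]")
    g1, g2, g3 = np.meshgrid(np.arange(3), np.arange(3), np.arange(3), indexing="ij")
    table = np.where((g1 + g2 + g3) % 2 == 1, 0.5 + h, 0.5 - h)
    return PenetranceModel(tuple(loci), table, name="parity3")


@dataclass
class SimConfig:
    """Study design for one simulated cohort.

    Defaults mirror a balanced 472/472 case-control cohort.  ``maf_range``
    bounds the uniform MAF draw for background SNPs; ``functional_maf``
    optionally pins the functional loci to a fixed MAF (0.5 makes the parity
    models purely epistatic).  ``ld_block_spec`` is a list of
    ``(block_size, target_r2)`` pairs realised by copy-with-mutation among
    background SNPs.
    """

    n_cases: int = 472
    n_controls: int = 472
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    models: list[PenetranceModel] = field(default_factory=list)
    functional_maf: float | None = None
    missing_rate: float = 0.0
    ld_block_spec: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        used: set[int] = set()
        for m in self.models:
            for i in m.loci:
                if i >= self.n_snps:
                    raise ValueError(f"functional locus {i} >= n_snps")
                if i in used:
                    raise ValueError(f"locus {i} used by more than one model")
                used.add(i)
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth for a simulated dataset: which loci carry signal."""

    functional_loci: list[int]
    model_names: list[str]
    model_loci: list[tuple[int, ...]]
    ld_blocks: list[list[int]] = field(default_factory=list)
    seed: int = 0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed\t{self.seed}\n")
            fh.write("functional_loci\t" + ",".join(map(str, self.functional_loci)) + "\n")
            for name, loci in zip(self.model_names, self.model_loci):
                fh.write(f"model\t{name}\t" + ",".join(map(str, loci)) + "\n")
            for block in self.ld_blocks:
                fh.write("ld_block\t" + ",".join(map(str, block)) + "\n")


def _draw_hwe_genotypes(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    """Draw (n, n_snps) genotypes as two independent Bernoulli(maf) alleles."""
    a1 = rng.random((n, maf.size)) < maf
    a2 = rng.random((n, maf.size)) < maf
    return (a1.astype(np.int8) + a2.astype(np.int8))


def _case_probability(models: list[PenetranceModel], genotypes: np.ndarray) -> np.ndarray:
    # Multiple models on disjoint loci combine as independent risks.
    p_not = np.ones(genotypes.shape[0])
    for m in models:
        p_not *= 1.0 - m.penetrance(genotypes)
    return 1.0 - p_not


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, Phenotype, TruthRecord]:
    """Simulate a case-control cohort under ``cfg``; seed-deterministic.

    Status is assigned by rejection sampling: draw a full genotype vector,
    draw case with its penetrance probability, and accept it into whichever
    quota (case/control) is still open.  This honours arbitrary penetrance
    tables exactly with no prevalence calibration.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_snps)
    functional = sorted(i for m in cfg.models for i in m.loci)
    if cfg.functional_maf is not None:
        maf[functional] = cfg.functional_maf

    # LD blocks occupy contiguous runs of background SNPs following their seed
    # SNP; functional loci are excluded so planted truth stays unambiguous.
    blocks: list[list[int]] = []
    flip_probs: list[float] = []
    free = [j for j in range(cfg.n_snps) if j not in set(functional)]
    cursor = 0
    for size, r2 in cfg.ld_block_spec:
        if cursor + size > len(free):
            raise SimulationError("ld_block_spec does not fit among background SNPs")
        members = free[cursor : cursor + size]
        cursor += size
        blocks.append(members)
        # copy-with-resample: corr = 1 - flip, so r^2 = (1 - flip)^2
        flip_probs.append(1.0 - float(np.sqrt(max(0.0, min(1.0, r2)))))
        maf[members] = maf[members[0]]  # shared MAF within a block

    n_total = cfg.n_cases + cfg.n_controls
    if not cfg.models:
        geno = _draw_hwe_genotypes(rng, maf, n_total)
        labels = np.zeros(n_total, dtype=np.int8)
        labels[: cfg.n_cases] = 1
        labels = rng.permutation(labels)
    else:
        geno_rows: list[np.ndarray] = []
        labels_list: list[int] = []
        cases = controls = 0
        max_batches = 2000
        batch = max(256, n_total)
        for _ in range(max_batches):
            if cases >= cfg.n_cases and controls >= cfg.n_controls:
                break
            cand = _draw_hwe_genotypes(rng, maf, batch)
            p_case = _case_probability(cfg.models, cand)
            is_case = rng.random(batch) < p_case
            for i in range(batch):
                if is_case[i] and cases < cfg.n_cases:
                    geno_rows.append(cand[i])
                    labels_list.append(1)
                    cases += 1
                elif not is_case[i] and controls < cfg.n_controls:
                    geno_rows.append(cand[i])
                    labels_list.append(0)
                    controls += 1
                if cases >= cfg.n_cases and controls >= cfg.n_controls:
                    break
        else:
            raise SimulationError(
                "rejection sampling could not fill the case/control quotas; "
                "check the penetrance table for degenerate probabilities"
            )
        geno = np.vstack(geno_rows)
        labels = np.array(labels_list, dtype=np.int8)
        order = rng.permutation(n_total)
        geno = geno[order]
        labels = labels[order]

    # apply LD block structure after sampling: members copy the block seed SNP
    # with per-genotype resampling to a fresh HWE draw
    for members, flip in zip(blocks, flip_probs):
        seed_col = geno[:, members[0]]
        for j in members[1:]:
            fresh = _draw_hwe_genotypes(rng, np.array([maf[j]]), n_total)[:, 0]
            mask = rng.random(n_total) < flip
            geno[:, j] = np.where(mask, fresh, seed_col)

    snp_ids = [f"snp{j:05d}" for j in range(cfg.n_snps)]
    sample_ids = [f"s{i:05d}" for i in range(n_total)]
    g = GenotypeMatrix(
        geno, snp_ids, sample_ids,
        chrom=np.array(["1"] * cfg.n_snps),
        pos=np.arange(1, cfg.n_snps + 1, dtype=np.int64) * 1000,
    )
    if cfg.missing_rate > 0:
        g = inject_missing(g, cfg.missing_rate, seed=int(rng.integers(2**31)))
    truth = TruthRecord(
        functional_loci=functional,
        model_names=[m.name for m in cfg.models],
        model_loci=[m.loci for m in cfg.models],
        ld_blocks=blocks,
        seed=cfg.seed,
    )
    return g, Phenotype(labels), truth


def inject_missing(g: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each genotype entry to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    geno = g.genotypes.copy()
    mask = rng.random(geno.shape) < rate
    geno[mask] = MISSING
    return GenotypeMatrix(geno, list(g.snp_ids), list(g.sample_ids),
                          chrom=g.chrom, pos=g.pos)
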