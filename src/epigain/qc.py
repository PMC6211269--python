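"""Per-sample and per-marker quality control for case-control genotype data.

The pipeline applies, in order: sample missingness and heterozygosity-outlier
removal, then SNP missingness, minor-allele-frequency and Hardy-Weinberg
filters, greedy LD pruning, and mode imputation of remaining missing calls.
A per-SNP chi-square association test on the genotype x status table is
provided for ranking context.

The Hardy-Weinberg filter removes SNPs with HWE chi-square p < ``hwe_alpha``
(the standard PLINK convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .genotype import MISSING, GenotypeMatrix, Phenotype

__all__ = [
    "QCParams",
    "QCReport",
    "QCError",
    "sample_missingness",
    "heterozygosity",
    "heterozygosity_outliers",
    "snp_missingness",
    "snp_missingness_filter",
    "snp_maf",
    "maf_filter",
    "hwe_test",
    "hwe_filter",
    "ld_r2",
    "ld_prune",
    "impute_mode",
    "run_qc",
    "single_snp_association",
]


class QCError(RuntimeError):
    """Raised when QC cannot produce a usable dataset (e.g. empties the matrix)."""


@dataclass
class QCParams:
    """Thresholds for the QC pipeline; defaults follow common GWAS practice.

    sample_missing_max : max fraction of missing genotypes per sample (0.01)
    het_sd             : SD multiplier flagging heterozygosity outliers (3)
    snp_missing_max    : max missing call rate per SNP (0.05)
    maf_min            : minimum minor allele frequency (0.05)
    hwe_alpha          : remove SNPs with HWE chi-square p below this (1e-4)
    ld_r2_max          : prune a SNP whose r^2 with a retained SNP exceeds this (0.6)
    ld_window          : number of previously retained SNPs scanned for LD (2000)
    """

    sample_missing_max: float = 0.01
    het_sd: float = 3.0
    snp_missing_max: float = 0.05
    maf_min: float = 0.05
    hwe_alpha: float = 1e-4
    ld_r2_max: float = 0.6
    ld_window: int = 2000

    def __post_init__(self) -> None:
        for name in ("sample_missing_max", "snp_missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ld_window < 2:
            raise ValueError("ld_window must be >= 2")


@dataclass
class QCReport:
    """Counts of samples/SNPs removed by each filter, in application order."""

    samples_removed_missing: int = 0
    samples_removed_het: int = 0
    snps_removed_missing: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    snps_removed_ld: int = 0
    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    params: dict = field(default_factory=dict)

    def check_consistent(self) -> None:
        assert (self.n_samples_in - self.samples_removed_missing
                - self.samples_removed_het) == self.n_samples_out
        assert (self.n_snps_in - self.snps_removed_missing - self.snps_removed_maf
                - self.snps_removed_hwe - self.snps_removed_ld) == self.n_snps_out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                if k == "params":
                    for pk, pv in v.items():
                        fh.write(f"param.{pk}\t{pv}\n")
                else:
                    fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# Per-sample statistics


def sample_missingness(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of missing genotype calls per sample."""
    if g.n_snps < 1:
        raise ValueError("need at least one SNP")
    return (g.genotypes == MISSING).mean(axis=1)


def heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Per-sample heterozygous fraction among non-missing calls (NaN if none)."""
    miss = g.genotypes == MISSING
    n_obs = (~miss).sum(axis=1)
    n_het = (g.genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, n_het / n_obs, np.nan)


def heterozygosity_outliers(g: GenotypeMatrix, het_sd: float = 3.0) -> np.ndarray:
    """Flag samples whose heterozygosity deviates > het_sd sample-SDs from the mean.

    Samples with no non-missing genotypes are excluded from the mean/SD and
    flagged as outliers.  If the SD is zero no sample is an outlier.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    h = heterozygosity(g)
    valid = ~np.isnan(h)
    out = ~valid  # all-missing samples flagged
    hv = h[valid]
    if hv.size >= 2:
        sd = hv.std(ddof=1)
        if sd > 0:
            out[valid] = np.abs(hv - hv.mean()) > het_sd * sd
    return out


# ---------------------------------------------------------------------------
# Per-SNP statistics


def snp_missingness(g: GenotypeMatrix) -> np.ndarray:
    return (g.genotypes == MISSING).mean(axis=0)


def snp_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over non-missing genotypes (NaN if all missing)."""
    miss = g.genotypes == MISSING
    n_obs = (~miss).sum(axis=0)
    dosage = np.where(miss, 0, g.genotypes).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, dosage / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


def snp_missingness_filter(g: GenotypeMatrix, params: QCParams) -> np.ndarray:
    """Indices of SNPs with missing call rate <= snp_missing_max."""
    return np.flatnonzero(snp_missingness(g) <= params.snp_missing_max)


def maf_filter(g: GenotypeMatrix, params: QCParams) -> np.ndarray:
    """Indices of SNPs with MAF >= maf_min (all-missing SNPs removed)."""
    maf = snp_maf(g)
    keep = np.where(np.isnan(maf), False, maf >= params.maf_min)
    return np.flatnonzero(keep)


def hwe_test(counts) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg proportions.

    ``counts`` is the genotype count triple (n0, n1, n2).  The allele frequency
    is estimated from the counts; a monomorphic SNP returns p = 1 by convention.
    """
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("empty genotype counts")
    p = (2 * n0 + n1) / (2.0 * n)  # frequency of the allele counted as 0
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_filter(g: GenotypeMatrix, params: QCParams) -> np.ndarray:
    """Indices of SNPs whose HWE test p-value is >= hwe_alpha."""
    keep = []
    for j in range(g.n_snps):
        col = g.genotypes[:, j]
        col = col[col != MISSING]
        counts = np.bincount(col, minlength=3)[:3]
        if hwe_test(counts) >= params.hwe_alpha:
            keep.append(j)
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# LD pruning


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype columns over complete pairs.

    Returns 0 when either column is constant or fewer than two complete pairs
    exist (such a pair cannot justify pruning).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(g: GenotypeMatrix, params: QCParams) -> np.ndarray:
    """Greedy keep-first LD pruning; returns surviving SNP indices.

    SNPs are scanned left to right (input order, assumed sorted by chromosome
    and position when available).  A SNP is dropped when its r^2 with any of
    the previous ``ld_window`` retained SNPs on the same chromosome exceeds
    ``ld_r2_max``.  Deterministic for a fixed input order.
    """
    chrom = g.chrom if g.chrom is not None else np.zeros(g.n_snps, dtype=int)
    kept: list[int] = []
    for j in range(g.n_snps):
        window = [i for i in kept[-params.ld_window:] if chrom[i] == chrom[j]]
        col = g.genotypes[:, j]
        if any(ld_r2(g.genotypes[:, i], col) > params.ld_r2_max for i in reversed(window)):
            continue
        kept.append(j)
    return np.asarray(kept, dtype=int)


# ---------------------------------------------------------------------------
# Imputation


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by that SNP's most frequent genotype code.

    Ties break toward the smaller code.  Raises if a SNP is entirely missing
    (filter such SNPs first).
    """
    geno = g.genotypes.copy()
    for j in range(g.n_snps):
        col = geno[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise QCError(
                f"SNP {g.snp_ids[j]} has no observed genotypes; "
                "apply missingness filtering before imputation"
            )
        counts = np.bincount(obs, minlength=3)[:3]
        mode = int(np.argmax(counts))  # argmax takes the smallest index on ties
        col[miss] = mode
    return GenotypeMatrix(geno, list(g.snp_ids), list(g.sample_ids),
                          chrom=g.chrom, pos=g.pos)


# ---------------------------------------------------------------------------
# Full pipeline


def run_qc(
    g: GenotypeMatrix, phen: Phenotype, params: QCParams | None = None
) -> tuple[GenotypeMatrix, Phenotype, QCReport]:
    """Apply the full QC sequence and return the cleaned data plus a report.

    Order: sample missingness -> heterozygosity outliers -> SNP missingness
    -> MAF -> HWE -> LD pruning -> mode imputation.  Raises :class:`QCError`
    if the output would be empty or single-class.
    """
    if params is None:
        params = QCParams()
    report = QCReport(n_samples_in=g.n_samples, n_snps_in=g.n_snps,
                      params=asdict(params))

    # sample filters
    keep_s = np.flatnonzero(sample_missingness(g) <= params.sample_missing_max)
    report.samples_removed_missing = g.n_samples - keep_s.size
    g = g.take_samples(keep_s)
    phen = phen.take(keep_s)
    if g.n_samples == 0:
        raise QCError("sample missingness filter removed all samples")

    out = heterozygosity_outliers(g, params.het_sd)
    keep_s = np.flatnonzero(~out)
    report.samples_removed_het = int(out.sum())
    g = g.take_samples(keep_s)
    phen = phen.take(keep_s)
    if not phen.both_classes_present():
        raise QCError("phenotype became single-class after sample filters")

    # marker filters
    keep = snp_missingness_filter(g, params)
    report.snps_removed_missing = g.n_snps - keep.size
    g = g.take_snps(keep)

    keep = maf_filter(g, params)
    report.snps_removed_maf = g.n_snps - keep.size
    g = g.take_snps(keep)

    keep = hwe_filter(g, params)
    report.snps_removed_hwe = g.n_snps - keep.size
    g = g.take_snps(keep)

    keep = ld_prune(g, params)
    report.snps_removed_ld = g.n_snps - keep.size
    g = g.take_snps(keep)

    if g.n_snps == 0:
        raise QCError("QC removed all SNPs; loosen thresholds")

    g = impute_mode(g)
    report.n_samples_out = g.n_samples
    report.n_snps_out = g.n_snps
    report.check_consistent()
    return g, phen, report


# ---------------------------------------------------------------------------
# Single-SNP association


def single_snp_association(g: GenotypeMatrix, phen: Phenotype) -> np.ndarray:
    """Chi-square p-value per SNP from the genotype x case/control table.

    Degrees of freedom are (observed genotype classes - 1); monomorphic SNPs
    get p = 1.  Expects an imputed (no-missing) matrix.
    """
    if (g.genotypes == MISSING).any():
        raise ValueError("association test expects an imputed matrix")
    y = phen.labels
    pvals = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = g.genotypes[:, j]
        table = np.array(
            [[np.sum((col == v) & (y == 0)), np.sum((col == v) & (y == 1))]
             for v in (0, 1, 2)]
        )
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        pvals[j] = p
    return pvals
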