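"""Genotype containers and text-format I/O for case-control SNP data.

Genotypes are coded by minor-allele dosage: 0 homozygous reference,
1 heterozygous, 2 homozygous variant, -1 missing.  Two plain-text
dialects are supported: PLINK PED/MAP and a TSV genotype matrix with a
``sample_id<TAB>phenotype<TAB><snp>...`` header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "Phenotype",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line/SNP."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs integer genotype codes plus SNP/sample metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` integer array with entries in {-1, 0, 1, 2}.
    snp_ids
        Unique SNP identifiers, one per column.
    sample_ids
        Sample identifiers, one per row.
    chrom, pos
        Optional per-SNP chromosome labels and base-pair positions; required
        only for chromosome-aware LD pruning.
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x SNPs array")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError("snp_ids length does not match genotype columns")
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        for name in ("chrom", "pos"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != self.genotypes.shape[1]:
                    raise ValueError(f"{name} length does not match n_snps")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def take_snps(self, idx) -> "GenotypeMatrix":
        """Subset to the SNP columns in ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        """Subset to the sample rows in ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            genotypes=self.genotypes[idx, :],
            snp_ids=list(self.snp_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
        )


@dataclass
class Phenotype:
    """Binary disease status vector: 1 = case, 0 = control."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def both_classes_present(self) -> bool:
        return 0 < self.labels.sum() < self.n

    def take(self, idx) -> "Phenotype":
        return Phenotype(self.labels[np.asarray(idx, dtype=int)])


# ---------------------------------------------------------------------------
# TSV dialect


def _read_tsv(path: Path) -> tuple[GenotypeMatrix, Phenotype]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
            raise GenotypeParseError(
                f"{path}: line 1: expected header 'sample_id\\tphenotype\\t<snp ids>'"
            )
        snp_ids = header[2:]
        sample_ids: list[str] = []
        labels: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            try:
                labels.append(int(parts[1]))
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: phenotype must be 0 or 1"
                ) from None
            row = []
            for cell in parts[2:]:
                if cell == "NA":
                    row.append(MISSING)
                elif cell in ("0", "1", "2"):
                    row.append(int(cell))
                else:
                    raise GenotypeParseError(
                        f"{path}: line {lineno}: invalid genotype cell {cell!r}"
                    )
            rows.append(row)
    g = GenotypeMatrix(np.array(rows, dtype=np.int8).reshape(len(rows), len(snp_ids)),
                       snp_ids, sample_ids)
    return g, Phenotype(np.array(labels))


def _write_tsv(g: GenotypeMatrix, phen: Phenotype, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(g.snp_ids) + "\n")
        for i, sid in enumerate(g.sample_ids):
            cells = ["NA" if v == MISSING else str(int(v)) for v in g.genotypes[i]]
            fh.write(f"{sid}\t{int(phen.labels[i])}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# PLINK PED/MAP dialect


def _read_ped_map(prefix: Path) -> tuple[GenotypeMatrix, Phenotype]:
    map_path = Path(str(prefix) + ".map")
    ped_path = Path(str(prefix) + ".ped")
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}: line {lineno}: expected 4 fields")
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            try:
                pos.append(int(parts[3]))
            except ValueError:
                raise GenotypeParseError(
                    f"{map_path}: line {lineno}: position must be an integer"
                ) from None
    n_snps = len(snp_ids)

    sample_ids: list[str] = []
    labels: list[int] = []
    allele_rows: list[list[str]] = []  # 2 alleles per SNP, "0" = missing
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            if parts[5] == "1":
                labels.append(0)
            elif parts[5] == "2":
                labels.append(1)
            else:
                raise GenotypeParseError(
                    f"{ped_path}: line {lineno}: phenotype must be 1 (control) or 2 (case)"
                )
            allele_rows.append(parts[6:])

    n = len(sample_ids)
    geno = np.full((n, n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        alleles = sorted(set(a for a in a1 + a2 if a != "0"))
        if len(alleles) > 2:
            raise GenotypeParseError(
                f"{ped_path}: SNP {snp_ids[j]} is not biallelic (alleles {alleles})"
            )
        for i in range(n):
            if (a1[i] == "0") != (a2[i] == "0"):
                raise GenotypeParseError(
                    f"{ped_path}: line {i + 1}: half-missing genotype at SNP {snp_ids[j]}"
                )
        if not alleles:
            continue  # all missing: leave as -1
        # Counted allele is the within-file minor allele; ties break to the
        # lexicographically smaller symbol.
        counts = {a: 0 for a in alleles}
        for i in range(n):
            if a1[i] != "0":
                counts[a1[i]] += 1
                counts[a2[i]] += 1
        minor = min(alleles, key=lambda a: (counts[a], a))
        for i in range(n):
            if a1[i] == "0":
                continue
            geno[i, j] = (a1[i] == minor) + (a2[i] == minor)

    g = GenotypeMatrix(geno, snp_ids, sample_ids,
                       chrom=np.array(chrom), pos=np.array(pos, dtype=np.int64))
    return g, Phenotype(np.array(labels))


_PED_ALLELES = {0: ("A", "A"), 1: ("A", "G"), 2: ("G", "G"), MISSING: ("0", "0")}


def _write_ped_map(g: GenotypeMatrix, phen: Phenotype, prefix: Path) -> None:
    chrom = g.chrom if g.chrom is not None else np.array(["1"] * g.n_snps)
    pos = g.pos if g.pos is not None else np.arange(1, g.n_snps + 1) * 1000
    with open(str(prefix) + ".map", "w") as fh:
        for j, sid in enumerate(g.snp_ids):
            fh.write(f"{chrom[j]}\t{sid}\t0\t{int(pos[j])}\n")
    with open(str(prefix) + ".ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            status = "2" if phen.labels[i] == 1 else "1"
            fields = [sid, sid, "0", "0", "0", status]
            for v in g.genotypes[i]:
                fields.extend(_PED_ALLELES[int(v)])
            fh.write(" ".join(fields) + "\n")


def read_genotypes(path, format: str = "tsv") -> tuple[GenotypeMatrix, Phenotype]:
    """Read a genotype matrix and phenotype from disk.

    ``format='tsv'`` expects a single TSV file; ``format='ped_map'`` expects
    ``path`` to be a prefix with ``.ped`` and ``.map`` alongside.  For PED
    input the counted allele of each SNP is the minor allele within the file
    (ties toward the lexicographically smaller symbol).
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "ped_map":
        return _read_ped_map(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(g: GenotypeMatrix, phen: Phenotype, path, format: str = "tsv") -> None:
    """Write genotypes in the named dialect; inverse of :func:`read_genotypes`.

    PED output encodes dosage with synthetic alleles (G minor, A reference),
    so a write/read round-trip preserves the {0,1,2} codes whenever the minor
    allele is actually minor in the file.
    """
    path = Path(path)
    if format == "tsv":
        _write_tsv(g, phen, path)
    elif format == "ped_map":
        _write_ped_map(g, phen, path)
    else:
        raise ValueError(f"unknown format {format!r}")
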