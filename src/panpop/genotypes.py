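"""Bi-allelic genotype matrices.

The central in-memory container for SNP data: a samples x SNPs dosage matrix
(count of alternate alleles, 0/1/2, with -1 for a missing call) plus 1-based
positions and chromosome labels.  All downstream statistics (SNP-set filters,
distances, nucleotide diversity, LD, introgression distances) operate on this
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x bi-allelic SNPs dosage matrix.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    chrom, pos
        Per-SNP chromosome label and 1-based position.  Positions must be
        strictly increasing within each chromosome.
    ref, alt
        Reference / alternate allele labels (single bases by convention).
    dosage
        ``(n_samples, n_snps)`` int8 array in ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == m):
            raise ValueError("per-SNP arrays do not match dosage columns")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, -1}")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic shape ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    # -- per-SNP summaries ---------------------------------------------------
    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as ``dosage``."""
        return self.dosage != MISSING

    def n_called(self) -> np.ndarray:
        """Number of called samples per SNP."""
        return self.called_mask().sum(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency among called alleles (NaN if none called)."""
        called = self.called_mask()
        n = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency among called alleles."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return 1.0 - self.n_called() / self.n_samples

    def het_counts(self) -> np.ndarray:
        """Number of heterozygous calls per SNP."""
        return (self.dosage == 1).sum(axis=0)

    # -- subsetting ----------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[index, :],
        )

    def samples_by_id(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples([lookup[s] for s in ids])

    # -- I/O -----------------------------------------------------------------
    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal bi-allelic VCF (GT field only, 1-based positions)."""
        path = Path(path)
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with path.open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=panpop\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in dict.fromkeys(self.chrom):
                length = int(self.pos[self.chrom == c].max())
                fh.write(f"##contig=<ID={c},length={length}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            for j in range(self.n_snps):
                gts = "\t".join(gt_map[int(d)] for d in self.dosage[:, j])
                fh.write(
                    f"{self.chrom[j]}\t{self.pos[j]}\t.\t{self.ref[j]}\t"
                    f"{self.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read bi-allelic SNP records from a VCF via cyvcf2.

        Multi-allelic records and records with symbolic alternates are skipped.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        sample_ids = list(vcf.samples)
        chrom, pos, ref, alt, rows = [], [], [], [], []
        for var in vcf:
            if len(var.ALT) != 1 or var.ALT[0].startswith("<"):
                continue
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0])
            # gts012: 0/1/2 dosage, 3 = unknown
            g = np.asarray(var.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            rows.append(g)
        dosage = (
            np.stack(rows, axis=1)
            if rows
            else np.empty((len(sample_ids), 0), dtype=np.int8)
        )
        return cls(
            sample_ids=sample_ids,
            chrom=np.asarray(chrom, dtype=object),
            pos=np.asarray(pos, dtype=np.int64),
            ref=np.asarray(ref, dtype=object),
            alt=np.asarray(alt, dtype=object),
            dosage=dosage,
        )
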