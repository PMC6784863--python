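"""Shared helpers for constructing tiny genotype fixtures."""

from __future__ import annotations

import numpy as np

from panpop.genotypes import GenotypeMatrix


def make_gm(
    dosage,
    pos=None,
    chrom=None,
    sample_ids=None,
) -> GenotypeMatrix:
    """GenotypeMatrix from a (samples x SNPs) dosage array with defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if chrom is None:
        chrom = ["chr1"] * m
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * m, dtype=object),
        alt=np.asarray(["T"] * m, dtype=object),
        dosage=dosage,
    )


def random_gm(rng: np.random.Generator, n=20, m=50, missing=0.1) -> GenotypeMatrix:
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing
    dosage[mask] = -1
    return make_gm(dosage)
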