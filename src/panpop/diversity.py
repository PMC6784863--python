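"""Diversity summaries: windowed π, LD decay, private alleles, doubletons.

Nucleotide diversity per site is the unbiased heterozygosity
(n/(n−1))·2p(1−p) over called alleles, summed within non-overlapping windows
and divided by the window width (an all-bases denominator; a called-sites
denominator is available via ``denominator="sites"``).  LD decay bins squared
dosage correlations of SNP pairs by physical distance (1-kb bins), takes the
per-chromosome bin median and averages medians across chromosomes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .groups import MAJOR_GROUP_OF, SubpopAssignment
from .snpsets import UndefinedR2, pairwise_r2


def per_site_pi(g: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site diversity (n/(n−1))·2p(1−p); 0 where n < 2 alleles."""
    called = g.dosage != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
        pi = np.where(
            n_alleles >= 2,
            n_alleles / np.maximum(n_alleles - 1, 1) * 2.0 * p * (1.0 - p),
            0.0,
        )
    return np.nan_to_num(pi)


def pi_windows(
    g: GenotypeMatrix,
    samples: list[str] | None = None,
    width: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    denominator: str = "width",
) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows of ``width`` bp.

    Returns a BED-like frame (chrom, start, end, pi, n_sites) with 0-based
    half-open window coordinates.  Windows with no called site get π = 0 and
    n_sites = 0.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if denominator not in ("width", "sites"):
        raise ValueError("denominator must be 'width' or 'sites'")
    if samples is not None:
        g = g.samples_by_id(samples)
    pi_site = per_site_pi(g)
    rows = []
    for c in dict.fromkeys(g.chrom):
        on_c = g.chrom == c
        pos0 = g.pos[on_c] - 1  # 0-based
        pis = pi_site[on_c]
        length = (
            chrom_lengths[c]
            if chrom_lengths is not None
            else int(g.pos[on_c].max())
        )
        n_win = int(np.ceil(length / width))
        win_idx = pos0 // width
        for w in range(n_win):
            sel = win_idx == w
            n_sites = int(sel.sum())
            total = float(pis[sel].sum())
            denom = width if denominator == "width" else max(n_sites, 1)
            rows.append(
                {
                    "chrom": c,
                    "start": w * width,
                    "end": min((w + 1) * width, length),
                    "pi": total / denom if n_sites else 0.0,
                    "n_sites": n_sites,
                }
            )
    return pd.DataFrame(rows)


def ld_decay(
    g: GenotypeMatrix,
    samples: list[str] | None = None,
    maf_min: float = 0.10,
    max_dist: int = 300_000,
    bin_bp: int = 1_000,
) -> pd.DataFrame:
    """r² decay profile: 1-kb distance bins, per-chromosome medians averaged.

    Only SNPs with subset MAF ≥ ``maf_min`` enter; pairs farther apart than
    ``max_dist`` or at identical positions are excluded.  Empty bins are NaN.
    """
    if samples is not None:
        g = g.samples_by_id(samples)
    keep = np.nan_to_num(g.maf()) >= maf_min
    g = g.take_snps(keep)
    n_bins = int(np.ceil(max_dist / bin_bp))
    per_chrom: list[np.ndarray] = []
    for c in dict.fromkeys(g.chrom):
        idx = np.flatnonzero(g.chrom == c)
        pos = g.pos[idx]
        bins: list[list[float]] = [[] for _ in range(n_bins)]
        for a, b in combinations(range(len(idx)), 2):
            dist = abs(int(pos[b]) - int(pos[a]))
            if dist == 0 or dist > max_dist:
                continue
            try:
                r2 = pairwise_r2(g.dosage[:, idx[a]], g.dosage[:, idx[b]])
            except UndefinedR2:
                continue
            bins[min(dist // bin_bp, n_bins - 1)].append(r2)
        per_chrom.append(
            np.array([np.median(v) if v else np.nan for v in bins])
        )
    if per_chrom:
        stacked = np.vstack(per_chrom)
        has_data = ~np.isnan(stacked).all(axis=0)
        mean_of_medians = np.full(n_bins, np.nan)
        mean_of_medians[has_data] = np.nanmean(stacked[:, has_data], axis=0)
    else:
        mean_of_medians = np.full(n_bins, np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_bp,
            "bin_end": (np.arange(n_bins) + 1) * bin_bp,
            "r2": mean_of_medians,
        }
    )


def _subpop_sample_index(
    g: GenotypeMatrix, a: SubpopAssignment, include_adm: bool
) -> dict[str, np.ndarray]:
    lookup = {s: i for i, s in enumerate(g.sample_ids)}
    out: dict[str, list[int]] = {}
    for s, l in zip(a.sample_ids, a.labels):
        if s not in lookup:
            continue
        if MAJOR_GROUP_OF[l] is None and not include_adm:
            continue
        if l.endswith("-adm") and not include_adm:
            continue
        out.setdefault(l, []).append(lookup[s])
    return {k: np.asarray(v) for k, v in out.items()}


def private_alleles(
    g: GenotypeMatrix, a: SubpopAssignment, include_adm: bool = False
) -> dict[str, int]:
    """Count alleles carried by exactly one subpopulation.

    Both the reference and alternate allele of each SNP are examined; an
    allele carried by ≥1 sample of subpopulation S and by no sample of any
    other subpopulation counts as private to S.
    """
    groups = _subpop_sample_index(g, a, include_adm)
    names = list(groups)
    counts = dict.fromkeys(names, 0)
    dos = g.dosage
    # carrier masks per subpop per allele, vectorized over SNPs
    alt_carrier = np.vstack(
        [((dos[idx] == 1) | (dos[idx] == 2)).any(axis=0) for idx in groups.values()]
    )
    ref_carrier = np.vstack(
        [((dos[idx] == 0) | (dos[idx] == 1)).any(axis=0) for idx in groups.values()]
    )
    for carrier in (alt_carrier, ref_carrier):
        n_subpops = carrier.sum(axis=0)
        for gi, name in enumerate(names):
            counts[name] += int((carrier[gi] & (n_subpops == 1)).sum())
    return counts


def doubleton_sharing(
    g: GenotypeMatrix, a: SubpopAssignment, include_adm: bool = False
) -> dict[tuple[str, str], int]:
    """Attribute doubleton alleles to (unordered) subpopulation pairs.

    A doubleton is an allele with total copy count exactly 2 across the
    included samples: either one homozygous carrier (a within-subpopulation
    doubleton) or two heterozygous carriers (attributed to the pair of their
    subpopulations).
    """
    groups = _subpop_sample_index(g, a, include_adm)
    sample_label = {}
    for name, idx in groups.items():
        for i in idx:
            sample_label[i] = name
    keep = np.asarray(sorted(sample_label))
    dos = g.dosage[keep]
    labels = [sample_label[i] for i in keep]
    called = dos != MISSING
    counts: dict[tuple[str, str], int] = {}

    for allele_copies in (
        np.where(called, dos, 0),  # alternate allele copies
        np.where(called, 2 - dos, 0),  # reference allele copies
    ):
        total = allele_copies.sum(axis=0)
        for j in np.flatnonzero(total == 2):
            carriers = np.flatnonzero(allele_copies[:, j] > 0)
            if len(carriers) == 1:
                pair = (labels[carriers[0]], labels[carriers[0]])
            else:
                pair = tuple(sorted((labels[carriers[0]], labels[carriers[1]])))
            counts[pair] = counts.get(pair, 0) + 1
    return counts
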