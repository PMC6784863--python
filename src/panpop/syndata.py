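"""Synthetic cohorts with the statistical structure of a selfing rice panel.

Four generators cover the inputs every downstream stage consumes:

* ``simulate_genotypes`` — multi-subpopulation SNP dosage matrices.  Subpopulation
  allele frequencies follow the Balding-Nichols model (a Beta draw around a
  shared ancestral frequency whose spread is set by a divergence parameter), and
  genotypes are drawn with an inbreeding coefficient ``f_sim`` so that
  P(het) = 2pq(1 - F), matching a predominantly self-pollinating species.
* ``simulate_pav_coverage`` — per-accession per-gene CDS and gene-body coverage
  around planted gene-family presence/absence states with group-specific loss
  rates.
* ``simulate_sv_candidates`` — jittered duplicate structural-variant candidate
  records emulating raw breakpoint caller output.
* ``simulate_introgression`` — XI/GJ haplotype pools at a single locus with a
  planted fraction of XI samples carrying the GJ haplotype.

Every generator takes an explicit seed and is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .groups import MAJOR_GROUP_OF, MAJOR_GROUPS, SubpopAssignment

FAMILY_CLASSES = ("core", "candidate_core", "distributed")


def _check_fraction(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {x}")


# ---------------------------------------------------------------------------
# genotype cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a synthetic multi-subpopulation genotype cohort.

    ``fst_like_divergence`` is the Balding-Nichols theta: 0 collapses all
    subpopulations onto the ancestral frequency, larger values produce
    stronger differentiation and private alleles.  ``f_sim`` deflates
    heterozygosity: P(het) = 2pq(1 - f_sim).
    """

    n_per_subpop: dict[str, int]
    n_snps: int = 1000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    fst_like_divergence: float = 0.15
    f_sim: float = 0.95
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_subpop:
            raise ValueError("n_per_subpop must not be empty")
        for sp, n in self.n_per_subpop.items():
            if n <= 0:
                raise ValueError(f"sample count for {sp} must be > 0")
            if sp not in MAJOR_GROUP_OF:
                raise ValueError(f"unknown subpopulation label {sp!r}")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be > 0")
        _check_fraction("fst_like_divergence", self.fst_like_divergence)
        _check_fraction("f_sim", self.f_sim)
        _check_fraction("missing_rate", self.missing_rate)


def _balding_nichols(
    rng: np.random.Generator, p_anc: np.ndarray, theta: float
) -> np.ndarray:
    """Subpopulation frequencies from Beta(p(1-t)/t, (1-p)(1-t)/t)."""
    if theta <= 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - theta) / theta
    b = (1.0 - p_anc) * (1.0 - theta) / theta
    return rng.beta(a, b)


def _draw_genotypes(
    rng: np.random.Generator, p: np.ndarray, n: int, f: float
) -> np.ndarray:
    """Draw n diploid dosages per SNP with inbreeding coefficient f."""
    het = 2.0 * p * (1.0 - p) * (1.0 - f)
    hom_alt = p**2 + f * p * (1.0 - p)
    u = rng.random((n, len(p)))
    g = np.zeros((n, len(p)), dtype=np.int8)
    g[u < hom_alt] = 2
    g[(u >= hom_alt) & (u < hom_alt + het)] = 1
    return g


def simulate_genotypes(spec: CohortSpec) -> tuple[GenotypeMatrix, SubpopAssignment]:
    """Generate a genotype matrix plus the true subpopulation labels."""
    rng = np.random.default_rng(spec.seed)

    # Spread SNPs over chromosomes proportionally to length.
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.floor(spec.n_snps * lengths / lengths.sum()).astype(int)
    per_chrom[: spec.n_snps - per_chrom.sum()] += 1
    chrom_col, pos_col = [], []
    for c, m in zip(chroms, per_chrom):
        if m == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(1, spec.chrom_lengths[c] + 1), size=m, replace=False)
        )
        chrom_col.extend([c] * m)
        pos_col.extend(pos.tolist())

    p_anc = rng.uniform(0.05, 0.95, size=spec.n_snps)
    rows, sample_ids, labels = [], [], []
    for sp, n in spec.n_per_subpop.items():
        p_sub = _balding_nichols(rng, p_anc, spec.fst_like_divergence)
        rows.append(_draw_genotypes(rng, p_sub, n, spec.f_sim))
        sample_ids.extend(f"{sp}_{i:04d}" for i in range(n))
        labels.extend([sp] * n)
    dosage = np.vstack(rows)
    if spec.missing_rate > 0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = MISSING

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = rng.choice(bases, size=spec.n_snps)
    alt_offset = rng.integers(1, 4, size=spec.n_snps)
    base_idx = np.array([np.flatnonzero(bases == r)[0] for r in ref])
    alt = bases[(base_idx + alt_offset) % 4]

    g = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.asarray(chrom_col, dtype=object),
        pos=np.asarray(pos_col, dtype=np.int64),
        ref=ref,
        alt=alt,
        dosage=dosage,
    )
    return g, SubpopAssignment(sample_ids, labels)


# ---------------------------------------------------------------------------
# gene-family presence/absence with coverage noise
# ---------------------------------------------------------------------------

#: high-depth rice panel composition: 303 XI, 92 GJ, 33 cA, 10 cB accessions
DEFAULT_PANEL = {"XI-1B": 303, "GJ-tmp": 92, "cA": 33, "cB": 10}


def _default_loss_rates() -> dict[tuple[str, str], float]:
    rates: dict[tuple[str, str], float] = {}
    for grp in MAJOR_GROUPS:
        rates[("core", grp)] = 0.0
        rates[("candidate_core", grp)] = 0.008
        rates[("distributed", grp)] = 0.08
    return rates


@dataclass
class PAVSpec:
    """Parameters of the synthetic gene-family presence/absence landscape.

    Class fractions default to the observed pan-genome mix (53.5% core,
    8.6% candidate core, 37.9% distributed).  ``group_loss_rates`` maps
    (family class, major group) to a per-accession loss probability; core
    families are never lost, candidate-core families sit below the 1% null
    loss rate, distributed families well above it.
    """

    n_families: int = 2000
    genes_per_family: dict = field(
        default_factory=lambda: {"kind": "geometric", "mean": 2.0}
    )
    frac_core: float = 0.535
    frac_candidate: float = 0.086
    frac_distributed: float = 0.379
    group_loss_rates: dict[tuple[str, str], float] = field(
        default_factory=_default_loss_rates
    )
    coverage_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be > 0")
        total = self.frac_core + self.frac_candidate + self.frac_distributed
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        for key, rate in self.group_loss_rates.items():
            _check_fraction(f"loss rate {key}", rate)


@dataclass
class PAVTruth:
    """Ground truth attached to a simulated coverage table."""

    family_classes: pd.Series  # family -> class
    gene_families: pd.Series  # gene -> family
    presence: pd.DataFrame  # accessions x families, bool


def _family_sizes(rng: np.random.Generator, spec: PAVSpec) -> np.ndarray:
    cfg = spec.genes_per_family
    if cfg["kind"] == "fixed":
        return np.full(spec.n_families, int(cfg["n"]))
    if cfg["kind"] == "geometric":
        return rng.geometric(1.0 / float(cfg["mean"]), size=spec.n_families)
    raise ValueError(f"unknown genes_per_family kind {cfg['kind']!r}")


def simulate_pav_coverage(
    spec: PAVSpec, assignments: SubpopAssignment
) -> tuple[pd.DataFrame, PAVTruth]:
    """Coverage table (accession, gene, cds_cov, body_cov) plus ground truth.

    Presence is planted at the family level: a lost family has every member
    gene absent in that accession.  Present genes get coverage just below 1.0
    (half-normal deficit with sd ``coverage_noise_sd``); absent genes get low
    residual coverage, so default thresholds (CDS > 0.95, body > 0.85)
    recover the planted states.
    """
    rng = np.random.default_rng(spec.seed)
    accessions = list(assignments.sample_ids)
    acc_group = []
    for s, l in zip(assignments.sample_ids, assignments.labels):
        grp = MAJOR_GROUP_OF[l]
        if grp is None:
            raise ValueError(f"accession {s} has no major group (label {l!r})")
        acc_group.append(grp)

    n_core = int(round(spec.frac_core * spec.n_families))
    n_cand = int(round(spec.frac_candidate * spec.n_families))
    classes = np.array(
        ["core"] * n_core
        + ["candidate_core"] * n_cand
        + ["distributed"] * (spec.n_families - n_core - n_cand),
        dtype=object,
    )
    rng.shuffle(classes)
    families = [f"FAM{i:05d}" for i in range(spec.n_families)]
    sizes = _family_sizes(rng, spec)
    genes, gene_fam = [], []
    for fam, sz in zip(families, sizes):
        for k in range(sz):
            genes.append(f"{fam}.g{k}")
            gene_fam.append(fam)

    # Planted family presence per accession.
    loss = np.zeros((len(accessions), spec.n_families))
    for i, grp in enumerate(acc_group):
        loss[i, :] = [spec.group_loss_rates[(cls, grp)] for cls in classes]
    present_fam = rng.random(loss.shape) >= loss

    # Expand to gene level and draw coverage.
    fam_index = {f: j for j, f in enumerate(families)}
    gene_fam_idx = np.array([fam_index[f] for f in gene_fam])
    present_gene = present_fam[:, gene_fam_idx]  # accessions x genes

    n_acc, n_genes = present_gene.shape
    cds = np.where(
        present_gene,
        1.0 - np.abs(rng.normal(0.0, spec.coverage_noise_sd, (n_acc, n_genes))),
        np.abs(rng.normal(0.20, 0.15, (n_acc, n_genes))),
    )
    body = np.where(
        present_gene,
        1.0 - np.abs(rng.normal(0.0, spec.coverage_noise_sd, (n_acc, n_genes))),
        np.abs(rng.normal(0.25, 0.15, (n_acc, n_genes))),
    )
    cds = np.clip(cds, 0.0, 1.0)
    body = np.clip(body, 0.0, 1.0)

    cov = pd.DataFrame(
        {
            "accession": np.repeat(accessions, n_genes),
            "gene": np.tile(np.asarray(genes, dtype=object), n_acc),
            "cds_cov": cds.ravel(),
            "body_cov": body.ravel(),
        }
    )
    truth = PAVTruth(
        family_classes=pd.Series(classes, index=families, name="class"),
        gene_families=pd.Series(gene_fam, index=genes, name="family"),
        presence=pd.DataFrame(present_fam, index=accessions, columns=families),
    )
    return cov, truth


# ---------------------------------------------------------------------------
# structural-variant candidates
# ---------------------------------------------------------------------------

def simulate_sv_candidates(
    n_true: int,
    jitter_bp: int,
    n_dup: int,
    seed: int,
    accessions: list[str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
):
    """Raw SV candidates: each true SV emitted ``1 + n_dup`` times with
    breakpoints jittered uniformly in ±``jitter_bp``.

    Returns a list of :class:`panpop.svkit.SVCandidate` with ``truth_id``
    set, so merge-recovery tests can compare cluster membership against the
    planted events.  Support counts are drawn to pass the candidate filter.
    """
    from .svkit import SVCandidate

    if jitter_bp < 0:
        raise ValueError("jitter_bp must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr1": 20_000_000, "chr2": 20_000_000}
    chroms = list(chrom_lengths)
    if accessions is None:
        accessions = [f"ACC{i:03d}" for i in range(1 + n_dup)]

    out: list[SVCandidate] = []
    for t in range(n_true):
        svtype = rng.choice(["DEL", "DUP", "INV", "TRA"], p=[0.45, 0.15, 0.1, 0.3])
        if svtype == "TRA":
            ca, cb = rng.choice(len(chroms), size=2, replace=False)
            pa = int(rng.integers(1, chrom_lengths[chroms[ca]] - 1))
            pb = int(rng.integers(1, chrom_lengths[chroms[cb]] - 1))
            base = dict(chrom=chroms[ca], start=pa, end=pa, chrom2=chroms[cb], pos2=pb)
        else:
            c = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(5_000, 50_000))
            start = int(rng.integers(1, chrom_lengths[c] - length))
            base = dict(chrom=c, start=start, end=start + length, chrom2=None, pos2=None)
        for d in range(1 + n_dup):
            j1 = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
            j2 = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
            start = max(1, base["start"] + j1)
            end = max(1, base["end"] + (j2 if svtype != "TRA" else j1))
            if svtype != "TRA" and end < start:
                start, end = end, start
            out.append(
                SVCandidate(
                    accession=accessions[d % len(accessions)],
                    svtype=str(svtype),
                    chrom=base["chrom"],
                    start=start,
                    end=end,
                    chrom2=base["chrom2"],
                    pos2=(
                        max(1, base["pos2"] + j2)
                        if base["pos2"] is not None
                        else None
                    ),
                    n_supporting_reads=int(rng.integers(3, 30)),
                    n_split_reads=int(rng.integers(5, 20)),
                    n_discordant_pairs=int(rng.integers(3, 15)),
                    truth_id=t,
                )
            )
    return out


# ---------------------------------------------------------------------------
# introgression locus
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionSpec:
    """XI/GJ haplotype pools at one locus with planted GJ→XI introgression.

    ``divergence`` is the Balding-Nichols theta between the two pools;
    ``introgressed_fraction`` of XI samples carry genotypes drawn from the GJ
    pool frequencies across the whole locus window.
    """

    n_xi: int = 200
    n_gj: int = 60
    locus_snps: int = 100
    divergence: float = 0.3
    introgressed_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_xi <= 0 or self.n_gj <= 0 or self.locus_snps <= 0:
            raise ValueError("counts must be positive")
        _check_fraction("divergence", self.divergence)
        _check_fraction("introgressed_fraction", self.introgressed_fraction)


def simulate_introgression(
    spec: IntrogressionSpec,
) -> tuple[GenotypeMatrix, SubpopAssignment, np.ndarray]:
    """Locus genotypes, labels, and the true per-XI-sample introgression flags.

    Genotypes are fully homozygous (dosage 0/2) — haplotype-like calls as in a
    selfer at a domestication locus.
    """
    rng = np.random.default_rng(spec.seed)
    p_anc = rng.uniform(0.1, 0.9, size=spec.locus_snps)
    p_xi = _balding_nichols(rng, p_anc, spec.divergence)
    p_gj = _balding_nichols(rng, p_anc, spec.divergence)

    n_intro = int(round(spec.introgressed_fraction * spec.n_xi))
    flags = np.zeros(spec.n_xi, dtype=bool)
    flags[rng.choice(spec.n_xi, size=n_intro, replace=False)] = True

    def draw(p: np.ndarray, n: int) -> np.ndarray:
        return (2 * (rng.random((n, len(p))) < p)).astype(np.int8)

    xi_rows = np.empty((spec.n_xi, spec.locus_snps), dtype=np.int8)
    xi_rows[~flags] = draw(p_xi, int((~flags).sum()))
    xi_rows[flags] = draw(p_gj, int(flags.sum()))
    gj_rows = draw(p_gj, spec.n_gj)

    sample_ids = [f"XI_{i:04d}" for i in range(spec.n_xi)] + [
        f"GJ_{i:04d}" for i in range(spec.n_gj)
    ]
    labels = ["XI-1A"] * spec.n_xi + ["GJ-tmp"] * spec.n_gj
    bases = np.array(["A"] * spec.locus_snps, dtype=object)
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.asarray(["chr1"] * spec.locus_snps, dtype=object),
        pos=np.arange(1, spec.locus_snps + 1, dtype=np.int64) * 100,
        ref=bases,
        alt=np.array(["T"] * spec.locus_snps, dtype=object),
        dosage=np.vstack([xi_rows, gj_rows]),
    )
    return g, SubpopAssignment(sample_ids, labels), flags
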