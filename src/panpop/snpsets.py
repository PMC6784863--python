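"""Nested SNP-set construction for a partially inbred species.

Three nested sets are built from a raw bi-allelic genotype matrix:

* **base set** — drop SNPs whose heterozygote count significantly exceeds the
  Hardy-Weinberg expectation deflated by the panel-wide inbreeding
  coefficient F (one-sided exact binomial test against n·2pq(1−F)).
* **filtered set** — drop SNPs with >20% missing calls or MAF < 1%.
* **core set** — two-pass LD pruning (10-kb bp window, then 50-SNP count
  window; r² threshold 0.8, step one SNP).

F is estimated as 1 − H_obs/H_exp, with both heterozygosities summed over
sites (ratio of sums).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


class UndefinedR2(ValueError):
    """r² is undefined: fewer than two co-called samples or zero variance."""


@dataclass
class SNPSetReport:
    """Outcome of one filtering stage: per-SNP keep flags and stage counts."""

    stage: str
    kept: np.ndarray  # bool per input SNP
    reason: np.ndarray  # object; "" for kept SNPs
    f_hat: float | None = None
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.kept)
        removed = int((~self.kept).sum())
        self.counts = {
            "input": n,
            "kept": int(self.kept.sum()),
            "removed": removed,
            **{
                f"removed_{r}": int((self.reason == r).sum())
                for r in sorted(set(self.reason[~self.kept]))
            },
        }
        assert self.counts["kept"] + self.counts["removed"] == n

    def kept_index(self) -> np.ndarray:
        return np.flatnonzero(self.kept)


# ---------------------------------------------------------------------------

def inbreeding_coefficient(g: GenotypeMatrix, clamp: bool = True) -> float:
    """Panel-wide inbreeding coefficient F = 1 − Σ H_obs / Σ H_exp.

    H_exp per site is n_called · 2p(1−p) with p the alternate-allele
    frequency among called alleles.  Raises if no site is polymorphic.
    """
    p = g.alt_freq()
    n = g.n_called()
    with np.errstate(invalid="ignore"):
        h_exp = n * 2.0 * p * (1.0 - p)
    h_exp = np.nan_to_num(h_exp)
    denom = h_exp.sum()
    if denom <= 0:
        raise ValueError("no polymorphic site with called samples; F undefined")
    f = 1.0 - g.het_counts().sum() / denom
    if clamp:
        f = min(1.0, max(0.0, f))
    return float(f)


def base_snp_filter(
    g: GenotypeMatrix, alpha: float = 0.05, f_hat: float | None = None
) -> SNPSetReport:
    """Remove SNPs with significant heterozygosity excess.

    A SNP with k heterozygotes among n called samples is removed iff the
    one-sided exact binomial tail P(X ≥ k | n, 2p(1−p)(1−F)) falls below
    ``alpha``.
    """
    if f_hat is None:
        f_hat = inbreeding_coefficient(g)
    p = np.nan_to_num(g.alt_freq())
    n = g.n_called()
    k = g.het_counts()
    het_prob = np.clip(2.0 * p * (1.0 - p) * (1.0 - f_hat), 0.0, 1.0)
    # P(X >= k) = sf(k - 1); k = 0 gives 1.0 -> always kept
    pvals = np.where(n > 0, stats.binom.sf(k - 1, n, het_prob), 1.0)
    kept = pvals >= alpha
    reason = np.where(kept, "", "het_excess").astype(object)
    return SNPSetReport("base", kept, reason, f_hat=f_hat)


def filtered_snp_filter(
    g: GenotypeMatrix, max_missing: float = 0.20, maf_min: float = 0.01
) -> SNPSetReport:
    """Keep SNPs with missing fraction ≤ 20% and MAF ≥ 1% (called alleles)."""
    miss = g.missing_rate()
    maf = np.nan_to_num(g.maf())
    miss_fail = miss > max_missing
    maf_fail = maf < maf_min
    kept = ~(miss_fail | maf_fail)
    reason = np.full(g.n_snps, "", dtype=object)
    reason[maf_fail] = "low_maf"
    reason[miss_fail] = "missing"  # missing takes precedence when both fail
    return SNPSetReport("filtered", kept, reason)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over co-called samples.

    Raises :class:`UndefinedR2` when fewer than two samples are co-called or
    either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise UndefinedR2("fewer than two co-called samples")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        raise UndefinedR2("zero variance on co-called samples")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov**2 / (vx * vy))


def _prune_pass(
    dosage: np.ndarray,
    order_coord: np.ndarray,
    maf: np.ndarray,
    window: float,
    r2_threshold: float,
) -> np.ndarray:
    """One left-to-right pruning pass.

    ``order_coord`` defines the window metric (bp position or survivor rank);
    SNPs whose coordinates differ by ≤ ``window`` are compared.  Within a
    violating pair the lower-MAF SNP is removed; MAF ties remove the
    right-hand (higher-index) SNP.  Returns indices (into the pass input) of
    survivors.
    """
    kept: list[int] = []
    m = dosage.shape[1]
    for j in range(m):
        drop_j = False
        for k in list(kept):
            if order_coord[j] - order_coord[k] > window:
                continue
            try:
                r2 = pairwise_r2(dosage[:, k], dosage[:, j])
            except UndefinedR2:
                continue
            if r2 <= r2_threshold:
                continue
            if maf[j] < maf[k] or (maf[j] == maf[k]):
                drop_j = True
                break
            kept.remove(k)
        if not drop_j:
            kept.append(j)
    return np.asarray(kept, dtype=np.int64)


def ld_prune_two_step(
    g: GenotypeMatrix,
    r2_threshold: float = 0.8,
    bp_window: int = 10_000,
    snp_window: int = 50,
) -> SNPSetReport:
    """Two-pass LD pruning: 10-kb bp windows then 50-SNP count windows.

    Both passes slide by one SNP and remove one SNP of any pair with
    r² > ``r2_threshold``; the second pass runs on the survivors of the
    first.  Scanning is left-to-right per chromosome with the MAF-preserving
    tie-break described in :func:`_prune_pass`.
    """
    maf = np.nan_to_num(g.maf())
    kept_global: list[int] = []
    for c in dict.fromkeys(g.chrom):
        idx = np.flatnonzero(g.chrom == c)
        dos = g.dosage[:, idx]
        pos = g.pos[idx].astype(float)
        s1 = _prune_pass(dos, pos, maf[idx], float(bp_window), r2_threshold)
        # pass 2: count window over survivors (rank distance < snp_window)
        s2 = _prune_pass(
            dos[:, s1],
            np.arange(len(s1), dtype=float),
            maf[idx][s1],
            float(snp_window - 1),
            r2_threshold,
        )
        kept_global.extend(idx[s1][s2].tolist())
    kept = np.zeros(g.n_snps, dtype=bool)
    kept[kept_global] = True
    reason = np.where(kept, "", "ld_pruned").astype(object)
    return SNPSetReport("core", kept, reason)


def build_snp_sets(
    g: GenotypeMatrix,
    alpha: float = 0.05,
    max_missing: float = 0.20,
    maf_min: float = 0.01,
    r2_threshold: float = 0.8,
    bp_window: int = 10_000,
    snp_window: int = 50,
) -> dict[str, SNPSetReport]:
    """Run the three stages and return nested reports keyed by stage name.

    The returned ``kept`` masks are all relative to the input matrix, so
    core ⊆ filtered ⊆ base ⊆ input holds by construction and is asserted.
    """
    base = base_snp_filter(g, alpha=alpha)
    g_base = g.take_snps(base.kept_index())
    filt_local = filtered_snp_filter(g_base, max_missing=max_missing, maf_min=maf_min)
    filt_kept = np.zeros(g.n_snps, dtype=bool)
    filt_kept[base.kept_index()[filt_local.kept_index()]] = True
    filt = SNPSetReport(
        "filtered",
        filt_kept,
        np.where(filt_kept, "", "filtered_out").astype(object),
    )
    g_filt = g.take_snps(filt.kept_index())
    core_local = ld_prune_two_step(
        g_filt,
        r2_threshold=r2_threshold,
        bp_window=bp_window,
        snp_window=snp_window,
    )
    core_kept = np.zeros(g.n_snps, dtype=bool)
    core_kept[filt.kept_index()[core_local.kept_index()]] = True
    core = SNPSetReport(
        "core", core_kept, np.where(core_kept, "", "ld_pruned").astype(object)
    )
    assert (core.kept <= filt.kept).all() and (filt.kept <= base.kept).all()
    return {"base": base, "filtered": filt, "core": core}
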