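"""Map-to-pan presence calling and pan-genome classification.

Gene presence is called from short-read mapping coverage (CDS coverage
> 0.95 AND gene-body coverage > 0.85, strict); a gene family is present when
any member gene is.  Families are partitioned into

* **core** — present in every accession,
* **candidate core** — loss rate not significantly above 1% in every major
  group (one-sided exact binomial test per group, α = 0.05),
* **distributed** — significant loss in at least one group,

and distributed families are further split into major-group-unbalanced,
subpopulation-unbalanced and random classes with an exact 2xK conditional
test (Fisher-Freeman-Halton) under Benjamini-Hochberg FDR control.  The
module also hosts the pan/core accumulation-curve simulation, pairwise PAV
differences, phylostratum age assignment and the assembly k-mer model.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

PHYLOSTRATA = tuple(f"PS{i}" for i in range(1, 14))


# ---------------------------------------------------------------------------
# presence calling
# ---------------------------------------------------------------------------

def call_presence(
    coverage: pd.DataFrame,
    accessions: list[str] | None = None,
    genes: list[str] | None = None,
    cds_min: float = 0.95,
    body_min: float = 0.85,
) -> pd.DataFrame:
    """Gene-level PAV matrix from a coverage table.

    ``coverage`` has columns accession, gene, cds_cov, body_cov.  A gene is
    present iff cds_cov > ``cds_min`` AND body_cov > ``body_min`` (both
    strict); accession/gene combinations without a record are absent.
    """
    present = coverage[
        (coverage["cds_cov"] > cds_min) & (coverage["body_cov"] > body_min)
    ]
    accessions = accessions or sorted(coverage["accession"].unique())
    genes = genes or sorted(coverage["gene"].unique())
    pav = pd.DataFrame(0, index=accessions, columns=genes, dtype=np.int8)
    hit = present[
        present["accession"].isin(pav.index) & present["gene"].isin(pav.columns)
    ]
    if len(hit):
        mat = pd.crosstab(hit["accession"], hit["gene"]).clip(upper=1)
        pav.loc[mat.index, mat.columns] = mat.astype(np.int8)
    return pav


def family_presence(gene_pav: pd.DataFrame, families: pd.Series) -> pd.DataFrame:
    """Family-level PAV: a family is present iff any member gene is present."""
    unmapped = [g for g in gene_pav.columns if g not in families.index]
    if unmapped:
        raise ValueError(f"genes without family mapping: {unmapped[:5]} ...")
    fam_of = families[gene_pav.columns]
    return (gene_pav.T.groupby(fam_of.values).any().T).astype(np.int8)


# ---------------------------------------------------------------------------
# core / candidate core / distributed
# ---------------------------------------------------------------------------

def classify_core_distributed(
    fam_pav: pd.DataFrame,
    groups: dict[str, list[str]],
    loss_null: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partition families into core / candidate_core / distributed.

    Core: present in all grouped accessions.  Otherwise, per major group g
    with n_g accessions and k_g losses, p_g = P(X ≥ k_g | n_g, loss_null)
    one-sided exact binomial; distributed iff p_g < ``alpha`` in at least
    one group, candidate core otherwise.  Returns a frame indexed by family
    with the class, per-group loss counts and p-values.
    """
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    all_acc = [a for members in groups.values() for a in members]
    sub = fam_pav.loc[all_acc]
    out = pd.DataFrame(index=fam_pav.columns)
    any_sig = np.zeros(fam_pav.shape[1], dtype=bool)
    for name, members in groups.items():
        n_g = len(members)
        k_g = (1 - fam_pav.loc[members]).sum(axis=0).to_numpy()
        p_g = stats.binom.sf(k_g - 1, n_g, loss_null)
        out[f"loss_{name}"] = k_g
        out[f"p_{name}"] = p_g
        any_sig |= p_g < alpha
    core = (sub.sum(axis=0) == len(all_acc)).to_numpy()
    cls = np.where(core, "core", np.where(any_sig, "distributed", "candidate_core"))
    out.insert(0, "class", cls)
    return out


# ---------------------------------------------------------------------------
# exact 2xK conditional test (Fisher-Freeman-Halton)
# ---------------------------------------------------------------------------

@dataclass
class ExactTestResult:
    p: float
    method: str  # "exact" or "monte_carlo"
    se: float | None = None

    def __float__(self) -> float:
        return self.p


def _log_table_prob(k: np.ndarray, n: np.ndarray, total_present: int) -> float:
    lp = -(
        lgamma(n.sum() + 1)
        - lgamma(total_present + 1)
        - lgamma(n.sum() - total_present + 1)
    )
    for kj, nj in zip(k, n):
        lp += lgamma(nj + 1) - lgamma(kj + 1) - lgamma(nj - kj + 1)
    return lp


def _enumerate_tables(n: np.ndarray, total: int):
    """Yield all count vectors k with 0 <= k_j <= n_j and sum k = total."""
    K = len(n)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == K - 1:
            if 0 <= remaining <= n[j]:
                yield prefix + [remaining]
            return
        tail = int(n[j + 1 :].sum())
        lo = max(0, remaining - tail)
        hi = min(n[j], remaining)
        for kj in range(lo, hi + 1):
            yield from rec(j + 1, remaining - kj, prefix + [kj])

    yield from rec(0, total, [])


def _table_count(n: np.ndarray, total: int) -> int:
    # dp over groups: number of k-vectors with the given sum
    counts = {0: 1}
    for nj in n:
        new: dict[int, int] = {}
        for s, c in counts.items():
            for kj in range(min(nj, total - s) + 1):
                new[s + kj] = new.get(s + kj, 0) + c
        counts = new
    return counts.get(total, 0)


def exact_2xk(
    present_counts,
    absent_counts,
    rel_tol: float = 1e-7,
    enum_budget: int = 200_000,
    mc_draws: int = 20_000,
    seed: int = 0,
) -> ExactTestResult:
    """Two-sided exact test of homogeneity for a 2xK contingency table.

    Conditional on both margins, sums the multivariate-hypergeometric
    probabilities of every table at most as probable as the observed one
    (with relative tolerance ``rel_tol``, the conventional two-sided
    definition).  When the number of candidate tables exceeds
    ``enum_budget`` the tail is estimated by seeded Monte-Carlo sampling
    from the null and the standard error is reported.
    """
    k_obs = np.asarray(present_counts, dtype=np.int64)
    a_obs = np.asarray(absent_counts, dtype=np.int64)
    if k_obs.shape != a_obs.shape or k_obs.ndim != 1 or len(k_obs) < 2:
        raise ValueError("need matching 1-D present/absent counts, K >= 2")
    if (k_obs < 0).any() or (a_obs < 0).any():
        raise ValueError("counts must be non-negative")
    n = k_obs + a_obs
    if (n == 0).any():
        raise ValueError("every group margin must be > 0")
    total = int(k_obs.sum())
    if total == 0 or total == int(n.sum()):
        return ExactTestResult(1.0, "exact")

    lp_obs = _log_table_prob(k_obs, n, total)
    cutoff = lp_obs + np.log1p(rel_tol)

    if _table_count(n, total) <= enum_budget:
        p = 0.0
        for k in _enumerate_tables(n, total):
            lp = _log_table_prob(np.asarray(k), n, total)
            if lp <= cutoff:
                p += np.exp(lp)
        return ExactTestResult(min(p, 1.0), "exact")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(n, total, size=mc_draws)
    lp_norm = lgamma(n.sum() + 1) - lgamma(total + 1) - lgamma(n.sum() - total + 1)
    lp_draws = (
        gammaln(n + 1).sum()
        - gammaln(draws + 1).sum(axis=1)
        - gammaln(n - draws + 1).sum(axis=1)
        - lp_norm
    )
    hits = lp_draws <= cutoff
    p_hat = float(hits.mean())
    se = float(np.sqrt(p_hat * (1 - p_hat) / mc_draws))
    return ExactTestResult(p_hat, "monte_carlo", se)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if (pvalues < 0).any() or (pvalues > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# unbalanced families
# ---------------------------------------------------------------------------

def unbalanced_test(
    fam_pav: pd.DataFrame,
    groups: dict[str, list[str]],
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact 2xK imbalance test per family for one grouping scheme.

    Returns a frame indexed like ``fam_pav.columns`` with p, fdr and the
    below-threshold flag; BH adjustment is applied across all families of
    this scheme.
    """
    idx = {g: fam_pav.index.get_indexer(members) for g, members in groups.items()}
    vals = fam_pav.to_numpy()
    pvals = []
    for j in range(vals.shape[1]):
        present = [int(vals[idx[g], j].sum()) for g in groups]
        absent = [len(idx[g]) - pr for g, pr in zip(groups, present)]
        pvals.append(exact_2xk(present, absent, seed=seed + j).p)
    adj = bh_adjust(np.asarray(pvals))
    return pd.DataFrame(
        {"p": pvals, "fdr": adj, "unbalanced": adj < fdr}, index=fam_pav.columns
    )


def unbalanced_families(
    fam_pav: pd.DataFrame,
    major_groups: dict[str, list[str]],
    xi_subpops: dict[str, list[str]] | None = None,
    gj_subpops: dict[str, list[str]] | None = None,
    families: list[str] | None = None,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Balance classes for (distributed) families.

    Each family is tested for imbalance among the four major groups and,
    when subpopulation maps are given, among XI and among GJ subpopulations
    (each scheme BH-adjusted separately).  The reported ``balance_class``
    applies the precedence major-group-unbalanced > XI-subpop-unbalanced >
    GJ-subpop-unbalanced > random; per-scheme flags are also returned.
    """
    sub = fam_pav[families] if families is not None else fam_pav
    major = unbalanced_test(sub, major_groups, fdr=fdr, seed=seed)
    out = pd.DataFrame(index=sub.columns)
    out["p_major"] = major["p"]
    out["fdr_major"] = major["fdr"]
    out["major_unbalanced"] = major["unbalanced"]
    for name, scheme in (("xi", xi_subpops), ("gj", gj_subpops)):
        if scheme is not None:
            res = unbalanced_test(sub, scheme, fdr=fdr, seed=seed)
            out[f"p_{name}"] = res["p"]
            out[f"fdr_{name}"] = res["fdr"]
            out[f"{name}_unbalanced"] = res["unbalanced"]
        else:
            out[f"{name}_unbalanced"] = False
    cls = np.where(
        out["major_unbalanced"],
        "major-group-unbalanced",
        np.where(
            out["xi_unbalanced"],
            "subpop-unbalanced(XI)",
            np.where(out["gj_unbalanced"], "subpop-unbalanced(GJ)", "random"),
        ),
    )
    out["balance_class"] = cls
    return out


# ---------------------------------------------------------------------------
# accumulation curves and pairwise differences
# ---------------------------------------------------------------------------

def accumulation_curves(
    fam_pav: pd.DataFrame, n_perm: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Pan- and core-genome sizes as genomes are added in random orders.

    For each of ``n_perm`` random accession orders (permutation i is seeded
    with ``seed + i``), step r records the number of families present in at
    least one (pan) and in all (core) of the first r genomes.  Returns the
    per-step mean and 5%/95% quantiles across permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = fam_pav.to_numpy().astype(bool)
    n_acc = present.shape[0]
    pans = np.empty((n_perm, n_acc), dtype=np.int64)
    cores = np.empty((n_perm, n_acc), dtype=np.int64)
    for i in range(n_perm):
        order = np.random.default_rng(seed + i).permutation(n_acc)
        m = present[order]
        pans[i] = np.logical_or.accumulate(m, axis=0).sum(axis=1)
        cores[i] = np.logical_and.accumulate(m, axis=0).sum(axis=1)
    return pd.DataFrame(
        {
            "n_genomes": np.arange(1, n_acc + 1),
            "pan_mean": pans.mean(axis=0),
            "pan_q05": np.quantile(pans, 0.05, axis=0),
            "pan_q95": np.quantile(pans, 0.95, axis=0),
            "core_mean": cores.mean(axis=0),
            "core_q05": np.quantile(cores, 0.05, axis=0),
            "core_q95": np.quantile(cores, 0.95, axis=0),
        }
    )


def pairwise_difference(
    pav: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean number of entities differing between two accessions, by group pair.

    The per-pair statistic is the symmetric-difference count (entities
    present in exactly one of the two accessions); cells average over all
    within-group (i < j) or between-group pairs.  Requires ≥2 accessions for
    within-group cells.
    """
    x = pav.to_numpy().astype(np.int64)
    diff = x @ (1 - x).T + (1 - x) @ x.T  # pairwise symmetric-difference counts
    pos = {a: i for i, a in enumerate(pav.index)}
    names = list(groups)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for gi in names:
        for gj in names:
            ia = [pos[a] for a in groups[gi]]
            ib = [pos[a] for a in groups[gj]]
            block = diff[np.ix_(ia, ib)]
            if gi == gj:
                if len(ia) < 2:
                    raise ValueError(f"group {gi!r} needs >= 2 accessions")
                iu = np.triu_indices(len(ia), k=1)
                out.loc[gi, gj] = block[iu].mean()
            else:
                out.loc[gi, gj] = block.mean()
    return out


# ---------------------------------------------------------------------------
# gene and family ages
# ---------------------------------------------------------------------------

def assign_ages(
    genes: list[str],
    hits: pd.DataFrame,
    wild_coverage: pd.DataFrame | None = None,
    families: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Phylostratum ages for genes and (optionally) families.

    ``hits`` has columns gene, stratum (PS1..PS13), one row per qualifying
    database hit.  A gene's age is its oldest stratum (lowest PS number);
    genes without hits are PS13.  PS13 genes covered by wild rice
    (``wild_coverage`` columns gene, body_cov, cds_cov; both > 0.95) are
    reassigned to PS12.  A family's age is the oldest member age.
    """
    bad = set(hits["stratum"]) - set(PHYLOSTRATA)
    if bad:
        raise ValueError(f"unknown phylostrata: {sorted(bad)}")
    rank = {ps: i for i, ps in enumerate(PHYLOSTRATA)}
    oldest = (
        hits.assign(r=hits["stratum"].map(rank)).groupby("gene")["r"].min()
    )
    ages = pd.Series(
        [PHYLOSTRATA[oldest[g]] if g in oldest.index else "PS13" for g in genes],
        index=genes,
        name="stratum",
    )
    if wild_coverage is not None:
        wc = wild_coverage.set_index("gene")
        for g in ages.index[ages == "PS13"]:
            if (
                g in wc.index
                and wc.loc[g, "body_cov"] > 0.95
                and wc.loc[g, "cds_cov"] > 0.95
            ):
                ages[g] = "PS12"
    fam_ages = None
    if families is not None:
        r = ages.map(rank)
        fam_ages = (
            r.groupby(families[ages.index].values)
            .min()
            .map(lambda i: PHYLOSTRATA[int(i)])
            .rename("stratum")
        )
    return ages, fam_ages


# ---------------------------------------------------------------------------
# assembly k-mer model
# ---------------------------------------------------------------------------

def soap_kmer(depth: float) -> int:
    """Initial assembly k-mer from sequencing depth: K = 2·int(0.38·d + 10) + 1."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    return 2 * int(0.38 * depth + 10) + 1


def select_kmer(depth: float, n50, k_min: int = 13, k_max: int = 127) -> tuple[int, int]:
    """Pick the assembly k-mer by hill climbing on N50.

    Starting from :func:`soap_kmer`, steps of ±2 are taken until the current
    k-mer's N50 exceeds both neighbours'.  ``n50`` is a callable k → N50.
    Returns ``(k, n_evaluations)``.
    """
    k = min(max(soap_kmer(depth), k_min), k_max)
    cache: dict[int, float] = {}

    def ev(kk: int) -> float:
        if kk not in cache:
            cache[kk] = float(n50(kk))
        return cache[kk]

    while True:
        here = ev(k)
        up = ev(k + 2) if k + 2 <= k_max else -np.inf
        down = ev(k - 2) if k - 2 >= k_min else -np.inf
        if here > up and here > down:
            return k, len(cache)
        k = k + 2 if up >= down else k - 2
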