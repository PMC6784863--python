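"""Structural-variant post-processing.

Raw breakpoint-caller candidates are filtered on read support and size,
pooled across accessions and merged into non-redundant calls: two same-type
candidates are the same SV when their start and end positions differ by at
most 1 kb and their overlap exceeds 50% of the union span (translocations are
matched on breakpoint proximity alone).  Merged calls yield a binary
presence-absence matrix, per-accession burden summaries, major-group
imbalance tests and an SV-based tree.

Intervals are half-open: the span of a call is ``[start, end)`` and its
length ``end − start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popstruct import DistanceMatrix, nj_tree

INTRA_TYPES = ("DEL", "DUP", "INV")
SV_TYPES = INTRA_TYPES + ("TRA",)


@dataclass
class SVCandidate:
    """One raw SV candidate from one accession.

    Intra-chromosomal types (DEL/DUP/INV) use ``chrom:start-end``;
    translocations (TRA) pair ``chrom:start`` with ``chrom2:pos2``.
    """

    accession: str
    svtype: str
    chrom: str
    start: int
    end: int
    chrom2: str | None = None
    pos2: int | None = None
    n_supporting_reads: int = 0
    n_split_reads: int = 0
    n_discordant_pairs: int = 0
    truth_id: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.svtype != "TRA" and self.end < self.start:
            raise ValueError("end < start for intra-chromosomal SV")
        if min(self.n_supporting_reads, self.n_split_reads, self.n_discordant_pairs) < 0:
            raise ValueError("support counts must be >= 0")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SVCall:
    """A merged SV: representative coordinates plus member candidates."""

    call_id: str
    svtype: str
    chrom: str
    start: int
    end: int
    chrom2: str | None
    pos2: int | None
    members: list[SVCandidate] = field(default_factory=list)

    @property
    def accessions(self) -> set[str]:
        return {m.accession for m in self.members}


def filter_candidates(
    candidates: list[SVCandidate],
    min_reads: int = 3,
    min_split: int = 4,
    min_discordant: int = 3,
    min_size: int = 100,
    max_size: int = 1_000_000,
) -> list[SVCandidate]:
    """Support and size filter.

    Keep a candidate iff supporting reads ≥ 3 AND (split reads > 4 OR
    discordant pairs ≥ 3).  DEL/DUP/INV must additionally have
    100 bp ≤ size ≤ 1 Mb; translocations are exempt from the size rule.
    """
    out = []
    for c in candidates:
        if c.n_supporting_reads < min_reads:
            continue
        if not (c.n_split_reads > min_split or c.n_discordant_pairs >= min_discordant):
            continue
        if c.svtype in INTRA_TYPES and not (min_size <= c.size <= max_size):
            continue
        out.append(c)
    return out


def _same_sv(a: SVCandidate, b: SVCandidate, tol_bp: int, min_overlap: float) -> bool:
    if a.svtype != b.svtype:
        return False
    if a.svtype == "TRA":
        ka = sorted([(a.chrom, a.start), (a.chrom2, a.pos2)])
        kb = sorted([(b.chrom, b.start), (b.chrom2, b.pos2)])
        return all(
            ca == cb and abs(pa - pb) <= tol_bp for (ca, pa), (cb, pb) in zip(ka, kb)
        )
    if a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > tol_bp or abs(a.end - b.end) > tol_bp:
        return False
    overlap = min(a.end, b.end) - max(a.start, b.start)
    union = max(a.end, b.end) - min(a.start, b.start)
    return union > 0 and overlap / union > min_overlap


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_svs(
    candidates: list[SVCandidate],
    tol_bp: int = 1000,
    min_overlap: float = 0.5,
) -> list[SVCall]:
    """Single-linkage merge of equivalent candidates into SV calls.

    Candidates are partitioned by type and chromosome (chromosome pair for
    TRA) and linked whenever the pair predicate holds; transitive chains form
    one call.  The representative is the member with the median start (lower
    median for even cluster sizes).  Output is ordered by type, chromosome
    and representative start, so cluster identity is independent of the
    input order.
    """
    def sort_pos(c: SVCandidate) -> int:
        # for TRA use the breakpoint on the lexicographically smaller chromosome
        if c.svtype == "TRA":
            return min((c.chrom, c.start), (c.chrom2, c.pos2))[1]
        return c.start

    buckets: dict[tuple, list[SVCandidate]] = {}
    for c in candidates:
        if c.svtype == "TRA":
            key = ("TRA",) + tuple(sorted([c.chrom, c.chrom2]))
        else:
            key = (c.svtype, c.chrom)
        buckets.setdefault(key, []).append(c)

    calls: list[SVCall] = []
    for key in sorted(buckets):
        group = sorted(
            buckets[key], key=lambda c: (sort_pos(c), c.start, c.end, c.accession)
        )
        uf = _UnionFind(len(group))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if sort_pos(group[j]) - sort_pos(group[i]) > tol_bp:
                    break
                if _same_sv(group[i], group[j], tol_bp, min_overlap):
                    uf.union(i, j)
        clusters: dict[int, list[SVCandidate]] = {}
        for i, c in enumerate(group):
            clusters.setdefault(uf.find(i), []).append(c)
        for root in sorted(clusters):
            members = clusters[root]
            by_start = sorted(members, key=lambda c: (c.start, c.end))
            rep = by_start[(len(by_start) - 1) // 2]
            calls.append(
                SVCall(
                    call_id="",
                    svtype=rep.svtype,
                    chrom=rep.chrom,
                    start=rep.start,
                    end=rep.end,
                    chrom2=rep.chrom2,
                    pos2=rep.pos2,
                    members=members,
                )
            )
    calls.sort(key=lambda s: (s.svtype, s.chrom, s.start, s.end))
    for i, s in enumerate(calls):
        s.call_id = f"SV{i:06d}"
    return calls


def sv_matrix(
    calls: list[SVCall],
    accessions: list[str],
    gene_intervals: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary presence matrix plus per-accession burden summaries.

    ``gene_intervals`` (optional) is a frame with columns gene, chrom,
    start, end (half-open); a gene counts as affected in an accession when
    its interval intersects any intra-chromosomal SV span present there
    (genes fully inside an SV are thereby included).

    Returns ``(presence, summary)``: presence is accessions x calls (0/1);
    summary has one row per accession with per-type counts, total,
    affected_bp (union of spans) and genes_affected.
    """
    presence = pd.DataFrame(
        0, index=list(accessions), columns=[s.call_id for s in calls], dtype=np.int8
    )
    for s in calls:
        for acc in s.accessions:
            if acc in presence.index:
                presence.loc[acc, s.call_id] = 1

    rows = []
    for acc in accessions:
        present = [s for s in calls if acc in s.accessions]
        type_counts = {t: sum(1 for s in present if s.svtype == t) for t in SV_TYPES}
        spans: dict[str, list[tuple[int, int]]] = {}
        for s in present:
            if s.svtype in INTRA_TYPES:
                spans.setdefault(s.chrom, []).append((s.start, s.end))
        affected = 0
        gene_hits: set[str] = set()
        for chrom, ivs in spans.items():
            ivs.sort()
            merged: list[list[int]] = []
            for st, en in ivs:
                if merged and st <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], en)
                else:
                    merged.append([st, en])
            affected += sum(en - st for st, en in merged)
            if gene_intervals is not None:
                sub = gene_intervals[gene_intervals["chrom"] == chrom]
                for st, en in merged:
                    hit = sub[(sub["start"] < en) & (sub["end"] > st)]
                    gene_hits.update(hit["gene"])
        rows.append(
            {
                "accession": acc,
                **type_counts,
                "total": len(present),
                "affected_bp": affected,
                "genes_affected": len(gene_hits),
            }
        )
    return presence, pd.DataFrame(rows).set_index("accession")


def group_unbalanced_svs(
    presence: pd.DataFrame,
    groups: dict[str, list[str]],
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact 2xK group-imbalance test per SV with Benjamini-Hochberg control.

    ``groups`` maps each major group to its accession ids (must be
    non-empty).  Returns a frame indexed by call id with columns p, fdr,
    unbalanced.
    """
    from .pangenome import bh_adjust, exact_2xk

    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    idx = {name: [presence.index.get_loc(a) for a in members]
           for name, members in groups.items()}
    vals = presence.to_numpy()
    pvals = []
    for j in range(vals.shape[1]):
        present = [int(vals[idx[g], j].sum()) for g in groups]
        absent = [len(idx[g]) - p for g, p in zip(groups, present)]
        pvals.append(exact_2xk(present, absent, seed=seed + j).p)
    adj = bh_adjust(np.asarray(pvals))
    return pd.DataFrame(
        {"p": pvals, "fdr": adj, "unbalanced": adj < fdr},
        index=presence.columns,
    )


_CAND_COLS = [
    "accession", "svtype", "chrom", "start", "end", "chrom2", "pos2",
    "n_supporting_reads", "n_split_reads", "n_discordant_pairs",
]


def write_candidates_tsv(candidates: list[SVCandidate], path) -> None:
    rows = [
        {c: getattr(cand, c) for c in _CAND_COLS} for cand in candidates
    ]
    pd.DataFrame(rows, columns=_CAND_COLS).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> list[SVCandidate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            SVCandidate(
                accession=str(r["accession"]),
                svtype=str(r["svtype"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                chrom2=None if pd.isna(r.get("chrom2")) else str(r["chrom2"]),
                pos2=None if pd.isna(r.get("pos2")) else int(r["pos2"]),
                n_supporting_reads=int(r["n_supporting_reads"]),
                n_split_reads=int(r["n_split_reads"]),
                n_discordant_pairs=int(r["n_discordant_pairs"]),
            )
        )
    return out


def write_calls_tsv(calls: list[SVCall], path) -> None:
    rows = [
        {
            "call_id": s.call_id,
            "svtype": s.svtype,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "chrom2": s.chrom2,
            "pos2": s.pos2,
            "n_members": len(s.members),
            "n_accessions": len(s.accessions),
        }
        for s in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sv_tree(presence: pd.DataFrame, n_svs: int, seed: int):
    """Neighbour-joining tree from a random subset of SV presence columns.

    Samples ``n_svs`` columns without replacement (seeded), computes the
    simple-matching distance between accession presence vectors and runs
    unweighted neighbour joining.
    """
    if n_svs > presence.shape[1]:
        raise ValueError("n_svs exceeds the number of SVs")
    rng = np.random.default_rng(seed)
    cols = rng.choice(presence.shape[1], size=n_svs, replace=False)
    sub = presence.to_numpy()[:, cols]
    n = sub.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = (sub != sub[i]).mean(axis=1)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return nj_tree(DistanceMatrix(list(presence.index), d))
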