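"""Population structure: distances, trees, ordination, admixture assignment.

The distance kernels are the two allele-sharing metrics used throughout the
pipeline — identity-by-state (IBS) and simple matching on dosages — computed
over pairwise-complete loci.  Trees come from unweighted neighbour joining,
ordination from classical (Torgerson) multidimensional scaling equivalent to
R's ``cmdscale``, and subpopulation labels from the ≥0.65 admixture-component
rule with XI-adm / GJ-adm / admix fallbacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotypes import MISSING, GenotypeMatrix
from .groups import GJ_SUBPOPS, SUBPOPULATIONS, XI_SUBPOPS, SubpopAssignment


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with values in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


def allele_sharing_distance(
    g: GenotypeMatrix,
    mode: str = "ibs",
    min_co_called: int = 50,
) -> DistanceMatrix:
    """Pairwise IBS or simple-matching distance over pairwise-complete loci.

    ``ibs``: d = 1 − (n_IBS2 + 0.5·n_IBS1) / n_co-called, where IBS2 means
    equal dosage and IBS1 a one-allele difference.  ``simple_matching``:
    d = fraction of co-called loci with unequal dosage.  A pair with fewer
    than ``min_co_called`` co-called loci is an error naming the pair.
    """
    if mode not in ("ibs", "simple_matching"):
        raise ValueError(f"unknown mode {mode!r}")
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    dos = g.dosage
    called = dos != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n - 1):
        co = called[i] & called[i + 1 :]
        n_co = co.sum(axis=1)
        short = np.flatnonzero(n_co < min_co_called)
        if short.size:
            j = int(short[0]) + i + 1
            raise ValueError(
                f"samples {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share only "
                f"{int(n_co[short[0]])} co-called loci (< {min_co_called})"
            )
        diff = np.abs(dos[i + 1 :].astype(np.int16) - dos[i].astype(np.int16))
        if mode == "ibs":
            ibs2 = ((diff == 0) & co).sum(axis=1)
            ibs1 = ((diff == 1) & co).sum(axis=1)
            row = 1.0 - (ibs2 + 0.5 * ibs1) / n_co
        else:
            row = ((diff != 0) & co).sum(axis=1) / n_co
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(list(g.sample_ids), d)


def nj_tree(d: DistanceMatrix):
    """Unweighted neighbour joining (Saitou-Nei) on a distance matrix.

    Returns a :class:`skbio.TreeNode`; negative branch lengths are clamped
    to zero.  Requires at least three samples.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    if len(d.sample_ids) < 3:
        raise ValueError("neighbour joining needs at least three samples")
    return nj(SkbioDM(d.values, ids=d.sample_ids), neg_as_zero=True)


def classical_mds(d: DistanceMatrix, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling: double-centre −D²/2, eigendecompose, scale by √λ.

    Returns ``(coords, eigenvalues)``.  Only positive eigenvalues are used;
    if fewer than ``dims`` exist the coordinate matrix has fewer columns
    (the caller can detect this from its shape).
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D2 = d.values**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0]))
    k = min(dims, int(pos.sum()))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return coords, vals


@dataclass
class QMatrix:
    """Admixture proportions: samples x k, columns labelled by subpopulation."""

    sample_ids: list[str]
    q: np.ndarray
    col_subpops: list[str]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.sample_ids), len(self.col_subpops)):
            raise ValueError("Q shape does not match samples x columns")
        if (self.q < -1e-12).any():
            raise ValueError("admixture proportions must be non-negative")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1 (±1e-6)")


def _aligned(run: QMatrix, ref: QMatrix) -> np.ndarray:
    """Permute run columns to maximize summed column correlation with ref."""
    k = run.q.shape[1]
    corr = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            x, y = ref.q[:, a], run.q[:, b]
            sx, sy = x.std(), y.std()
            corr[a, b] = (
                0.0 if sx == 0 or sy == 0 else np.corrcoef(x, y)[0, 1]
            )
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return run.q[:, perm]


def align_and_average_q(
    runs: list[QMatrix], similarity_cutoff: float = 0.9
) -> QMatrix:
    """Align replicate Q-matrices, cluster by similarity, average the
    largest cluster.

    Columns of every run are permuted to best match the first run (optimal
    assignment on column correlations).  Aligned runs whose mean column
    correlation exceeds ``similarity_cutoff`` are connected; the largest
    connected component is averaged and row-renormalized.
    """
    if not runs:
        raise ValueError("no runs given")
    ref = runs[0]
    for r in runs[1:]:
        if r.sample_ids != ref.sample_ids or r.q.shape != ref.q.shape:
            raise ValueError("all runs must share samples and k")
    if len(runs) == 1:
        return ref
    aligned = [ref.q] + [_aligned(r, ref) for r in runs[1:]]

    m = len(aligned)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            cc = [
                np.corrcoef(aligned[i][:, c], aligned[j][:, c])[0, 1]
                if aligned[i][:, c].std() > 0 and aligned[j][:, c].std() > 0
                else 0.0
                for c in range(ref.q.shape[1])
            ]
            sim[i, j] = sim[j, i] = float(np.mean(cc))
    # connected components of the similarity graph
    comp = -np.ones(m, dtype=int)
    nc = 0
    for i in range(m):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = nc
        while stack:
            u = stack.pop()
            for v in range(m):
                if comp[v] < 0 and sim[u, v] >= similarity_cutoff:
                    comp[v] = nc
                    stack.append(v)
        nc += 1
    sizes = np.bincount(comp, minlength=nc)
    biggest = int(np.argmax(sizes))
    members = [aligned[i] for i in range(m) if comp[i] == biggest]
    avg = np.mean(members, axis=0)
    avg /= avg.sum(axis=1, keepdims=True)
    return QMatrix(ref.sample_ids, avg, list(ref.col_subpops))


def assign_subpopulations(
    q: QMatrix, threshold: float = 0.65
) -> SubpopAssignment:
    """Label each sample from its admixture proportions.

    A sample gets its maximal subpopulation if that component is ≥ threshold;
    otherwise XI-adm (resp. GJ-adm) if the summed XI (GJ) components reach the
    threshold; otherwise admix.
    """
    if len(set(q.col_subpops)) != len(q.col_subpops):
        raise ValueError("duplicate subpopulation columns in Q matrix")
    unknown = set(q.col_subpops) - set(SUBPOPULATIONS)
    if unknown:
        raise ValueError(f"unknown subpopulations in Q columns: {sorted(unknown)}")
    qn = q.q / q.q.sum(axis=1, keepdims=True)
    xi_cols = [i for i, s in enumerate(q.col_subpops) if s in XI_SUBPOPS]
    gj_cols = [i for i, s in enumerate(q.col_subpops) if s in GJ_SUBPOPS]
    labels = []
    for row in qn:
        m = int(np.argmax(row))
        if row[m] >= threshold:
            labels.append(q.col_subpops[m])
        elif xi_cols and row[xi_cols].sum() >= threshold:
            labels.append("XI-adm")
        elif gj_cols and row[gj_cols].sum() >= threshold:
            labels.append("GJ-adm")
        else:
            labels.append("admix")
    return SubpopAssignment(list(q.sample_ids), labels)
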