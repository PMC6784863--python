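"""Distances, neighbour joining, classical MDS, Q alignment and assignment."""

import numpy as np
import pytest

from _util import make_gm
from panpop.popstruct import (
    DistanceMatrix,
    QMatrix,
    align_and_average_q,
    allele_sharing_distance,
    assign_subpopulations,
    classical_mds,
    nj_tree,
)


class TestAlleleSharingDistance:
    def test_identical_samples_distance_zero(self):
        g = make_gm([[0, 1, 2], [0, 1, 2]])
        for mode in ("ibs", "simple_matching"):
            d = allele_sharing_distance(g, mode=mode, min_co_called=1)
            assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        g = make_gm([[0, 0, 0], [2, 2, 2]])
        for mode in ("ibs", "simple_matching"):
            d = allele_sharing_distance(g, mode=mode, min_co_called=1)
            assert d.values[0, 1] == 1.0

    def test_hand_counted_mixed_pair(self):
        # sites (0,0) and (1,1) are IBS2; (2,0) shares no allele (IBS0):
        # ibs d = 1 - (2 + 0.5*0)/3 = 1/3; simple matching d = 1/3 as well
        g = make_gm([[0, 1, 2], [0, 1, 0]])
        ibs = allele_sharing_distance(g, mode="ibs", min_co_called=1)
        sm = allele_sharing_distance(g, mode="simple_matching", min_co_called=1)
        assert ibs.values[0, 1] == pytest.approx(1 / 3)
        assert sm.values[0, 1] == pytest.approx(1 / 3)

    def test_hand_counted_ibs1_pair(self):
        # sites (0,0) IBS2, (1,1) IBS2, (1,0) IBS1:
        # ibs d = 1 - (2 + 0.5)/3 = 1/6; simple matching d = 1/3
        g = make_gm([[0, 1, 1], [0, 1, 0]])
        ibs = allele_sharing_distance(g, mode="ibs", min_co_called=1)
        sm = allele_sharing_distance(g, mode="simple_matching", min_co_called=1)
        assert ibs.values[0, 1] == pytest.approx(1 / 6)
        assert sm.values[0, 1] == pytest.approx(1 / 3)

    def test_low_co_called_pair_error_names_samples(self):
        g = make_gm([[0, -1], [-1, 2]], sample_ids=["alpha", "beta"])
        with pytest.raises(ValueError, match="alpha.*beta"):
            allele_sharing_distance(g, min_co_called=1)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        dosage[rng.random((6, 40)) < 0.1] = -1
        g = make_gm(dosage)
        d = allele_sharing_distance(g, mode="simple_matching", min_co_called=5)
        for i in range(6):
            for j in range(i + 1, 6):
                ok = (dosage[i] != -1) & (dosage[j] != -1)
                expected = (dosage[i][ok] != dosage[j][ok]).mean()
                assert d.values[i, j] == pytest.approx(expected)


class TestNJTree:
    def test_additive_matrix_reproduced_exactly(self):
        # classic additive 4-taxon matrix (AB|CD with internal branch 1)
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0, 3, 7, 8],
                [3, 0, 6, 7],
                [7, 6, 0, 5],
                [8, 7, 5, 0],
            ],
            dtype=float,
        ) / 10.0
        tree = nj_tree(DistanceMatrix(ids, m))
        for i in range(4):
            for j in range(i + 1, 4):
                path = tree.find(ids[i]).distance(tree.find(ids[j]))
                assert path == pytest.approx(m[i, j], abs=1e-10)

    def test_three_taxa_closed_form_branch_lengths(self):
        ids = ["x", "y", "z"]
        m = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(ids, m))
        # b_x = (d_xy + d_xz - d_yz)/2, etc.
        expected = {"x": 0.1, "y": 0.3, "z": 0.5}
        for tip in tree.tips():
            assert tip.length == pytest.approx(expected[tip.name], abs=1e-10)

    def test_ultrametric_matrix_pairs_closest_taxa(self):
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0, 0.2, 0.8, 0.8],
                [0.2, 0, 0.8, 0.8],
                [0.8, 0.8, 0, 0.4],
                [0.8, 0.8, 0.4, 0],
            ]
        )
        tree = nj_tree(DistanceMatrix(ids, m))
        # single-linkage pairs (a,b) and (c,d); NJ must produce the same split
        a = tree.find("a")
        siblings = {t.name for t in a.parent.tips()}
        assert siblings == {"a", "b"}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]])))


class TestClassicalMDS:
    def test_two_points_at_unit_distance(self):
        d = DistanceMatrix(["p", "q"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        coords, _ = classical_mds(d, dims=1)
        assert sorted(coords[:, 0]) == pytest.approx([-0.5, 0.5])

    def test_planar_configuration_recovered_up_to_rotation(self):
        rng = np.random.default_rng(4)
        pts = rng.random((8, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dist /= dist.max()  # keep within [0, 1]
        pts_scaled = pts / dist.max() if False else pts  # scaling applied to dist only
        d = DistanceMatrix([f"s{i}" for i in range(8)], dist)
        coords, _ = classical_mds(d, dims=2)
        # Procrustes: recovered inter-point distances equal input distances
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(rec, dist, atol=1e-8)

    def test_duplicate_points_identical_coordinates(self):
        m = np.array(
            [[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]], dtype=float
        )
        coords, _ = classical_mds(DistanceMatrix(["a", "b", "c"], m), dims=2)
        assert np.allclose(coords[0], coords[1], atol=1e-10)

    def test_excess_dims_flagged_by_fewer_columns(self):
        d = DistanceMatrix(["p", "q"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        coords, _ = classical_mds(d, dims=5)
        assert coords.shape[1] == 1


def _q(rows, cols, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return QMatrix(ids, rows, cols)


class TestAlignAndAverageQ:
    COLS = ["XI-1A", "GJ-tmp", "cA"]

    def test_single_run_returned_unchanged(self):
        q = _q([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]], self.COLS)
        out = align_and_average_q([q])
        assert np.allclose(out.q, q.q)

    def test_permuted_identical_runs_average_to_one_run(self):
        rng = np.random.default_rng(6)
        base = rng.dirichlet([5, 1, 1], size=20)
        runs = [_q(base, self.COLS)]
        for perm in ([1, 0, 2], [2, 1, 0]):
            runs.append(_q(base[:, perm], self.COLS))
        out = align_and_average_q(runs)
        assert np.allclose(out.q, base, atol=1e-12)

    def test_outlier_run_excluded_from_largest_cluster(self):
        rng = np.random.default_rng(7)
        base = rng.dirichlet([5, 1, 1], size=30)
        outlier = rng.dirichlet([1, 1, 1], size=30)
        runs = [_q(base, self.COLS) for _ in range(4)] + [_q(outlier, self.COLS)]
        out = align_and_average_q(runs)
        assert np.allclose(out.q, base, atol=1e-12)

    def test_mismatched_runs_rejected(self):
        q1 = _q([[0.5, 0.3, 0.2]], self.COLS, ids=["a"])
        q2 = _q([[0.5, 0.3, 0.2]], self.COLS, ids=["b"])
        with pytest.raises(ValueError):
            align_and_average_q([q1, q2])


class TestAssignSubpopulations:
    COLS = ["XI-1A", "XI-2", "GJ-tmp", "cA"]

    def test_dominant_component_assigns_subpopulation(self):
        q = _q([[0.1, 0.70, 0.1, 0.1]], self.COLS)
        assert assign_subpopulations(q).labels == ["XI-2"]

    def test_major_group_sum_assigns_adm(self):
        q = _q([[0.4, 0.3, 0.0, 0.3]], self.COLS)
        assert assign_subpopulations(q).labels == ["XI-adm"]

    def test_split_between_groups_is_admix(self):
        q = _q([[0.25, 0.25, 0.5, 0.0]], self.COLS)
        assert assign_subpopulations(q).labels == ["admix"]

    def test_scale_invariant_to_row_renormalization(self):
        rng = np.random.default_rng(8)
        rows = rng.dirichlet([3, 2, 2, 1], size=50)
        labels1 = assign_subpopulations(_q(rows, self.COLS)).labels
        jitter = rows * (1 + (rng.random(rows.shape) - 0.5) * 2e-7)
        labels2 = assign_subpopulations(_q(jitter, self.COLS)).labels
        assert labels1 == labels2

    def test_duplicate_columns_rejected(self):
        with pytest.raises(ValueError):
            assign_subpopulations(
                _q([[0.5, 0.5]], ["XI-1A", "XI-1A"])
            )

    def test_planted_dirichlet_rows_recovered(self):
        """Concentrated Dirichlet Q rows recover >= 99% of true labels."""
        rng = np.random.default_rng(9)
        cols = ["XI-1A", "XI-2", "GJ-tmp", "cA"]
        truth, rows = [], []
        for i in range(400):
            k = i % 4
            alpha = np.full(4, 0.05)
            alpha[k] = 20.0
            rows.append(rng.dirichlet(alpha))
            truth.append(cols[k])
        labels = assign_subpopulations(_q(np.asarray(rows), cols)).labels
        acc = np.mean([a == b for a, b in zip(labels, truth)])
        assert acc >= 0.99
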