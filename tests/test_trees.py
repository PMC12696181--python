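"""Distance matrices, Ward clustering, NJ/BIONJ and bootstrap supports."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from phylophen.synthetic import DivergenceSpec, evolve_pair
from phylophen.trees import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    read_newick,
    tree_tip_distance_matrix,
    ward_cluster,
    write_newick,
)

from conftest import random_additive_tree


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], data=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(labels=["a", "b"], data=np.array([[1.0, 1], [1, 0]]))
        with pytest.raises(ValueError, match="duplicate"):
            DistanceMatrix(labels=["a", "a"], data=np.zeros((2, 2)))

    def test_phylip_round_trip(self, tmp_path, rng):
        x = rng.random((4, 4))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        m = DistanceMatrix(labels=list("abcd"), data=d)
        p = tmp_path / "m.phylip"
        m.to_phylip(p)
        m2 = DistanceMatrix.from_phylip(p)
        assert m2.labels == m.labels
        assert np.allclose(m2.data, m.data)


class TestWard:
    def test_one_dimensional_points_merge_order(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        d = squareform(pdist(pts))
        m = DistanceMatrix(labels=["a", "b", "c"], data=d)
        _, merges = ward_cluster(m)
        assert merges[0][:2] == ("a", "b")  # {0,1} joined first

    def test_identical_labels_merge_at_zero(self):
        d = np.array([[0, 0, 5.0], [0, 0, 5.0], [5.0, 5.0, 0]])
        m = DistanceMatrix(labels=["a", "b", "c"], data=d)
        _, merges = ward_cluster(m)
        assert merges[0] == ("a", "b", 0.0)

    def test_monotone_heights(self, rng):
        for _ in range(10):
            pts = rng.random((8, 3))
            m = DistanceMatrix(
                labels=[f"t{i}" for i in range(8)], data=squareform(pdist(pts))
            )
            _, merges = ward_cluster(m)
            heights = [h for _, _, h in merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_matches_scipy_linkage_heights(self, rng):
        # same Lance-Williams recurrence as scipy's 'ward' on euclidean input
        for trial in range(5):
            pts = rng.random((7, 4))
            cond = pdist(pts)
            m = DistanceMatrix(
                labels=[f"t{i}" for i in range(7)], data=squareform(cond)
            )
            _, merges = ward_cluster(m)
            ours = sorted(h for _, _, h in merges)
            scipys = sorted(linkage(cond, method="ward")[:, 2])
            assert np.allclose(ours, scipys, atol=1e-9)

    def test_outlier_attaches_last(self, rng):
        # one profile far from two tight groups joins at the final merge
        pts = np.vstack([rng.normal(0, 0.01, (3, 5)),
                         rng.normal(1, 0.01, (3, 5)),
                         np.full((1, 5), 10.0)])
        labels = [f"g{i}" for i in range(6)] + ["outlier"]
        m = DistanceMatrix(labels=labels, data=squareform(pdist(pts)))
        _, merges = ward_cluster(m)
        assert "outlier" in merges[-1][:2]


class TestNJ:
    @pytest.mark.parametrize("method", ["nj", "bionj"])
    def test_additive_matrices_recovered_exactly(self, method, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            tr = random_additive_tree(n, rng)
            dm = tree_tip_distance_matrix(tr)
            rec = nj_tree(dm, method=method)
            dm2 = tree_tip_distance_matrix(rec)
            idx = [dm2.labels.index(l) for l in dm.labels]
            assert np.allclose(dm.data, dm2.data[np.ix_(idx, idx)], atol=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        m = DistanceMatrix(labels=["a", "b", "c"], data=d)
        t = nj_tree(m)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_fewer_than_three_rejected(self):
        m = DistanceMatrix(labels=["a", "b"], data=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_agrees_with_skbio_nj_topology(self, rng):
        import skbio

        tr = random_additive_tree(6, rng)
        dm = tree_tip_distance_matrix(tr)
        ours = nj_tree(dm, method="nj")
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(dm.data, ids=dm.labels)
        )
        assert ours.compare_rfd(theirs) == 0.0

    def test_ultrametric_matrix_matches_ward_topology(self, rng):
        # ultrametric distances: both methods reduce to the same grouping
        tr = random_additive_tree(5, rng)
        dmw = tree_tip_distance_matrix(tr)
        # build an ultrametric matrix from a Ward dendrogram of it
        dendro, merges = ward_cluster(dmw)
        um = tree_tip_distance_matrix(dendro)
        njt = nj_tree(um)
        assert njt.compare_rfd(dendro.copy()) == 0.0


class TestNewick:
    def test_round_trip_lossless(self, rng):
        tr = random_additive_tree(7, rng)
        for node, support in zip(tr.non_tips(), [0.9, 0.85, 1.0]):
            node.name = f"{support}"
        text = write_newick(tr)
        back = read_newick(text)
        assert sorted(t.name for t in back.tips()) == sorted(
            t.name for t in tr.tips()
        )
        d1 = tree_tip_distance_matrix(tr)
        d2 = tree_tip_distance_matrix(back)
        idx = [d2.labels.index(l) for l in d1.labels]
        assert np.allclose(d1.data, d2.data[np.ix_(idx, idx)], atol=1e-9)
        assert {n.name for n in back.non_tips()} >= {"0.9", "0.85", "1.0"}

    def test_newick_file_io(self, tmp_path, rng):
        tr = random_additive_tree(5, rng)
        p = tmp_path / "t.nwk"
        write_newick(tr, p)
        back = read_newick(p)
        assert back.compare_rfd(tr) == 0.0


class TestBootstrap:
    def _four_separated_genomes(self):
        genomes = []
        for i, seed in enumerate([21, 22]):
            a, b, _ = evolve_pair(
                DivergenceSpec(ancestor_length=30_000, substitution_rate=0.02,
                               seed=seed)
            )
            a.id, b.id = f"pair{i}_a", f"pair{i}_b"
            genomes += [a, b]
        return genomes

    def test_clean_separation_full_support(self):
        genomes = self._four_separated_genomes()
        tree = bootstrap_support(genomes, reps=50, seed=3)
        supports = [n.support for n in tree.non_tips(include_self=False)]
        assert supports and all(s == pytest.approx(1.0) for s in supports)

    def test_single_rep_supports_binary(self):
        genomes = self._four_separated_genomes()
        tree = bootstrap_support(genomes, reps=1, seed=3)
        assert all(
            n.support in (0.0, 1.0) for n in tree.non_tips(include_self=False)
        )

    def test_star_like_distances_low_support(self, rng):
        # five descendants of one ancestor, each independently mutated at the
        # same high rate: a star radiation where resampling noise dominates
        from phylophen.genome import GenomeRecord

        anc = rng.integers(0, 4, size=20_000)
        genomes = []
        for i in range(5):
            codes = anc.copy()
            pos = rng.random(codes.size) < 0.15
            codes[pos] = (codes[pos] + rng.integers(1, 4, pos.sum())) % 4
            seq = "".join("ACGT"[c] for c in codes)
            genomes.append(GenomeRecord(id=f"star{i}", scaffolds=[("chr1", seq)]))
        tree = bootstrap_support(genomes, reps=50, seed=4)
        supports = [n.support for n in tree.non_tips(include_self=False)]
        assert min(supports) < 0.9
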