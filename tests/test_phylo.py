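"""Distances, NJ, the nesting test, and UPGMA activity histories."""

import itertools

import dendropy
import numpy as np
import pytest

from htt import phylo, simulate
from htt.phylo import DistanceMatrix


class TestPDistance:
    def test_simple_mismatch(self):
        assert phylo.p_distance("ACGT", "ACGA") == 0.25

    def test_pairwise_deletion_skips_gap_columns(self):
        assert phylo.p_distance("AC-T", "ACGT") == 0.0

    def test_no_retained_columns_raises(self):
        with pytest.raises(ValueError, match="retained"):
            phylo.p_distance("--", "AC")

    @pytest.mark.parametrize("seed", range(10))
    def test_column_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alpha = "ACGT-N"
        a = "".join(rng.choice(list(alpha), size=200))
        b = "".join(rng.choice(list(alpha), size=200))
        mism = kept = 0
        for x, y in zip(a, b):
            if x in "-N" or y in "-N":
                continue
            kept += 1
            mism += x != y
        if kept == 0:
            pytest.skip("degenerate draw")
        assert phylo.p_distance(a, b) == pytest.approx(mism / kept)


def _random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths."""
    labels = [f"T{i}" for i in range(n)]
    nodes = [(lab,) for lab in labels]
    parent = {}
    lengths = {}
    next_id = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = f"N{next_id}"
        next_id += 1
        for child in (nodes[i], nodes[j]):
            parent[child] = new
            lengths[child] = float(rng.uniform(0.5, 3.0))
        nodes = [n_ for k, n_ in enumerate(nodes) if k not in (i, j)] + [(new,)]
        parent[(new,)] = None
    # path lengths via dendropy for independence
    def newick(node):
        children = [c for c, p in parent.items() if p == node[0]]
        if not children:
            return node[0]
        return "(" + ",".join(f"{newick(c)}:{lengths[c]}" for c in children) + ")"

    tree = dendropy.Tree.get(data=newick(nodes[0]) + ";", schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        d[a, b] = d[b, a] = pdm.distance(taxa[labels[a]], taxa[labels[b]])
    return DistanceMatrix(labels=labels, d=d)


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        tree = phylo.nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(3.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(5.0)
        assert pdm.distance(taxa["B"], taxa["C"]) == pytest.approx(6.0)

    def test_four_taxon_split_and_lengths(self):
        # additive AB|CD matrix: a=2,b=3,c=4,d=5, internal edge 1
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = phylo.nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        bip = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in tree.preorder_edge_iter()
            if e.tail_node is not None
        }
        assert frozenset({"A", "B"}) in bip or frozenset({"C", "D"}) in bip
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_fewer_than_three_raises(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            phylo.nj_tree(dm)

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrices_reproduced_exactly(self, seed):
        rng = np.random.default_rng(seed)
        dm = _random_additive_matrix(rng, int(rng.integers(4, 9)))
        tree = phylo.nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(len(dm.labels)), 2):
            got = pdm.distance(taxa[dm.labels[i]], taxa[dm.labels[j]])
            assert got == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(42)
        dm = _random_additive_matrix(rng, 6)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            [dm.labels[p] for p in perm], dm.d[np.ix_(perm, perm)]
        )
        def bipartitions(tree):
            all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            out = set()
            for e in tree.preorder_edge_iter():
                if e.tail_node is None:
                    continue
                side = frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(min(side, all_leaves - side, key=sorted))
            return out
        assert bipartitions(phylo.nj_tree(dm)) == bipartitions(phylo.nj_tree(dm2))

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        dm = _random_additive_matrix(rng, 7)
        noise = rng.uniform(0, 0.05, size=dm.d.shape)
        d = dm.d + noise + noise.T
        np.fill_diagonal(d, 0)
        dm_noisy = DistanceMatrix(dm.labels, d)
        import io

        ours = phylo.nj_tree(dm_noisy)
        buf = io.StringIO()
        skbio_nj(SkbioDM(d, dm.labels)).write(buf)
        theirs = dendropy.Tree.get(
            data=buf.getvalue(),
            schema="newick",
            taxon_namespace=ours.taxon_namespace,
        )
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert (
            dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0
        )


class TestNestingTest:
    def test_recipient_nested(self):
        t = dendropy.Tree.get(data="((D1,(D2,(R1,R2))),D3);", schema="newick")
        assert phylo.nesting_test(t, {"D1", "D2", "D3"}, {"R1", "R2"}) == (
            "recipient_nested_in_donor"
        )

    def test_donor_nested(self):
        t = dendropy.Tree.get(data="((R1,(R2,(D1,D2))),R3);", schema="newick")
        assert phylo.nesting_test(t, {"D1", "D2"}, {"R1", "R2", "R3"}) == (
            "donor_nested_in_recipient"
        )

    def test_balanced_split_not_nested(self):
        t = dendropy.Tree.get(data="((D1,D2),(R1,R2));", schema="newick")
        assert phylo.nesting_test(t, {"D1", "D2"}, {"R1", "R2"}) == "not_nested"

    def test_missing_label_raises(self):
        t = dendropy.Tree.get(data="((D1,D2),(R1,R2));", schema="newick")
        with pytest.raises(ValueError, match="missing"):
            phylo.nesting_test(t, {"D1", "D9"}, {"R1", "R2"})

    def test_simulated_transfers_read_as_nested(self):
        """Donor diversity predating the transfer yields the nested verdict."""
        rng = np.random.default_rng(0)
        n_ok = 0
        n_sims = 100
        for sim in range(n_sims):
            ancestor = simulate.random_dna(400, rng)
            donors = {}
            for i, div in enumerate((10.0, 8.0, 6.0, 5.0, 4.0, 3.0)):
                donors[f"D{i}"] = simulate.mutate(
                    ancestor, div, seed=sim * 100 + i
                ).seq
            # the transfer comes from an unsampled relative of one donor
            # lineage; sampled donor copies are its cousins
            source = simulate.mutate(donors["D5"], 2.0, seed=sim * 100 + 40).seq
            recips = {
                f"R{i}": simulate.mutate(source, 0.5, seed=sim * 100 + 50 + i).seq
                for i in range(3)
            }
            seqs = {**donors, **recips}
            labels = sorted(seqs)
            dm = phylo.p_distance_matrix(labels, [seqs[l] for l in labels])
            tree = phylo.nj_tree(dm)
            verdict = phylo.nesting_test(tree, set(donors), set(recips))
            n_ok += verdict == "recipient_nested_in_donor"
        assert n_ok >= 0.95 * n_sims


class TestUpgmaHistory:
    def test_worked_example_heights(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float),
            metric="identity_distance",
        )
        hist = phylo.upgma_history(dm)
        assert hist.node_heights == [1.0, 4.0]
        assert hist.merge_distances == [2.0, 8.0]
        assert hist.histogram == {1: 1, 4: 1}

    def test_identical_leaves_all_zero(self):
        n = 5
        dm = DistanceMatrix(
            [f"L{i}" for i in range(n)], np.zeros((n, n)),
            metric="identity_distance",
        )
        hist = phylo.upgma_history(dm)
        assert hist.node_heights == [0.0] * (n - 1)
        assert hist.histogram == {0: n - 1}

    def test_single_leaf_raises(self):
        with pytest.raises(ValueError):
            phylo.upgma_history(DistanceMatrix(["A"], np.zeros((1, 1))))

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_monotone_and_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        x = rng.uniform(0, 30, size=(n, n))
        d = np.triu(x, 1)
        d = d + d.T
        dm = DistanceMatrix([f"L{i}" for i in range(n)], d,
                            metric="identity_distance")
        hist = phylo.upgma_history(dm)
        assert len(hist.node_heights) == n - 1
        assert hist.node_heights == sorted(hist.node_heights)
        assert sum(hist.histogram.values()) == n - 1

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_scipy_average_linkage(self, seed):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(seed)
        n = 8
        x = rng.uniform(1, 40, size=(n, n))
        d = np.triu(x, 1)
        d = d + d.T
        dm = DistanceMatrix([f"L{i}" for i in range(n)], d,
                            metric="identity_distance")
        hist = phylo.upgma_history(dm)
        Z = linkage(squareform(d), method="average")
        np.testing.assert_allclose(
            sorted(hist.merge_distances), sorted(Z[:, 2]), atol=1e-9
        )

    def test_amplification_burst_peaks_low(self):
        """One amplification episode at ~2% divergence concentrates the
        branching points in the 0-2% height bins."""
        rng = np.random.default_rng(7)
        ancestor = simulate.random_dna(600, rng)
        copies = {f"C{i}": simulate.mutate(ancestor, 1.0, seed=900 + i).seq
                  for i in range(12)}
        labels = sorted(copies)
        dm = phylo.p_distance_matrix(labels, [copies[l] for l in labels])
        dm_ident = DistanceMatrix(labels, dm.d * 100.0, "identity_distance")
        hist = phylo.upgma_history(dm_ident)
        peak = max(hist.histogram, key=hist.histogram.get)
        assert peak in (0, 1, 2)
        assert max(hist.node_heights) < 4.0
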