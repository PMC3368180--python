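import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgene_atlas.phylogeny import (
    DistanceMatrix,
    Node,
    SaturatedDistanceError,
    bipartitions,
    bootstrap,
    distance_matrix,
    from_newick,
    gblocks_lite,
    k2p_distance,
    nj,
    p_distance,
    poisson_distance,
    to_newick,
)


def random_tree(n, rng):
    nodes = [Node(name=f"t{i:02d}", branch_length=float(rng.uniform(0.05, 1.0))) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(
            children=[nodes[i], nodes[j]], branch_length=float(rng.uniform(0.05, 1.0))
        )
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    return Node(children=nodes)


def path_distances(tree):
    parent = {}

    def walk(nd):
        for c in nd.children:
            parent[id(c)] = nd
            walk(c)

    walk(tree)
    leaves = tree.leaves()

    def path(nd):
        out = []
        while id(nd) in parent:
            out.append(nd)
            nd = parent[id(nd)]
        return out

    names = [l.name for l in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for a in range(n):
        pa = path(leaves[a])
        sa = {id(x) for x in pa}
        for b in range(a + 1, n):
            pb = path(leaves[b])
            sb = {id(x) for x in pb}
            dist = sum(x.branch_length for x in pa if id(x) not in sb)
            dist += sum(x.branch_length for x in pb if id(x) not in sa)
            d[a, b] = d[b, a] = dist
    return names, d


class TestDistances:
    def test_identical_sequences_have_zero_distance(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0
        assert poisson_distance("MKLV", "MKLV") == 0.0

    def test_k2p_closed_form(self):
        # 80 identical sites, 10 transitions (A->G), 10 transversions (C->A)
        a = "A" * 80 + "A" * 10 + "C" * 10
        b = "A" * 80 + "G" * 10 + "A" * 10
        expected = -0.5 * math.log((1 - 2 * 0.1 - 0.1) * math.sqrt(1 - 2 * 0.1))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_k2p_saturation(self):
        a = "A" * 50 + "C" * 50
        b = "G" * 50 + "C" * 50  # P = 0.5, Q = 0 -> log-domain boundary
        with pytest.raises(SaturatedDistanceError):
            k2p_distance(a, b)

    def test_k2p_excludes_gap_and_ambiguous_sites_pairwise(self):
        assert k2p_distance("ACGT-N", "ACGTAC") == 0.0

    def test_poisson_closed_form(self):
        assert poisson_distance("AAAA", "AACC") == pytest.approx(math.log(2))

    def test_poisson_saturation(self):
        with pytest.raises(SaturatedDistanceError):
            poisson_distance("AAAA", "CCCC")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_corrections_inflate_raw_distance(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = "".join(
            c if rng.random() > 0.2 else "ACGT"[rng.integers(4)] for c in a
        )
        p = p_distance(a, b)
        try:
            assert k2p_distance(a, b) >= p - 1e-12
        except SaturatedDistanceError:
            pass
        aa = "".join(rng.choice(list("ACDEFGHIKL"), size=n))
        bb = "".join(c if rng.random() > 0.3 else "M" for c in aa)
        assert poisson_distance(aa, bb) >= p_distance(bb, aa, protein=True)


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj(DistanceMatrix(["A", "B", "C"], d))
        lengths = {l.name: l.branch_length for l in tree.leaves()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-9)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2, abs=1e-9)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2, abs=1e-9)

    def test_fewer_than_three_taxa_is_hard_error(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]])))

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        rng = np.random.default_rng(11)
        tree0 = random_tree(5, rng)
        names, d = path_distances(tree0)
        tree1 = nj(DistanceMatrix(names, d))
        assert bipartitions(tree1) == bipartitions(tree0)
        # path distances on the reconstructed tree reproduce the input
        n1, dd = path_distances(tree1)
        idx = {nm: i for i, nm in enumerate(n1)}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert dd[idx[a], idx[b]] == pytest.approx(d[i, j], abs=1e-9)

    def test_equal_distances_are_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        taxa = ["D", "C", "B", "A"]
        t1 = to_newick(nj(DistanceMatrix(taxa, d.copy())))
        t2 = to_newick(nj(DistanceMatrix(taxa, d.copy())))
        assert t1 == t2

    @settings(max_examples=25, deadline=None)
    @given(st.integers(4, 12), st.integers(0, 10**6))
    def test_additive_recovery_property(self, n, seed):
        rng = np.random.default_rng(seed)
        tree0 = random_tree(n, rng)
        names, d = path_distances(tree0)
        tree1 = nj(DistanceMatrix(names, d))
        assert bipartitions(tree1) == bipartitions(tree0)

    def test_topology_agrees_with_dendropy(self):
        """Cross-check against dendropy's independent NJ implementation."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            tree0 = random_tree(8, rng)
            names, d = path_distances(tree0)
            mine = nj(DistanceMatrix(names, d))
            csv = "," + ",".join(names) + "\n"
            for i, nm in enumerate(names):
                csv += nm + "," + ",".join(str(x) for x in d[i]) + "\n"
            import io

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(names)
            )
            theirs = pdm.nj_tree()
            tns = theirs.taxon_namespace
            mine_dp = dendropy.Tree.get(
                data=to_newick(mine), schema="newick", taxon_namespace=tns
            )
            theirs.encode_bipartitions()
            mine_dp.encode_bipartitions()
            assert (
                dendropy.calculate.treecompare.symmetric_difference(theirs, mine_dp) == 0
            )


class TestBootstrap:
    def alignment(self):
        # two clean clades (t0,t1) vs (t2,t3): every column supports the split
        return [
            ("t0", "AAAAAAAACC"),
            ("t1", "AAAAAAAACC"),
            ("t2", "CCCCCCCCAA"),
            ("t3", "CCCCCCCCAA"),
            ("t4", "ACACACACAC"),
        ]

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap(self.alignment(), n_reps=50, seed=9, distance_mode="p")
        t2 = bootstrap(self.alignment(), n_reps=50, seed=9, distance_mode="p")
        assert to_newick(t1) == to_newick(t2)

    def test_congruent_alignment_gives_full_support(self):
        tree = bootstrap(self.alignment(), n_reps=100, seed=1, distance_mode="p")

        def supports(node):
            out = []
            if node.support is not None:
                out.append(node.support)
            for c in node.children:
                out.extend(supports(c))
            return out

        assert all(s == 100 for s in supports(tree))
        assert frozenset({"t0", "t1"}) in bipartitions(tree) or frozenset(
            {"t2", "t3", "t4"}
        ) in bipartitions(tree)

    def test_supports_bounded(self):
        rng = np.random.default_rng(5)
        aln = [(f"t{i}", "".join(rng.choice(list("ACGT"), size=40))) for i in range(6)]
        tree = bootstrap(aln, n_reps=30, seed=2, distance_mode="p")

        def supports(node):
            out = [] if node.support is None else [node.support]
            for c in node.children:
                out.extend(supports(c))
            return out

        assert all(0 <= s <= 100 for s in supports(tree))

    def test_too_few_columns_is_hard_error(self):
        with pytest.raises(ValueError):
            bootstrap([("a", "A"), ("b", "C"), ("c", "G")], n_reps=5, seed=0, distance_mode="p")


class TestGblocksLite:
    def test_conserved_gapfree_alignment_unchanged(self):
        aln = [("a", "MKLV"), ("b", "MKLV"), ("c", "MKLV")]
        trimmed, retained = gblocks_lite(aln)
        assert trimmed == aln and retained == [0, 1, 2, 3]

    def test_all_gap_column_removed(self):
        aln = [("a", "M-KV"), ("b", "M-KV"), ("c", "M-KV")]
        trimmed, retained = gblocks_lite(aln)
        assert retained == [0, 2, 3]

    def test_everything_removed_is_hard_error(self):
        aln = [("a", "--"), ("b", "--"), ("c", "--")]
        with pytest.raises(ValueError):
            gblocks_lite(aln)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_retained_set_matches_per_column_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, cols = 6, 30
        aln = []
        for i in range(n):
            aln.append(
                (
                    f"s{i}",
                    "".join(
                        "-" if rng.random() < 0.3 else "AC"[rng.integers(2)]
                        for _ in range(cols)
                    ),
                )
            )
        expected = []
        for c in range(cols):
            col = [s[c] for _n, s in aln]
            residues = [x for x in col if x != "-"]
            if len(residues) / len(col) < 0.5:
                continue
            modal = max(residues.count(x) for x in set(residues))
            if modal / len(residues) >= 0.5:
                expected.append(c)
        if not expected:
            with pytest.raises(ValueError):
                gblocks_lite(aln)
        else:
            _trimmed, retained = gblocks_lite(aln)
            assert retained == expected


class TestDistanceMatrixContainer:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))

    def test_mode_dispatch(self):
        aln = [("a", "AAAA"), ("b", "AACC"), ("c", "CCCC")]
        dm = distance_matrix(aln, "p")
        assert dm.d[0, 1] == pytest.approx(0.5)
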