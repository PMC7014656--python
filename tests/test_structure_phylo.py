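"""structure_phylo: distances, NJ recovery on additive matrices, Newick
round-trips, bootstrap support, PCA properties."""
import numpy as np
import pytest

from domestiscan import structure_phylo as sp
from domestiscan import synthetic_data as sd
from domestiscan.errors import ValidationError
from domestiscan.variant_io import PopulationGrouping

from conftest import make_gm


def random_additive_tree(n_taxa, rng):
    """Random binary topology with branch lengths in [0.1, 1]; returns
    (Tree, DistanceMatrix) where distances are exact path lengths."""
    import networkx as nx

    labels = [f"t{i}" for i in range(n_taxa)]
    g = nx.Graph()
    nodes = list(labels)
    nxt = 0
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = f"int{nxt}"
        nxt += 1
        g.add_edge(parent, a, weight=float(rng.uniform(0.1, 1.0)))
        g.add_edge(parent, b, weight=float(rng.uniform(0.1, 1.0)))
        nodes = [x for x in nodes if x not in (a, b)] + [parent]
    center = f"int{nxt}"
    for x in nodes:
        g.add_edge(center, x, weight=float(rng.uniform(0.1, 1.0)))

    d = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n_taxa):
        for j in range(n_taxa):
            d[i, j] = lengths[labels[i]][labels[j]]

    # true bipartitions: remove each internal edge, collect one side
    ref = min(labels)
    parts = set()
    for u, v in list(g.edges):
        if u in labels or v in labels:
            continue
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(l for l in labels if nx.has_path(h, l, u))
        if ref in side:
            side = frozenset(labels) - side
        if 2 <= len(side) <= n_taxa - 2:
            parts.add(side)
    return parts, sp.DistanceMatrix(labels, d)


class TestPairwiseDistance:
    def test_identical_and_opposite(self):
        gm = make_gm([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        dm = sp.pairwise_distance(gm)
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] == pytest.approx((2 + 2 + 0) / (2 * 3))

    def test_opposite_homozygotes_distance_one(self):
        gm = make_gm([[0, 0, 0], [2, 2, 2]])
        assert sp.pairwise_distance(gm).d[0, 1] == 1.0

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(6)
        dos = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
        gm = make_gm(dos)
        dm = sp.pairwise_distance(gm)
        for i in range(10):
            for j in range(10):
                m = (dos[i] >= 0) & (dos[j] >= 0)
                expect = np.abs(dos[i][m] - dos[j][m]).mean() / 2
                assert abs(dm.d[i, j] - expect) < 1e-12

    def test_site_order_invariance(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        perm = rng.permutation(40)
        d1 = sp.pairwise_distance(make_gm(dos)).d
        d2 = sp.pairwise_distance(make_gm(dos[:, perm])).d
        assert np.allclose(d1, d2)

    def test_no_shared_sites_is_error(self):
        gm = make_gm([[1, -1], [-1, 1]])
        with pytest.raises(ValidationError, match="share no called sites"):
            sp.pairwise_distance(gm)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # ((A,B),(C,D)) with all five branches length 1
        labels = list("ABCD")
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = sp.nj_tree(sp.DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # leaf branch lengths are all exactly 1
        lengths = {}

        def walk(node):
            for child, ln in node.children:
                if child.is_leaf:
                    lengths[child.name] = ln
                walk(child)

        walk(tree.root)
        assert lengths == {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0}

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = sp.nj_tree(sp.DistanceMatrix(list("ABC"), d))
        got = {c.name: ln for c, ln in tree.root.children}
        assert got == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_star_tie_break_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        dm = sp.DistanceMatrix(list("ABCDE"), d)
        t1 = sp.write_newick(sp.nj_tree(dm))
        t2 = sp.write_newick(sp.nj_tree(dm))
        assert t1 == t2

    def test_invalid_matrix_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValidationError):
            sp.nj_tree(sp.DistanceMatrix(["a", "b"], d))

    def test_random_additive_recovery(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            parts, dm = random_additive_tree(8, rng)
            tree = sp.nj_tree(dm)
            assert tree.bipartitions() == parts


class TestNewick:
    def test_three_taxon_form(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        nwk = sp.write_newick(sp.nj_tree(sp.DistanceMatrix(list("ABC"), d)))
        assert nwk == "(A:1,B:1,C:1);"

    def test_label_quoting(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        nwk = sp.write_newick(
            sp.nj_tree(sp.DistanceMatrix(["sample 1", "b", "c"], d))
        )
        assert "'sample 1'" in nwk

    def test_roundtrip_bipartitions_via_dendropy(self):
        """Writing then parsing 50 random trees preserves the bipartition
        set (checked with an independent Newick parser)."""
        import dendropy

        rng = np.random.default_rng(33)
        for _ in range(50):
            _, dm = random_additive_tree(8, rng)
            tree = sp.nj_tree(dm)
            nwk = sp.write_newick(tree)
            dt = dendropy.Tree.get(data=nwk, schema="newick")
            labels = frozenset(l.taxon.label for l in dt.leaf_node_iter())
            ref = min(labels)
            parts = set()
            for node in dt.preorder_internal_node_iter(exclude_seed_node=True):
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if ref in side:
                    side = labels - side
                if 2 <= len(side) <= len(labels) - 2:
                    parts.add(side)
            assert parts == tree.bipartitions()


class TestBootstrap:
    @staticmethod
    def _two_pop_gm(seed=5, F=0.3, n_per=8, L=500):
        rng = np.random.default_rng(seed)
        anc = rng.uniform(0.1, 0.9, size=L)
        dos = []
        for _ in range(2):
            p = rng.beta(anc * (1 - F) / F, (1 - anc) * (1 - F) / F)
            dos.append(rng.binomial(2, p[None, :], size=(n_per, L)))
        return make_gm(np.vstack(dos).astype(np.int8), spacing=10)

    def test_population_split_high_support(self):
        gm = self._two_pop_gm()
        tree = sp.bootstrap_support(gm, n_replicates=100, seed=1)
        split = frozenset(gm.samples[8:])
        supports = {
            frozenset(n.leaves()): n.support for n in tree.internal_nodes()
        }
        # normalize side like bipartitions() does
        all_leaves = frozenset(gm.samples)
        ref = min(all_leaves)
        norm = {
            (k if ref not in k else all_leaves - k): v for k, v in supports.items()
        }
        assert norm[split] >= 0.99

    def test_single_replicate_supports_are_binary(self):
        gm = self._two_pop_gm()
        tree = sp.bootstrap_support(gm, n_replicates=1, seed=2)
        sups = {n.support for n in tree.internal_nodes() if n.support is not None}
        assert sups <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self):
        gm = self._two_pop_gm()
        a = sp.write_newick(sp.bootstrap_support(gm, n_replicates=10, seed=9))
        b = sp.write_newick(sp.bootstrap_support(gm, n_replicates=10, seed=9))
        assert a == b


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        gm = TestBootstrap._two_pop_gm(seed=11, F=0.3, n_per=10, L=800)
        coords, explained = sp.pca(gm, n_components=4)
        pc1 = coords["PC1"].to_numpy()
        a, b = pc1[:10], pc1[10:]
        between = abs(a.mean() - b.mean())
        within = np.sqrt((a.var() + b.var()) / 2)
        assert between > 2 * within

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(14)
        dos = rng.integers(0, 3, size=(6, 100)).astype(np.int8)
        dos[3] = dos[0]
        coords, _ = sp.pca(make_gm(dos), n_components=3)
        assert np.allclose(coords.iloc[0].to_numpy(), coords.iloc[3].to_numpy())

    def test_explained_fractions_spectral_properties(self):
        gm = TestBootstrap._two_pop_gm(seed=15)
        _, explained = sp.pca(gm, n_components=6)
        assert explained.sum() <= 1 + 1e-9
        assert (np.diff(explained) <= 1e-12).all()

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(21)
        dos = rng.integers(0, 3, size=(10, 300)).astype(np.int8)
        gm1 = make_gm(dos)
        perm = rng.permutation(10)
        gm2 = make_gm(dos[perm], samples=[f"s{i + 1}" for i in perm])
        c1, _ = sp.pca(gm1, n_components=3)
        c2, _ = sp.pca(gm2, n_components=3)
        c2 = c2.loc[c1.index]
        for col in c1.columns:
            assert np.allclose(c1[col], c2[col], atol=1e-8) or np.allclose(
                c1[col], -c2[col], atol=1e-8
            )
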