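"""NJ, bootstrap, consensus, RELL topology tests, parsimony origins."""

import itertools

import dendropy
import numpy as np
import pytest

from lhc_origins import bundled_character_matrix, bundled_species_tree
from lhc_origins.evolve_models import AA_ORDER, RateModel
from lhc_origins.seqio import Alignment, SeqRecord, read_newick, write_newick
from lhc_origins.synthetic_data import evolve
from lhc_origins.trees_tests import (CharacterMatrix, DistanceMatrix,
                                     bootstrap_support, consensus,
                                     distance_matrix, elw, fitch,
                                     infer_origins, nj, sh_test)


def _splits(tree):
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            out.add(min(side, frozenset(labels - side), key=sorted))
    return out


class TestNeighborJoining:
    ADDITIVE = DistanceMatrix(
        ["A", "B", "C", "D"],
        np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 dtype=float))

    def test_additive_matrix_recovered_exactly(self):
        # distances generated on ((A:1,B:2):1,(C:3,D:4))
        tree = nj(self.ADDITIVE)
        assert frozenset({"A", "B"}) in _splits(tree)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_unique_topology(self):
        t = nj(DistanceMatrix(["A", "B", "C"],
                              np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.]])))
        assert {l.taxon.label for l in t.leaf_node_iter()} == {"A", "B", "C"}

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_robust_to_small_perturbations(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            noise = rng.uniform(-0.01, 0.01, size=(4, 4))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            d = self.ADDITIVE.matrix * (1 + noise)
            tree = nj(DistanceMatrix(list("ABCD"), d))
            assert frozenset({"A", "B"}) in _splits(tree)

    def test_invariant_to_taxon_order(self):
        rng = np.random.default_rng(3)
        labels = list("ABCDEF")
        d = rng.uniform(0.5, 2.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        base = _splits(nj(DistanceMatrix(labels, d)))
        for _ in range(5):
            perm = rng.permutation(6)
            shuffled = nj(DistanceMatrix([labels[i] for i in perm],
                                         d[np.ix_(perm, perm)]))
            assert _splits(shuffled) == base

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check of the NJ topology against skbio."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        n = 7
        d = rng.uniform(0.5, 3.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        ours = nj(DistanceMatrix(labels, d))
        theirs_nwk = str(skbio.tree.nj(
            skbio.DistanceMatrix(d, ids=labels))).strip()
        theirs = read_newick(theirs_nwk)
        assert _splits(ours) == _splits(theirs)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def boot_tree(self, dayhoff):
        rng = np.random.default_rng(42)
        root = SeqRecord("r", "".join(rng.choice(list(AA_ORDER), 2000)))
        sim = dendropy.Tree.get(
            data="((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.0);", schema="newick")
        aln = Alignment(evolve(root, sim, dayhoff, seed=rng))
        return aln, bootstrap_support(aln, dayhoff, B=100, seed=3)

    def test_supports_in_range(self, boot_tree):
        _, tree = boot_tree
        sup = [float(n.label) for n in tree.preorder_internal_node_iter()
               if n.label]
        assert sup and all(0 <= s <= 100 for s in sup)

    def test_long_internal_branch_strongly_supported(self, boot_tree):
        _, tree = boot_tree
        assert frozenset({"A", "B"}) in _splits(tree)
        sup = [float(n.label) for n in tree.preorder_internal_node_iter()
               if n.label]
        assert max(sup) >= 95

    def test_reproducible_under_seed(self, boot_tree, dayhoff):
        aln, tree = boot_tree
        again = bootstrap_support(aln, dayhoff, B=100, seed=3)
        assert write_newick(again) == write_newick(tree)

    def test_too_few_taxa_rejected(self, dayhoff):
        aln = Alignment([SeqRecord("A", "MM"), SeqRecord("B", "MM"),
                         SeqRecord("C", "MM")])
        with pytest.raises(ValueError):
            bootstrap_support(aln, dayhoff, B=10)


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [read_newick("((A,B),(C,D),E);") for _ in range(3)]
        c = consensus(trees)
        assert _splits(c) == _splits(trees[0])

    def test_fifty_fifty_conflict_excluded(self):
        trees = [read_newick("((A,B),C,D);"), read_newick("((A,C),B,D);")]
        assert _splits(consensus(trees)) == set()

    def test_consensus_splits_pairwise_compatible(self):
        trees = [read_newick(n) for n in
                 ["((A,B),(C,D),E);", "((A,B),C,(D,E));", "((A,C),B,(D,E));"]]
        c = consensus(trees)
        for s1, s2 in itertools.combinations(_splits(c), 2):
            assert s1 <= s2 or s2 <= s1 or not (s1 & s2)

    def test_mismatched_tip_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus([read_newick("((A,B),C,D);"),
                       read_newick("((A,B),C,E);")])


class TestRellTests:
    def test_ml_topology_p_one_and_max(self, rng):
        mat = rng.normal(-3, 1, size=(4, 60))
        mat[2] += 0.2
        p = sh_test(mat, B=2000, seed=1)
        ml = int(np.argmax(mat.sum(axis=1)))
        assert p[ml] == 1.0
        assert np.all((0 <= p) & (p <= 1))
        assert p[ml] == p.max()

    def test_duplicate_ml_topology_also_p_one(self, rng):
        mat = rng.normal(-3, 1, size=(2, 40))
        mat = np.vstack([mat, mat[np.argmax(mat.sum(axis=1))]])
        p = sh_test(mat, B=2000, seed=2)
        assert (p == 1.0).sum() >= 2

    def test_single_topology_rejected(self, rng):
        with pytest.raises(ValueError):
            sh_test(rng.normal(size=(1, 10)), B=100)

    def test_sitewise_domination_monotone(self, rng):
        """A topology dominated site-wise never gets the larger p."""
        base = rng.normal(-3, 1, size=(1, 50))
        dominated = base - rng.uniform(0.0, 0.3, size=(1, 50))
        other = rng.normal(-3, 1, size=(1, 50))
        mat = np.vstack([base, dominated, other])
        p = sh_test(mat, B=3000, seed=3)
        assert p[1] <= p[0]

    def test_rell_matches_direct_monte_carlo(self, rng):
        """Small case: vectorized RELL vs a naive resampling loop."""
        mat = rng.normal(-2, 0.8, size=(3, 10))
        B = 100000
        p_fast = sh_test(mat, B=B, seed=4)
        w_fast = elw(mat, B=B, seed=4)
        loop_rng = np.random.default_rng(999)
        totals = mat.sum(axis=1)
        delta = totals.max() - totals
        reps = np.empty((B, 3))
        for b in range(B):
            idx = loop_rng.integers(0, 10, size=10)
            reps[b] = mat[:, idx].sum(axis=1)
        centered = reps - reps.mean(axis=0)
        stat = centered.max(axis=1, keepdims=True) - centered
        p_naive = (stat >= delta[None, :]).mean(axis=0)
        ww = np.exp(reps - reps.max(axis=1, keepdims=True))
        w_naive = (ww / ww.sum(axis=1, keepdims=True)).mean(axis=0)
        assert np.allclose(p_fast, p_naive, atol=0.01)
        assert np.allclose(w_fast, w_naive, atol=0.01)

    def test_elw_weights_sum_to_one(self, rng):
        mat = rng.normal(-3, 1, size=(5, 30))
        w = elw(mat, B=2000, seed=5)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_elw_single_topology_weight_one(self, rng):
        assert elw(rng.normal(size=(1, 10)), B=100) == pytest.approx([1.0])

    def test_elw_dominant_topology(self, rng):
        mat = rng.normal(-3, 1, size=(3, 40))
        mat[1] += 50.0 / 40
        w = elw(mat, B=2000, seed=6)
        assert w[1] >= 0.999


def _exhaustive_parsimony_score(tree, states):
    internal = [n for n in tree.postorder_internal_node_iter()]
    best = np.inf
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = states[leaf.taxon.label]
        changes = sum(
            assign[id(n)] != assign[id(n.parent_node)]
            for n in tree.preorder_node_iter() if n.parent_node is not None)
        best = min(best, changes)
    return best


class TestParsimony:
    def test_unrooted_tree_rejected(self):
        tree = read_newick("(A,B,C);")
        cm = CharacterMatrix(["A", "B", "C"], ["f"], np.array([[1], [0], [1]]))
        with pytest.raises(ValueError, match="root"):
            fitch(tree, cm)

    def test_ubiquitous_character_origin_at_root(self):
        tree = read_newick("(A,((B,C),D)X)R;")
        cm = CharacterMatrix(list("ABCD"), ["f"], np.ones((4, 1), dtype=int))
        states = fitch(tree, cm)
        assert states.scores["f"] == 0
        origins = infer_origins(states)
        assert origins.loc[0, "origin"] == "R"
        assert origins.loc[0, "n_losses"] == 0

    def test_single_tip_character_origin_at_tip(self):
        tree = read_newick("(A,((B,C),D));")
        cm = CharacterMatrix(list("ABCD"), ["f"],
                             np.array([[0], [1], [0], [0]]))
        states = fitch(tree, cm)
        assert states.scores["f"] == 1
        assert infer_origins(states).loc[0, "origin"] == "B"

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        newicks = ["((A,B),((C,D),(E,F)))R;",
                   "((((A,B),C),D),((E,F),(G,H)))R;",
                   "((A,(B,(C,D))),(E,(F,(G,H))))R;"]
        for nwk in newicks:
            tree = read_newick(nwk)
            taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
            for _ in range(10):
                col = rng.integers(0, 2, size=len(taxa))
                cm = CharacterMatrix(taxa, ["f"], col[:, None])
                got = fitch(tree, cm).scores["f"]
                want = _exhaustive_parsimony_score(
                    tree, dict(zip(taxa, col)))
                assert got == want

    def test_tip_states_preserved(self):
        tree = bundled_species_tree()
        cm = bundled_character_matrix()
        states = fitch(tree, cm)
        for character in cm.characters:
            obs = cm.states(character)
            for taxon, s in obs.items():
                assert states.mpr[character][taxon] == frozenset({s})


class TestBundledOrigins:
    """Family origins on the bundled species tree and character matrix."""

    @pytest.fixture(scope="class")
    def origins(self):
        table = infer_origins(fitch(bundled_species_tree(),
                                    bundled_character_matrix()))
        return table.set_index("character")

    @pytest.mark.parametrize("family,node", [
        ("HLIP", "Root"), ("OHP1", "GreenLineage"), ("OHP2", "Plantae"),
        ("SEP", "Plantae"), ("ELIP", "GreenLineage"),
        ("RedCAP", "RedLineage"), ("LHC", "RedGreen"),
        ("PSBS", "GreenLineage")])
    def test_origin_nodes(self, origins, family, node):
        assert origins.loc[family, "origin"] == node

    def test_sep_lost_once_in_cyanidioschyzon(self, origins):
        assert origins.loc["SEP", "n_losses"] == 1
        states = fitch(bundled_species_tree(), bundled_character_matrix())
        assert states.resolved["SEP"]["Cyanidioschyzon"] == 0
        assert states.resolved["SEP"]["RedAlgae"] == 1

    def test_no_ambiguity_on_bundled_data(self, origins):
        assert not origins["ambiguous"].any()


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0.]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[1, 1], [1, 0.]]))


def test_ml_distance_tree_recovers_topology(dayhoff):
    """End-to-end: simulate, estimate distances, NJ recovers the split."""
    rng = np.random.default_rng(55)
    root = SeqRecord("r", "".join(rng.choice(list(AA_ORDER), 1500)))
    sim = dendropy.Tree.get(
        data="((A:0.15,B:0.2):0.3,(C:0.1,D:0.25):0.0);", schema="newick")
    aln = Alignment(evolve(root, sim, dayhoff, seed=rng))
    tree = nj(distance_matrix(aln, dayhoff))
    assert frozenset({"A", "B"}) in _splits(tree)
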