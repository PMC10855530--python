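import numpy as np
import pytest

from mitocompare.divergence import SaturatedPairError
from mitocompare.phylogeny import (BootstrapResult, DistanceMatrix,
                                   bootstrap_support, distance_matrix,
                                   nj_tree, read_newick, write_newick)
from mitocompare.synthetic import random_ultrametric_tree


def tree_path_distances(tree):
    """Leaf-to-leaf path lengths of a PhyloTree (independent of NJ)."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    names = sorted(paths)
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            d = sum(x.length for x in pa[k:]) + sum(x.length for x in pb[k:])
            D[i, j] = D[j, i] = d
    return names, D


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = distance_matrix({c: "ACGT" * 30 for c in "abc"})
        assert np.all(dm.d == 0)

    def test_symmetry_and_mean(self):
        dm = distance_matrix({"a": "AAAA" * 25, "b": "AAAG" * 25,
                              "c": "AACG" * 25})
        assert np.allclose(dm.d, dm.d.T)
        assert dm.mean_distance > 0

    def test_saturated_pair_error_names_pair(self):
        with pytest.raises(SaturatedPairError, match="a.*b|b.*a"):
            distance_matrix({"a": "A" * 100, "b": "G" * 100, "c": "A" * 100})

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


class TestNJ:
    def test_four_taxon_additive_oracle(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4))
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = nj_tree(DistanceMatrix(taxa, d))
        assert t.bipartitions() == {frozenset({"A", "B"})}
        lengths = {}
        for node in t.root.postorder():
            if node is t.root:
                continue
            key = node.name or "internal"
            lengths[key] = node.length
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)
        assert lengths["internal"] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        L = {n.name: n.length for n in t.root.children}
        assert L["a"] == pytest.approx((2 + 3 - 5) / 2)
        assert L["b"] == pytest.approx((2 + 5 - 3) / 2)
        assert L["c"] == pytest.approx((3 + 5 - 2) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_random_additive_trees_recovered_exactly(self, n_taxa):
        # 100 seeded trials across sizes: NJ is consistent on additive input
        for trial in range(34):
            rng = np.random.default_rng(1000 * n_taxa + trial)
            true = random_ultrametric_tree(
                rng, [f"t{i}" for i in range(n_taxa)], 1.0)
            # perturb to non-ultrametric additive: stretch leaf branches
            for node in true.root.postorder():
                if node.is_leaf:
                    node.length += rng.uniform(0, 0.5)
            names, D = tree_path_distances(true)
            rec = nj_tree(DistanceMatrix(names, D))
            assert rec.bipartitions() == true.bipartitions()
            _, Drec = tree_path_distances(rec)
            assert np.allclose(D, Drec, atol=1e-9)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(9)
        true = random_ultrametric_tree(rng, [f"t{i}" for i in range(7)], 1.0)
        names, D = tree_path_distances(true)
        mine = nj_tree(DistanceMatrix(names, D))
        sk = sknj(SkDM(D, names))
        allt = frozenset(names)
        sk_bps = set()
        for nd in sk.non_tips():
            side = frozenset(t.name for t in nd.tips())
            if 2 <= len(side) <= len(names) - 2:
                sk_bps.add(min(side, allt - side,
                               key=lambda s: (len(s), tuple(sorted(s)))))
        assert mine.bipartitions() == sk_bps

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.01, 0.5, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        t = nj_tree(DistanceMatrix([f"t{i}" for i in range(6)], d))
        assert all(n.length >= 0 for n in t.root.postorder())


class TestNewick:
    def test_three_leaf_star_shape(self):
        d = np.zeros((3, 3))
        t = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        assert write_newick(t) == "(A:0,B:0,C:0);"

    def test_round_trip_canonical_stability(self):
        rng = np.random.default_rng(4)
        true = random_ultrametric_tree(rng, [f"t{i}" for i in range(6)], 1.0)
        names, D = tree_path_distances(true)
        t = nj_tree(DistanceMatrix(names, D))
        nwk = write_newick(t)
        assert write_newick(read_newick(nwk)) == nwk

    def test_ab_cd_example_round_trip(self):
        t = read_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert t.bipartitions() == {frozenset({"A", "B"})}


class TestBootstrap:
    def _alignment(self, seed=0, n=6, height=0.5, L=1998):
        from mitocompare.synthetic import SimulationSpec, simulate_family

        spec = SimulationSpec(seed=seed, n_taxa=n, tree_height=height,
                              genome_template=(("ND1", "PCG", L, "H"),),
                              cr_repeat_taxon=None, rearrangements=())
        genomes, truth = simulate_family(spec)
        return ({g.accession: g.feature_seq(g.features[0]) for g in genomes},
                truth)

    def test_same_seed_identical_supports(self):
        seqs, _ = self._alignment()
        r1 = bootstrap_support(seqs, replicates=50, seed=3)
        r2 = bootstrap_support(seqs, replicates=50, seed=3)
        assert write_newick(r1.tree) == write_newick(r2.tree)

    def test_clean_simulated_clades_strongly_supported(self):
        seqs, truth = self._alignment(seed=8, n=6, height=0.5, L=3000)
        # L=3000 is divisible by 3; keep the template valid
        res = bootstrap_support(seqs, replicates=200, seed=1)
        true_bps = read_newick(truth.tree_newick).bipartitions()
        assert res.tree.bipartitions() == true_bps
        supports = [n.support for n in res.tree.internal_nodes()]
        assert min(supports) >= 95.0

    def test_zero_variation_flagged(self):
        res = bootstrap_support({c: "ACGT" * 100 for c in "abcd"},
                                replicates=20, seed=0)
        assert res.no_variation
        assert all(n.support == 0.0 for n in res.tree.internal_nodes())

    def test_supports_invariant_under_taxon_relabeling(self):
        seqs, _ = self._alignment(seed=2)
        res1 = bootstrap_support(seqs, replicates=100, seed=5)
        relabeled = {f"x_{k}": v for k, v in seqs.items()}
        res2 = bootstrap_support(relabeled, replicates=100, seed=5)
        sup1 = sorted(round(n.support, 6) for n in res1.tree.internal_nodes())
        sup2 = sorted(round(n.support, 6) for n in res2.tree.internal_nodes())
        assert sup1 == sup2
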