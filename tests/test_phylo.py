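import math

import dendropy
import numpy as np
import pytest
from scipy import stats

from mhcev.errors import CladeError, SizeError
from mhcev.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    is_ultrametric,
    neighbor_joining,
    node_depths,
    pairwise_distance,
    prune_outgroup,
    random_labeled_topology,
    read_newick,
    root_on_outgroup,
    scale_clade_stem,
    tip_labels,
    ultrametricize,
    write_newick,
)
from tests.conftest import make_aln, random_binary_tree_with_lengths, tree_path_distances


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        aln = make_aln(("a", "ACGTCA"), ("b", "ACGTCA"))
        for model in ("K2P", "TN93", "TN93G"):
            dm = pairwise_distance(aln, model=model)
            assert dm.d[0, 1] == 0.0

    def test_k2p_closed_form_ten_transitions(self):
        # 100 sites, 10 A<->G transitions, no transversions
        a = "AG" * 50 + "CC"
        b = "GG" * 10 + "AG" * 40 + "CC"  # first ten A's -> G
        aln = make_aln(("a", a), ("b", b))
        p = 10 / 102
        expected = -0.5 * math.log(1 - 2 * p) - 0.25 * math.log(1.0)
        dm = pairwise_distance(aln, model="K2P")
        assert dm.d[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_gamma_inflates_tn93(self, rng):
        bases = "ACGT"
        s1 = "".join(bases[i] for i in rng.integers(0, 4, size=120))
        s2 = list(s1)
        for pos in rng.choice(120, size=15, replace=False):
            s2[pos] = bases[(bases.index(s2[pos]) + int(rng.integers(1, 4))) % 4]
        aln = make_aln(("a", s1), ("b", "".join(s2)))
        plain = pairwise_distance(aln, model="TN93").d[0, 1]
        gamma = pairwise_distance(aln, model="TN93G", alpha=0.78).d[0, 1]
        assert gamma >= plain > 0.0

    def test_k2p_equals_tn93_equal_frequencies(self):
        # count-preserving substitutions keep all base frequencies at 1/4
        s1 = "ACGT" * 6
        s2 = list(s1)
        s2[0], s2[2] = "G", "A"  # A<->G transitions
        s2[5], s2[7] = "T", "C"  # C<->T transitions
        s2[8], s2[11] = "T", "A"  # A<->T transversions
        aln = make_aln(("a", s1), ("b", "".join(s2)))
        k2p = pairwise_distance(aln, model="K2P").d[0, 1]
        tn93 = pairwise_distance(aln, model="TN93").d[0, 1]
        assert k2p == pytest.approx(tn93, rel=1e-10)

    def test_pairwise_deletion(self):
        aln = make_aln(("a", "ACG---"), ("b", "ACGTTT"))
        dm = pairwise_distance(aln, model="K2P")
        assert dm.d[0, 1] == 0.0

    def test_saturated_flagged_infinite(self):
        aln = make_aln(("a", "AAACCC"), ("b", "CCCAAA"))
        dm = pairwise_distance(aln, model="K2P")
        assert math.isinf(dm.d[0, 1])
        assert dm.has_saturated


class TestNeighborJoining:
    def test_too_few_taxa(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(SizeError):
            neighbor_joining(dm)

    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(labels=["a", "b", "c"], d=d))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) with internal edge 1
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        paths = tree_path_distances(tree)
        for (x, y), expect in {
            ("a", "b"): 3.0, ("a", "c"): 5.0, ("a", "d"): 6.0,
            ("b", "c"): 6.0, ("b", "d"): 7.0, ("c", "d"): 7.0,
        }.items():
            assert paths[(x, y)] == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("n_taxa", [6, 7, 8])
    def test_additive_matrix_exactness_fuzz(self, n_taxa, rng):
        for rep in range(7):
            labels = [f"t{i}" for i in range(n_taxa)]
            src = random_binary_tree_with_lengths(labels, rng, 0.1, 1.0)
            true_paths = tree_path_distances(src)
            d = np.zeros((n_taxa, n_taxa))
            for (a, b), v in true_paths.items():
                i, j = labels.index(a), labels.index(b)
                d[i, j] = d[j, i] = v
            nj = neighbor_joining(DistanceMatrix(labels=labels, d=d))
            nj_paths = tree_path_distances(nj)
            for pair, v in true_paths.items():
                assert nj_paths[pair] == pytest.approx(v, abs=1e-8)

    def test_negative_lengths_clamped(self, rng):
        n = 5
        d = np.abs(rng.normal(1.0, 0.5, size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(labels=[f"t{i}" for i in range(n)], d=d))
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0.0


class TestBootstrap:
    def _two_group_alignment(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        other = list(base)
        for pos in rng.choice(60, size=25, replace=False):
            other[pos] = "ACGT"[("ACGT".index(other[pos]) + 2) % 4]
        other = "".join(other)

        def jitter(s, k):
            s = list(s)
            for pos in rng.choice(60, size=k, replace=False):
                s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
            return "".join(s)

        return make_aln(
            ("a1", jitter(base, 1)), ("a2", jitter(base, 1)),
            ("a3", jitter(base, 2)), ("a4", jitter(base, 2)),
            ("b1", jitter(other, 1)), ("b2", jitter(other, 1)),
            ("b3", jitter(other, 2)), ("b4", jitter(other, 2)),
        )

    def test_central_split_high_support(self, rng):
        aln = self._two_group_alignment(rng)
        tree = bootstrap_support(aln, model="K2P", n=100, seed=5)
        supports = {}
        all_tips = frozenset(tip_labels(tree))
        ref = min(all_tips)
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if ref in below:
                below = all_tips - below
            supports[below] = getattr(node, "support", None)
        central = frozenset({"b1", "b2", "b3", "b4"})
        assert supports.get(central) is not None
        assert supports[central] >= 0.95

    def test_no_signal_low_support(self, rng):
        # shuffling every column across sequences destroys the grouping signal
        src = self._two_group_alignment(rng)
        cols = [[s.bases[j] for s in src] for j in range(src.length)]
        for col in cols:
            rng.shuffle(col)
        rows = [
            (s.id, "".join(cols[j][i] for j in range(src.length)))
            for i, s in enumerate(src)
        ]
        aln = make_aln(*rows)
        tree = bootstrap_support(aln, model="K2P", n=100, seed=6)
        sup = [
            node.support
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
            and not node.is_leaf()
            and hasattr(node, "support")
        ]
        assert sup and min(sup) < 0.8

    def test_n_zero_no_annotations(self, rng):
        aln = self._two_group_alignment(rng)
        tree = bootstrap_support(aln, model="K2P", n=0)
        for node in tree.preorder_node_iter():
            assert not hasattr(node, "support")

    def test_support_in_unit_interval_and_counts(self, rng):
        aln = self._two_group_alignment(rng)
        tree = bootstrap_support(aln, model="K2P", n=20, seed=1)
        n_used = tree.n_bootstrap_used
        assert 1 <= n_used <= 20
        for node in tree.preorder_node_iter():
            if hasattr(node, "support"):
                assert 0.0 <= node.support <= 1.0
                # support is (count of matching replicates) / n_used
                assert (node.support * n_used) == pytest.approx(
                    round(node.support * n_used)
                )


class TestUltrametricize:
    def test_fixed_point(self):
        tree = read_newick_str("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
        out = ultrametricize(tree)
        d0 = {l.taxon.label: d for l, d in _tip_depths(tree).items()}
        d1 = {l.taxon.label: d for l, d in _tip_depths(out).items()}
        for k in d0:
            assert d1[k] == pytest.approx(d0[k])

    def test_two_tip_mean(self):
        tree = read_newick_str("(a:1,b:3);")
        out = ultrametricize(tree)
        depths = {l.taxon.label: d for l, d in _tip_depths(out).items()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_all_paths_equal_any_input(self, rng):
        for _ in range(10):
            tree = random_binary_tree_with_lengths(
                [f"t{i}" for i in range(6)], rng, 0.1, 2.0
            )
            out = ultrametricize(tree)
            assert is_ultrametric(out, rel_tol=1e-9)


class TestScaleCladeStem:
    def _tree(self):
        return read_newick_str("((a:1,b:1):2,(c:1,d:1):3);")

    def test_factor_one_identity(self):
        t0 = self._tree()
        t1 = scale_clade_stem(t0, {"a", "b"}, 1.0)
        assert tree_path_distances(t1) == tree_path_distances(t0)

    def test_halving_stem(self):
        t1 = scale_clade_stem(self._tree(), {"a", "b"}, 0.5)
        paths = tree_path_distances(t1)
        assert paths[("a", "c")] == pytest.approx(1 + 1 + 1 + 3)  # stem 2 -> 1
        assert paths[("a", "b")] == pytest.approx(2.0)  # unchanged

    def test_breaks_ultrametricity(self):
        tree = read_newick_str("((a:1,b:1):2,(c:2,d:2):1);")
        assert is_ultrametric(tree)
        scaled = scale_clade_stem(tree, {"a", "b"}, 0.5)
        assert not is_ultrametric(scaled)

    def test_non_monophyletic_rejected(self):
        with pytest.raises(CladeError):
            scale_clade_stem(self._tree(), {"a", "c"}, 0.5)

    def test_root_clade_rejected(self):
        with pytest.raises(CladeError):
            scale_clade_stem(self._tree(), {"a", "b", "c", "d"}, 0.5)


class TestRandomTopology:
    def test_three_labels_single_topology(self, rng):
        # 3 taxa: no non-trivial bipartitions; all draws identical star
        for _ in range(5):
            t = random_labeled_topology(["a", "b", "c"], rng)
            assert len(bipartitions(t)) == 0
            assert sorted(tip_labels(t)) == ["a", "b", "c"]

    def test_uniform_over_four_taxon_topologies(self, rng):
        counts = {}
        for _ in range(3000):
            t = random_labeled_topology(["a", "b", "c", "d"], rng)
            (split,) = bipartitions(t)
            counts[split] = counts.get(split, 0) + 1
        assert len(counts) == 3
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-4

    def test_seed_determinism(self):
        t1 = random_labeled_topology(list("abcdefg"), np.random.default_rng(11))
        t2 = random_labeled_topology(list("abcdefg"), np.random.default_rng(11))
        assert bipartitions(t1) == bipartitions(t2)

    def test_unit_branch_lengths(self, rng):
        t = random_labeled_topology(list("abcdef"), rng)
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length == 1.0


class TestOutgroupHandling:
    def test_root_and_prune(self, rng):
        aln_rows = []
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        for i in range(5):
            s = list(base)
            for pos in rng.choice(60, size=3 + i, replace=False):
                s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
            aln_rows.append((f"s{i}", "".join(s)))
        far = "".join(
            "ACGT"[("ACGT".index(c) + 2) % 4] if i % 3 == 0 else c
            for i, c in enumerate(base)
        )
        aln_rows.append(("out", far))
        aln = make_aln(*aln_rows)
        tree = neighbor_joining(pairwise_distance(aln, model="K2P"))
        rooted = root_on_outgroup(tree, "out")
        kids = rooted.seed_node.child_nodes()
        assert any(
            k.is_leaf() and k.taxon.label == "out" for k in kids
        )
        pruned = prune_outgroup(tree, "out")
        assert "out" not in tip_labels(pruned)
        assert sorted(tip_labels(pruned)) == [f"s{i}" for i in range(5)]

    def test_missing_outgroup(self, rng):
        tree = random_labeled_topology(list("abcd"), rng)
        with pytest.raises(CladeError):
            root_on_outgroup(tree, "zz")


def test_newick_roundtrip(tmp_path, rng):
    tree = random_binary_tree_with_lengths(list("abcde"), rng)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    again = read_newick(path)
    assert bipartitions(again) == bipartitions(tree)
    p0 = tree_path_distances(tree)
    p1 = tree_path_distances(again)
    for k, v in p0.items():
        assert p1[k] == pytest.approx(v, abs=1e-9)


def read_newick_str(s):
    return dendropy.Tree.get(data=s, schema="newick", rooting="force-rooted")


def _tip_depths(tree):
    depths = node_depths(tree)
    return {l: depths[l] for l in tree.leaf_node_iter()}
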