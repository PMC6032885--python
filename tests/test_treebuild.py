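"""Distances, neighbor joining, bootstrap and newick handling."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from oracles import random_additive_tree

from vps9phylo.profile import ProfileAlignment
from vps9phylo.treebuild import (
    DistanceMatrix,
    TreeError,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    pairwise_distance,
    prune_long_branches,
    read_tree,
    write_tree,
)


def rf_distance(newick1: str, newick2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


class TestDistances:
    def test_identical_rows_give_zero(self):
        mask = np.ones(20, dtype=bool)
        d, shared, warned = pairwise_distance("A" * 20, "A" * 20, mask)
        assert d == 0.0 and shared == 20 and not warned

    def test_half_mismatch_poisson_corrected(self):
        mask = np.ones(20, dtype=bool)
        d, _, _ = pairwise_distance("A" * 10 + "C" * 10, "A" * 10 + "D" * 10, mask)
        assert d == pytest.approx(math.log(2))

    def test_saturation_and_sparse_overlap_capped(self):
        mask = np.ones(20, dtype=bool)
        d, _, warned = pairwise_distance("A" * 1 + "C" * 19, "A" * 1 + "D" * 19, mask)
        assert d == 5.0 and warned
        d, shared, warned = pairwise_distance("A" + "-" * 19, "A" + "-" * 19, mask)
        assert shared == 1 and d == 5.0 and warned

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        rows = {
            f"s{i}": "".join(rng.choice(list("ACDE-"), 40)) for i in range(6)
        }
        rows = {k: v if v.replace("-", "") else "A" * 40 for k, v in rows.items()}
        D = distance_matrix(rows, np.ones(40, dtype=bool))
        assert np.allclose(D.matrix, D.matrix.T)
        assert np.all(np.diag(D.matrix) == 0)

    def test_zero_masked_columns_rejected(self):
        with pytest.raises(TreeError):
            pairwise_distance("AC", "AC", np.zeros(2, dtype=bool))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ("A", "B", "C")
        M = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(
            DistanceMatrix(ids, M, np.zeros_like(M, int), np.zeros_like(M, bool))
        )
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        M = np.zeros((2, 2))
        with pytest.raises(TreeError):
            neighbor_joining(
                DistanceMatrix(("A", "B"), M, np.zeros_like(M, int), np.zeros_like(M, bool))
            )

    def test_equal_distances_resolved_deterministically(self):
        ids = tuple("ABCD")
        M = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(ids, M, np.zeros_like(M, int), np.zeros_like(M, bool))
        n1 = write_tree(neighbor_joining(dm))
        n2 = write_tree(neighbor_joining(dm))
        assert n1 == n2

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            M = rng.uniform(0.5, 3.0, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            dm = DistanceMatrix(
                tuple(f"t{i}" for i in range(n)),
                M,
                np.zeros_like(M, int),
                np.zeros_like(M, bool),
            )
            tree = neighbor_joining(dm)
            for nd in tree.preorder_node_iter():
                if nd.edge.length is not None:
                    assert nd.edge.length >= 0

    def test_recovers_generating_topology_on_additive_matrices(self, rng):
        """NJ is consistent: path-length distances on 200 random binary
        trees (4-12 tips) return the generating topology (RF = 0)."""
        for trial in range(200):
            n = int(rng.integers(4, 13))
            newick, dist = random_additive_tree(n, rng)
            ids = tuple(f"t{i}" for i in range(n))
            M = np.array([[dist[(a, b)] for b in ids] for a in ids])
            dm = DistanceMatrix(ids, M, np.zeros_like(M, int), np.zeros_like(M, bool))
            out = write_tree(neighbor_joining(dm))
            assert rf_distance(newick, out) == 0, (trial, newick)


class TestNewickIO:
    def test_fractional_support_dialect(self):
        tree = read_tree("((A:1,B:1)0.99:1,C:2);")
        sups = [
            nd.support
            for nd in tree.preorder_node_iter()
            if getattr(nd, "support", None) is not None
        ]
        assert sups == [0.99]

    def test_percentage_support_dialect(self):
        tree = read_tree("((A:1,B:1)87:1,C:2);")
        sups = [
            nd.support
            for nd in tree.preorder_node_iter()
            if getattr(nd, "support", None) is not None
        ]
        assert sups == [0.87]

    def test_round_trip_preserves_topology_lengths_supports(self):
        src = "((A:1.5,B:0.25)0.9:1,(C:2,D:1)0.5:0.125);"
        tree = read_tree(src)
        back = read_tree(write_tree(tree))
        assert rf_distance(src, write_tree(back)) == 0
        sups = sorted(
            nd.support
            for nd in back.preorder_node_iter()
            if getattr(nd, "support", None) is not None
        )
        assert sups == [0.5, 0.9]
        lengths = sorted(
            nd.edge.length
            for nd in back.leaf_node_iter()
        )
        assert lengths == [0.25, 1.0, 1.5, 2.0]

    def test_malformed_newick_raises(self):
        with pytest.raises(TreeError):
            read_tree("((A:1,B:1;")

    def test_negative_lengths_clamped(self):
        tree = read_tree("((A:1,B:-0.5):1,C:2);")
        assert all(
            (nd.edge.length or 0) >= 0 for nd in tree.preorder_node_iter()
        )


class TestBootstrap:
    def test_compatible_alignment_gives_full_support(self):
        # every column carries the same split -> every replicate agrees
        rows = ["AAAA", "AAAA", "CCCC", "CCCC", "GGGG"]
        aln = ProfileAlignment(
            backbone_ids=tuple(f"s{i}" for i in range(5)),
            backbone_rows=tuple(rows),
        )
        tree = bootstrap_support(aln, n_reps=20, seed=3)
        sups = [
            nd.support
            for nd in tree.preorder_node_iter()
            if getattr(nd, "support", None) is not None
        ]
        assert sups and all(s == 1.0 for s in sups)

    def test_supports_in_unit_interval_and_deterministic(self, rng):
        rows = {
            f"s{i}": "".join(rng.choice(list("ACDE"), 30)) for i in range(8)
        }
        aln = ProfileAlignment(
            backbone_ids=tuple(rows), backbone_rows=tuple(rows.values())
        )
        t1 = bootstrap_support(aln, n_reps=25, seed=11)
        t2 = bootstrap_support(aln, n_reps=25, seed=11)
        assert write_tree(t1) == write_tree(t2)
        for nd in t1.preorder_node_iter():
            s = getattr(nd, "support", None)
            if s is not None:
                assert 0.0 <= s <= 1.0

    def test_deep_clean_split_is_strongly_supported(self, small_params):
        """A deep two-clade simulated split at low divergence gets
        bootstrap support >= 0.9 at 100 replicates."""
        rng = np.random.default_rng(5)
        anc1 = rng.integers(0, 20, 60)
        anc2 = (anc1 + 10) % 20  # far-removed second clade ancestor
        def noisy(anc):
            out = anc.copy()
            idx = rng.choice(60, 4, replace=False)
            out[idx] = (out[idx] + rng.integers(1, 20, 4)) % 20
            return out
        from vps9phylo.seqs import AA20
        rows = {}
        for i in range(4):
            rows[f"a{i}"] = "".join(AA20[c] for c in noisy(anc1))
            rows[f"b{i}"] = "".join(AA20[c] for c in noisy(anc2))
        aln = ProfileAlignment(
            backbone_ids=tuple(rows), backbone_rows=tuple(rows.values())
        )
        tree = bootstrap_support(aln, n_reps=100, seed=23)
        # find the a|b bipartition
        from vps9phylo.treebuild import bipartition_keys
        keys = bipartition_keys(tree)
        aside = frozenset(f"a{i}" for i in range(4))
        bside = frozenset(f"b{i}" for i in range(4))
        node = keys.get(aside) or keys.get(bside)
        assert node is not None, "clean split not recovered"
        assert node.support >= 0.9


class TestPruning:
    def test_equidistant_tips_untouched(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        pruned, removed, _ = prune_long_branches(tree, factor=3.0)
        assert removed == []

    def test_single_long_tip_removed(self):
        tree = read_tree("((A:0.1,B:0.1):0.1,(C:0.1,LONG:3.0):0.1,D:0.1);")
        pruned, removed, _ = prune_long_branches(tree, factor=3.0)
        assert removed == ["LONG"]
        assert "LONG" not in write_tree(pruned)

    def test_protected_anchor_retained_with_warning(self):
        tree = read_tree("((A:0.1,B:0.1):0.1,(C:0.1,LONG:3.0):0.1,D:0.1);")
        pruned, removed, warnings = prune_long_branches(
            tree, factor=3.0, protected={"LONG"}
        )
        assert removed == []
        assert any("LONG" in w for w in warnings)

    def test_never_prunes_below_three_tips(self):
        tree = read_tree("(A:0.1,B:0.1,LONG:5.0);")
        pruned, removed, warnings = prune_long_branches(tree, factor=3.0)
        assert len(list(pruned.leaf_node_iter())) >= 3
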