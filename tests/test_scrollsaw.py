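"""Backbone-anchored subfamily assignment and Scrollsaw reduction."""

import pytest

from vps9phylo.scrollsaw import (
    BackboneCatalog,
    CladeAssignment,
    assign_subfamilies,
    clade_depth,
    normalized_depth,
    select_representatives,
)
from vps9phylo.treebuild import TreeError, read_tree


def _catalog(**extra):
    mapping = {
        "V1": "Varp", "V2": "Varp",
        "R1": "Rabex5", "G1": "GAPVD1",
        "RIN1": "RIN", "RIN2": "RIN",
    }
    mapping.update(extra)
    return BackboneCatalog(mapping, anchor_id="RIN2", anchor_clade="RIN")


class TestAssignment:
    def test_query_inside_fully_supported_pure_clade(self):
        tree = read_tree(
            "(((q:0.1,V1:0.1)1.0:0.1,V2:0.1)1.0:0.5,"
            "(RIN1:0.1,RIN2:0.2)1.0:0.5,(R1:0.1,G1:0.1)1.0:0.5);"
        )
        asg = assign_subfamilies(tree, _catalog())
        assert asg["q"].subfamily == "Varp"
        assert not asg["q"].megaclade

    def test_low_support_clade_leaves_query_unclassified(self):
        tree = read_tree(
            "((q:0.1,V1:0.1)0.5:0.5,"
            "(RIN1:0.1,RIN2:0.2)1.0:0.5,(R1:0.1,G1:0.1)1.0:0.5);"
        )
        asg = assign_subfamilies(tree, _catalog(), min_support=0.80)
        assert asg["q"].subfamily == "unclassified"

    def test_megaclade_fallback_flagged(self):
        # q groups with Rabex5 and GAPVD1 together, with neither alone
        tree = read_tree(
            "((q:0.1,(R1:0.1,G1:0.1)0.5:0.1)0.95:0.5,"
            "(V1:0.1,V2:0.1)1.0:0.5,(RIN1:0.1,RIN2:0.2)1.0:0.5);"
        )
        asg = assign_subfamilies(tree, _catalog())
        assert asg["q"].subfamily == "Rabex5+GAPVD1"
        assert asg["q"].megaclade

    def test_conflicting_backbone_context_unclassified(self):
        # q's only supported sides mix Varp with RIN backbones
        tree = read_tree(
            "((q:0.1,V1:0.1)0.2:0.1,(RIN1:0.1,RIN2:0.2)0.3:0.1,R1:0.5);"
        )
        asg = assign_subfamilies(tree, _catalog())
        assert asg["q"].subfamily == "unclassified"

    def test_classification_purity_invariant(self):
        """No classified query's supporting clade may contain backbone of a
        conflicting subfamily."""
        tree = read_tree(
            "(((q1:0.1,V1:0.1)1.0:0.1,V2:0.1)1.0:0.5,"
            "((q2:0.1,RIN1:0.1)1.0:0.1,RIN2:0.2)1.0:0.5,(R1:0.1,G1:0.1)1.0:0.5);"
        )
        cat = _catalog()
        for sid, asg in assign_subfamilies(tree, cat).items():
            if asg.subfamily in ("unclassified",):
                continue
            if asg.megaclade:
                continue
            assert asg.subfamily == {"q1": "Varp", "q2": "RIN"}[sid]


class TestDepths:
    def test_cherry_depths_are_pendant_lengths(self):
        tree = read_tree("((A:0.1,B:0.4):0.5,C:0.2,D:0.3);", rooted=True)
        assert clade_depth(tree, "A", {"A", "B"}) == pytest.approx(0.1)
        assert clade_depth(tree, "B", {"A", "B"}) == pytest.approx(0.4)

    def test_single_tip_clade_uses_pendant_edge(self):
        tree = read_tree("((A:0.1,B:0.4):0.5,C:0.2,D:0.3);", rooted=True)
        assert clade_depth(tree, "C", {"C"}) == pytest.approx(0.2)

    def test_depth_sums_along_chain(self):
        tree = read_tree("(((A:0.1,B:0.3):0.2,C:0.5):0.1,D:1.0,E:1.0);", rooted=True)
        assert clade_depth(tree, "A", {"A", "B", "C"}) == pytest.approx(0.3)

    def test_non_monophyletic_clade_rejected(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        with pytest.raises(TreeError):
            clade_depth(tree, "A", {"A", "C"})

    def test_normalized_depth_ratio_and_scale_invariance(self):
        import re

        cat = _catalog()
        t1 = "((q:0.2,V1:0.1)1.0:0.5,(RIN1:0.1,RIN2:0.4)1.0:0.5,(R1:0.1,G1:0.1)1.0:0.5);"
        t2 = re.sub(r":(\d\.\d)", lambda m: f":{2 * float(m.group(1))}", t1)
        # doubling every branch length leaves the normalised depth unchanged
        a1 = assign_subfamilies(read_tree(t1), cat)["q"]
        a2 = assign_subfamilies(read_tree(t2), cat)["q"]
        assert not a1.norm_flag and not a2.norm_flag
        assert a1.normalized_depth == pytest.approx(a2.normalized_depth)

    def test_anchor_absent_returns_raw_depth_with_flag(self):
        cat = _catalog()
        tree = read_tree(
            "((q:0.2,V1:0.1)1.0:0.5,(R1:0.1,G1:0.1)1.0:0.5,V2:0.9);"
        )
        asg = assign_subfamilies(tree, cat)["q"]
        assert asg.norm_flag
        assert asg.normalized_depth is not None

    def test_normalized_depth_explicit_api(self):
        tree = read_tree(
            "((q:0.2,V1:0.1)1.0:0.5,(RIN1:0.1,RIN2:0.4)1.0:0.5,(R1:0.1,G1:0.1)1.0:0.5);",
            rooted=True,
        )
        ratio, flag = normalized_depth(tree, "q", {"q", "V1"}, _catalog())
        assert not flag
        assert ratio == pytest.approx(0.2 / 0.4)


class TestRepresentatives:
    def _asg(self, sid, fam, depth):
        return CladeAssignment(sid, fam, normalized_depth=depth)

    def test_minimum_depth_selected(self):
        assignments = {
            "X": self._asg("X", "Varp", 0.2),
            "Y": self._asg("Y", "Varp", 0.5),
        }
        grouping = {"X": "SAR", "Y": "SAR"}
        reps = select_representatives(assignments, grouping)
        assert reps == {("SAR", "Varp"): "X"}

    def test_exact_tie_broken_lexicographically(self):
        assignments = {
            "b": self._asg("b", "Varp", 0.3),
            "a": self._asg("a", "Varp", 0.3),
        }
        reps = select_representatives(assignments, {"a": "g", "b": "g"})
        assert reps[("g", "Varp")] == "a"

    def test_one_representative_per_cell_and_idempotent(self):
        assignments = {
            f"s{i}": self._asg(f"s{i}", fam, 0.1 * i)
            for i, fam in enumerate(["Varp", "Varp", "RIN", "RIN", "Alsin"])
        }
        grouping = {f"s{i}": ("G1" if i % 2 else "G2") for i in range(5)}
        reps = select_representatives(assignments, grouping)
        assert len(set(reps.keys())) == len(reps)
        selected = {sid: assignments[sid] for sid in reps.values()}
        again = select_representatives(
            selected, {s: grouping[s] for s in selected}
        )
        assert set(again.values()) == set(reps.values())

    def test_unlabelled_classified_sequence_rejected(self):
        assignments = {"s": self._asg("s", "Varp", 0.1)}
        with pytest.raises(ValueError):
            select_representatives(assignments, {})
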