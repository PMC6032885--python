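"""Scrollsaw classification: backbone-anchored subfamily assignment and
shortest-branch representative selection.

A query is assigned to a subfamily when the smallest supported clade
containing it holds backbone members of exactly that subfamily and no other;
queries grouping with Rabex5 and GAPVD1 backbones together (but neither
alone) fall back to the Rabex5+GAPVD1 megaclade.  For the Scrollsaw
reduction, each sequence's branch length from tip to its clade's base is
normalised by the anchor sequence's depth within the anchor clade (by
default HsRIN2 within RIN, a clade whose branch lengths stay comparatively
stable across trees), and the shortest-branching member of each
(group, subfamily) cell is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .treebuild import TreeError, clone_tree, leaf_labels

SUBFAMILIES = ("Rabex5", "GAPVD1", "Varp", "Alsin", "Vps9DCP1", "RIN")
MEGACLADE = "Rabex5+GAPVD1"
MEGACLADE_MEMBERS = frozenset({"Rabex5", "GAPVD1"})
DEFAULT_MIN_SUPPORT = 0.80
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class BackboneCatalog:
    """Subfamily of every backbone sequence, plus the normalisation anchor."""

    subfamily_of: dict[str, str]
    anchor_id: str = "HsRIN2"
    anchor_clade: str = "RIN"
    megaclades: dict[str, frozenset] = field(
        default_factory=lambda: {MEGACLADE: MEGACLADE_MEMBERS}
    )

    def __post_init__(self) -> None:
        if self.anchor_id in self.subfamily_of:
            if self.subfamily_of[self.anchor_id] != self.anchor_clade:
                raise ValueError("anchor_id does not belong to anchor_clade")

    def backbone_ids(self) -> set[str]:
        return set(self.subfamily_of)


@dataclass(frozen=True)
class CladeAssignment:
    seq_id: str
    subfamily: str              # subfamily, megaclade name, or "unclassified"
    support: float | None = None
    node_id: str | None = None  # newick-order index of the supporting node
    megaclade: bool = False
    normalized_depth: float | None = None
    norm_flag: bool = False     # True when the anchor was absent (raw depth)


def _index_nodes(tree: dendropy.Tree) -> None:
    for i, nd in enumerate(tree.preorder_node_iter()):
        nd.node_id = f"n{i}"


class _EdgeCuts:
    """Candidate clades of an unrooted tree, one per edge cut.

    Cutting any edge splits the tips in two; the side holding a query is
    the clade that rooting the tree on that edge would create.  The side's
    base node (where the cut edge attaches) gives tip-to-base depths, and
    the edge's bipartition support applies to either side.
    """

    def __init__(self, tree: dendropy.Tree, catalog: BackboneCatalog) -> None:
        self.work = clone_tree(tree, rooted=True)
        _index_nodes(self.work)
        self.leaves = {lf.taxon.label: lf for lf in self.work.leaf_node_iter()}
        self.all_tips = frozenset(self.leaves)
        self.backbone = catalog.subfamily_of
        self.depth: dict[str, float] = {}
        for nd in self.work.preorder_node_iter():
            p = nd.parent_node
            self.depth[nd.node_id] = (
                0.0 if p is None else self.depth[p.node_id] + (nd.edge.length or 0.0)
            )
        self.below: dict[str, frozenset] = {}
        self.fams_below: dict[str, frozenset] = {}
        for nd in self.work.postorder_node_iter():
            if nd.is_leaf():
                tips = frozenset({nd.taxon.label})
            else:
                tips = frozenset().union(
                    *(self.below[c.node_id] for c in nd.child_nodes())
                )
            self.below[nd.node_id] = tips
            self.fams_below[nd.node_id] = frozenset(
                self.backbone[t] for t in tips if t in self.backbone
            )
        # candidate sides: (tips, backbone fams, support, base node, order)
        self.sides: list[tuple] = []
        order = 0
        for nd in self.work.preorder_node_iter():
            if nd.parent_node is None:
                continue
            sup = getattr(nd, "support", None)
            tips = self.below[nd.node_id]
            self.sides.append((tips, self.fams_below[nd.node_id], sup, nd, order))
            order += 1
            rest = self.all_tips - tips
            rest_fams = frozenset(
                self.backbone[t] for t in rest if t in self.backbone
            )
            self.sides.append((rest, rest_fams, sup, nd.parent_node, order))
            order += 1

    def path_to_base(self, tip: str, base: dendropy.Node) -> float:
        a = self.leaves[tip]
        anc_a = set()
        nd = a
        while nd is not None:
            anc_a.add(nd.node_id)
            nd = nd.parent_node
        nd = base
        while nd.node_id not in anc_a:
            nd = nd.parent_node
        lca_d = self.depth[nd.node_id]
        return (self.depth[a.node_id] - lca_d) + (self.depth[base.node_id] - lca_d)


def assign_subfamilies(
    tree: dendropy.Tree,
    catalog: BackboneCatalog,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> dict[str, CladeAssignment]:
    """Assign every non-backbone tip to a subfamily via backbone anchors.

    For each query tip the smallest clade over all rootings of the
    unrooted tree — i.e. the smallest edge-cut side — containing the query
    and backbone members of exactly one subfamily (and no others) with
    bipartition support >= ``min_support`` determines the subfamily.  If
    no such clade exists but the smallest adequately supported side holds
    Rabex5 and GAPVD1 backbones together and nothing else, the megaclade
    is assigned with the fallback flag.  Otherwise the query is
    unclassified.
    """
    cuts = _EdgeCuts(tree, catalog)
    out: dict[str, CladeAssignment] = {}
    for label in sorted(cuts.all_tips):
        if label in cuts.backbone:
            continue
        out[label] = _assign_one(cuts, label, catalog, min_support)
    return out


def _assign_one(
    cuts: _EdgeCuts, label: str, catalog: BackboneCatalog, min_support: float
) -> CladeAssignment:
    pure = None
    mega = None
    for tips, fams, sup, base, order in cuts.sides:
        if label not in tips or not fams:
            continue
        if sup is not None and sup < min_support:
            continue
        key = (len(tips), order)
        if len(fams) == 1:
            if pure is None or key < pure[0]:
                pure = (key, next(iter(fams)), sup, base)
        else:
            mc = _megaclade_of(set(fams), catalog)
            if mc is not None and (mega is None or key < mega[0]):
                mega = (key, mc, sup, base)
    chosen, is_mega = (pure, False) if pure is not None else (mega, True)
    if chosen is None:
        return CladeAssignment(label, UNCLASSIFIED)
    _, fam, sup, base = chosen
    # depths are measured to the subfamily clade's common base so that
    # they are comparable between members of the same subfamily
    fam_members = catalog.megaclades.get(fam, frozenset({fam}))
    fam_base = _clade_base_cuts(cuts, fam_members)
    depth, flag = _normalized_depth_cuts(cuts, label, fam_base or base, catalog)
    return CladeAssignment(
        label,
        fam,
        support=sup,
        node_id=base.node_id,
        megaclade=is_mega,
        normalized_depth=depth,
        norm_flag=flag,
    )


def _clade_base_cuts(
    cuts: _EdgeCuts, fam_members: frozenset | set
) -> dendropy.Node | None:
    """Base node of a subfamily's clade: the smallest edge-cut side holding
    every present backbone tip of the subfamily (or megaclade members) and
    no backbone of other subfamilies."""
    target = frozenset(
        f for f in fam_members
        if any(
            catalog_fam == f and sid in cuts.all_tips
            for sid, catalog_fam in cuts.backbone.items()
        )
    )
    if not target:
        return None
    member_bb = frozenset(
        sid
        for sid, fam in cuts.backbone.items()
        if fam in target and sid in cuts.all_tips
    )
    best = None
    for tips, fams, _sup, base, order in cuts.sides:
        if fams == target and member_bb <= tips:
            key = (len(tips), order)
            if best is None or key < best[0]:
                best = (key, base)
    return None if best is None else best[1]


def _anchor_depth_cuts(cuts: _EdgeCuts, catalog: BackboneCatalog) -> float | None:
    """Depth of the anchor sequence to the base of the anchor clade."""
    if catalog.anchor_id not in cuts.all_tips:
        return None
    base = _clade_base_cuts(cuts, frozenset({catalog.anchor_clade}))
    if base is None:
        return None
    return cuts.path_to_base(catalog.anchor_id, base)


def _normalized_depth_cuts(
    cuts: _EdgeCuts, label: str, base: dendropy.Node, catalog: BackboneCatalog
) -> tuple[float, bool]:
    raw = cuts.path_to_base(label, base)
    anchor = _anchor_depth_cuts(cuts, catalog)
    if anchor is None or anchor == 0.0:
        return raw, True
    return raw / anchor, False


def _megaclade_of(fams: set, catalog: BackboneCatalog) -> str | None:
    for name, members in catalog.megaclades.items():
        if fams <= members:
            return name
    return None


# ---------------------------------------------------------------------------
# branch-length depths


def clade_depth(tree: dendropy.Tree, tip: str, clade_tips: set[str]) -> float:
    """Branch length from ``tip`` to the base (MRCA) of ``clade_tips``.

    A single-tip clade's depth is its pendant edge length.  Raises on
    non-monophyletic ``clade_tips``.
    """
    if tip not in clade_tips:
        raise TreeError("tip must belong to clade_tips")
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if tip not in leaves:
        raise TreeError(f"tip {tip} not in tree")
    if len(clade_tips) == 1:
        return leaves[tip].edge.length or 0.0
    base = tree.mrca(taxon_labels=list(clade_tips))
    below = {lf.taxon.label for lf in base.leaf_iter()}
    if below != set(clade_tips):
        raise TreeError("clade_tips are not monophyletic under this rooting")
    depth = 0.0
    node = leaves[tip]
    while node is not base:
        depth += node.edge.length or 0.0
        node = node.parent_node
    return depth


def normalized_depth(
    tree: dendropy.Tree,
    tip: str,
    clade_tips: set[str],
    catalog: BackboneCatalog,
) -> tuple[float, bool]:
    """Depth of ``tip`` within its clade, divided by the anchor sequence's
    depth within the anchor clade.  If the anchor is absent from the tree
    the raw depth is returned with a no-normalisation flag."""
    raw = clade_depth(tree, tip, clade_tips)
    present = set(leaf_labels(tree))
    if catalog.anchor_id not in present:
        return raw, True
    anchor_tips = {
        sid
        for sid, fam in catalog.subfamily_of.items()
        if fam == catalog.anchor_clade and sid in present
    }
    anchor_depth = clade_depth(tree, catalog.anchor_id, anchor_tips)
    if anchor_depth == 0.0:
        raise TreeError("anchor depth is 0 (degenerate tree)")
    return raw / anchor_depth, False


def select_representatives(
    assignments: dict[str, CladeAssignment],
    grouping: dict[str, str],
) -> dict[tuple[str, str], str]:
    """Scrollsaw reduction: per (group, subfamily), the sequence with the
    minimal normalised depth (ties: lexicographically smallest id)."""
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for sid, asg in assignments.items():
        if asg.subfamily == UNCLASSIFIED or asg.normalized_depth is None:
            continue
        if sid not in grouping:
            raise ValueError(f"no group label for classified sequence {sid}")
        key = (grouping[sid], asg.subfamily)
        cand = (asg.normalized_depth, sid)
        if key not in best or cand < best[key]:
            best[key] = cand
    return {key: sid for key, (_, sid) in best.items()}


# ---------------------------------------------------------------------------
# TSV output


def write_assignments_tsv(
    assignments: dict[str, CladeAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tsubfamily\tsupport\tnode_id\tmegaclade_flag\tnormalized_depth\n"
        )
        for sid in sorted(assignments):
            a = assignments[sid]
            sup = "NA" if a.support is None else f"{a.support:.3f}"
            dep = "NA" if a.normalized_depth is None else f"{a.normalized_depth:.6f}"
            fh.write(
                f"{a.seq_id}\t{a.subfamily}\t{sup}\t{a.node_id or 'NA'}\t"
                f"{int(a.megaclade)}\t{dep}\n"
            )


def read_catalog_tsv(path: str | Path) -> BackboneCatalog:
    """Catalog TSV: rows ``seq_id<TAB>subfamily``; optional header line
    ``#anchor=<id>:<clade>``."""
    anchor_id, anchor_clade = "HsRIN2", "RIN"
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#anchor="):
            anchor_id, _, anchor_clade = line[len("#anchor="):].partition(":")
            continue
        sid, _, fam = line.partition("\t")
        mapping[sid] = fam
    return BackboneCatalog(mapping, anchor_id, anchor_clade)


def write_catalog_tsv(catalog: BackboneCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#anchor={catalog.anchor_id}:{catalog.anchor_clade}\n")
        for sid in sorted(catalog.subfamily_of):
            fh.write(f"{sid}\t{catalog.subfamily_of[sid]}\n")
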