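"""Ancestral gene-complement reconstruction on a rooted species tree.

Builds taxa x subfamily presence matrices from clade assignments, infers the
LECA (last eukaryotic common ancestor) complement under a root-agnostic
presence rule, and maps gains and losses by Dollo parsimony (one gain,
minimal losses), cross-checked by Fitch parsimony.

Transcriptome-only taxa are handled as tri-state evidence: a zero hit count
is UNKNOWN, never an absence, and UNKNOWN tips neither force losses in the
Dollo mapping nor count toward (or against) the LECA rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .scrollsaw import UNCLASSIFIED, CladeAssignment
from .taxa import TaxonInfo

LECA_RULES = ("two-of-three", "strict")


# ---------------------------------------------------------------------------
# presence matrix


@dataclass
class PresenceMatrix:
    """Paralogue counts per taxon and character (pd.NA = UNKNOWN)."""

    counts: pd.DataFrame               # index: taxa; columns: characters; Int64
    taxa: dict[str, TaxonInfo]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype("Int64")
        for taxon in self.counts.index:
            if taxon not in self.taxa:
                raise ValueError(f"no TaxonInfo for {taxon}")
            row = self.counts.loc[taxon]
            if not self.taxa[taxon].transcriptome and row.isna().any():
                raise ValueError(f"UNKNOWN count for genome taxon {taxon}")
            if (row.dropna() < 0).any():
                raise ValueError("negative counts")

    @property
    def characters(self) -> list[str]:
        return [c for c in self.counts.columns if c != UNCLASSIFIED]

    def present_taxa(self, character: str) -> list[str]:
        col = self.counts[character]
        return [t for t in self.counts.index if pd.notna(col[t]) and col[t] >= 1]

    def tip_states(self, character: str) -> dict[str, int | None]:
        """States for Dollo/Fitch: 1 present, 0 absent, None UNKNOWN."""
        out: dict[str, int | None] = {}
        for t in self.counts.index:
            v = self.counts.loc[t, character]
            out[t] = None if pd.isna(v) else int(v >= 1)
        return out

    def vps9_free_taxa(self) -> list[str]:
        """Genome taxa (absences trustworthy) with zero proteins in every
        column, including the unclassified tally."""
        out = []
        for t in self.counts.index:
            if self.taxa[t].transcriptome:
                continue
            if (self.counts.loc[t].fillna(0) == 0).all():
                out.append(t)
        return sorted(out)


def build_matrix(
    assignments: dict[str, CladeAssignment],
    seq_taxon: dict[str, str],
    taxa: dict[str, TaxonInfo],
) -> PresenceMatrix:
    """Count classified sequences per (taxon, subfamily); unclassified
    sequences are tallied in their own column; a transcriptome taxon's zero
    counts become UNKNOWN."""
    characters: list[str] = []
    rows: dict[str, dict[str, int]] = {t: {} for t in taxa}
    for sid, asg in assignments.items():
        if sid not in seq_taxon:
            raise ValueError(f"unknown taxon for sequence {sid}")
        taxon = seq_taxon[sid]
        if taxon not in rows:
            raise ValueError(f"assignment for unlisted taxon {taxon}")
        col = asg.subfamily if asg.subfamily != UNCLASSIFIED else UNCLASSIFIED
        rows[taxon][col] = rows[taxon].get(col, 0) + 1
        if col not in characters:
            characters.append(col)
    ordered = sorted(c for c in characters if c != UNCLASSIFIED)
    if UNCLASSIFIED in characters:
        ordered.append(UNCLASSIFIED)
    def cell(t: str, c: str):
        v = rows[t].get(c, 0)
        if v == 0 and taxa[t].transcriptome:
            return pd.NA  # transcriptome absence is unknowable
        return v

    df = pd.DataFrame(
        [[cell(t, c) for c in ordered] for t in sorted(rows)],
        index=sorted(rows),
        columns=ordered,
        dtype="Int64",
    )
    return PresenceMatrix(df, dict(taxa))


def infer_ancestral_set(
    matrix: PresenceMatrix, rule: str = "two-of-three"
) -> set[str]:
    """Characters inferred present in the LECA.

    ``two-of-three`` (default, root-agnostic): present in taxa of at least 2
    of the 3 eukaryote domains.  ``strict``: present in both Amorphea and
    Excavata representatives.  UNKNOWN cells never count as presence.
    """
    if rule not in LECA_RULES:
        raise ValueError(f"rule must be one of {LECA_RULES}")
    ancestral: set[str] = set()
    for char in matrix.characters:
        domains = {
            matrix.taxa[t].eu_domain for t in matrix.present_taxa(char)
        }
        if rule == "two-of-three" and len(domains) >= 2:
            ancestral.add(char)
        elif rule == "strict" and {"Amorphea", "Excavata"} <= domains:
            ancestral.add(char)
    return ancestral


# ---------------------------------------------------------------------------
# event mapping


@dataclass(frozen=True)
class DolloEvents:
    """Single-gain / minimal-loss mapping of one character."""

    character: str
    gain_node: str | None                       # node label, None if never present
    loss_edges: tuple[tuple[str, str], ...]     # (parent_label, child_label)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or ""


def label_internal_nodes(tree: dendropy.Tree) -> dendropy.Tree:
    """Give unlabeled internal nodes deterministic preorder labels N1..Nk."""
    i = 0
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and not nd.label:
            i += 1
            nd.label = f"N{i}"
    return tree


def dollo_map(
    tree: dendropy.Tree,
    states: dict[str, int | None],
    character: str = "",
    force_root_gain: bool = False,
) -> DolloEvents:
    """Dollo mapping: one gain at the MRCA of the present tips (or at the
    root when forced), plus the minimal set of loss edges covering exactly
    the present tips.  UNKNOWN tips (None, or tips absent from ``states``)
    are free and never force a loss."""
    label_internal_nodes(tree)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    present = {t for t, s in states.items() if s == 1 and t in leaves}
    if not present:
        return DolloEvents(character, None, ())
    if force_root_gain or len(present) == len(leaves):
        gain = tree.seed_node
    elif len(present) == 1:
        gain = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label in present
        )
    else:
        gain = tree.mrca(taxon_labels=list(present))
    # below the gain node: a subtree needs a loss iff it has no present tip
    # but does contain a known-absent tip
    required: dict[int, bool] = {}
    has_absent: dict[int, bool] = {}
    for nd in gain.postorder_iter():
        if nd.is_leaf():
            lbl = nd.taxon.label
            required[id(nd)] = lbl in present
            has_absent[id(nd)] = states.get(lbl) == 0
        else:
            required[id(nd)] = any(required[id(c)] for c in nd.child_nodes())
            has_absent[id(nd)] = any(has_absent[id(c)] for c in nd.child_nodes())
    losses = []
    for nd in gain.preorder_iter():
        if nd is gain:
            continue
        parent = nd.parent_node
        if required[id(parent)] and not required[id(nd)] and has_absent[id(nd)]:
            losses.append((_node_label(parent), _node_label(nd)))
        # do not descend into already-lost subtrees: preorder_iter cannot be
        # pruned, but deeper edges fail the required[parent] test anyway
    return DolloEvents(character, _node_label(gain), tuple(losses))


def fitch_changes(tree: dendropy.Tree, states: dict[str, int | None]) -> int:
    """Minimal number of binary state changes (equal-weight Fitch).

    UNKNOWN tips are ambiguous ({0, 1}); tips missing from ``states`` are
    treated the same way."""
    changes = 0
    sets: dict[int, frozenset] = {}
    for nd in tree.seed_node.postorder_iter():
        if nd.is_leaf():
            s = states.get(nd.taxon.label)
            sets[id(nd)] = frozenset({0, 1}) if s is None else frozenset({s})
        else:
            children = [sets[id(c)] for c in nd.child_nodes()]
            inter = frozenset.intersection(*children)
            if inter:
                sets[id(nd)] = inter
            else:
                # generalised Fitch for >2 children: pick states covering the
                # most children; each uncovered child costs one change
                counts = {0: 0, 1: 0}
                for c in children:
                    for s in c:
                        counts[s] += 1
                best = max(counts.values())
                sets[id(nd)] = frozenset(s for s, c in counts.items() if c == best)
                changes += len(children) - best
    return changes


@dataclass
class EventMap:
    """Per-character gain/loss events on the species tree."""

    events: dict[str, DolloEvents] = field(default_factory=dict)

    @property
    def total_events(self) -> int:
        return sum(
            (1 if e.gain_node is not None else 0) + e.n_losses
            for e in self.events.values()
        )


def map_events(
    tree: dendropy.Tree,
    matrix: PresenceMatrix,
    force_root_gain: set[str] | None = None,
) -> EventMap:
    force = force_root_gain or set()
    em = EventMap()
    for char in matrix.characters:
        em.events[char] = dollo_map(
            tree, matrix.tip_states(char), char, force_root_gain=char in force
        )
    return em


def count_independent_acquisitions(
    characters: dict[str, dict[str, int | None]], tree: dendropy.Tree
) -> int:
    """Number of independent Dollo gains over architecture characters.

    Each character is one phylogenetically distinct subfamily context of the
    architecture (cross-character identity is already excluded by the
    phylogeny), so each character with at least one present tip contributes
    exactly one gain."""
    n = 0
    for name in sorted(characters):
        ev = dollo_map(tree, characters[name], name)
        if ev.gain_node is not None:
            n += 1
    return n


# ---------------------------------------------------------------------------
# serialisation and plotting


def write_matrix_tsv(matrix: PresenceMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "supergroup", [matrix.taxa[t].supergroup for t in df.index])
    df.insert(1, "eu_domain", [matrix.taxa[t].eu_domain for t in df.index])
    df.insert(2, "transcriptome", [int(matrix.taxa[t].transcriptome) for t in df.index])
    df.to_csv(path, sep="\t", na_rep="NA", index_label="taxon")


def read_matrix_tsv(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="taxon", na_values=["NA"])
    taxa = {
        t: TaxonInfo(
            taxon_id=t,
            supergroup=df.loc[t, "supergroup"],
            eu_domain=df.loc[t, "eu_domain"],
            transcriptome=bool(df.loc[t, "transcriptome"]),
        )
        for t in df.index
    }
    counts = df.drop(columns=["supergroup", "eu_domain", "transcriptome"]).astype(
        "Int64"
    )
    return PresenceMatrix(counts, taxa)


def write_events_tsv(em: EventMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("character\tnode_or_edge\tevent\n")
        for char in sorted(em.events):
            ev = em.events[char]
            if ev.gain_node is not None:
                fh.write(f"{char}\t{ev.gain_node}\tgain\n")
            for parent, child in ev.loss_edges:
                fh.write(f"{char}\t{parent}->{child}\tloss\n")


def plot_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    """Coulson-style presence/absence grid written as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chars = list(matrix.counts.columns)
    taxa = list(matrix.counts.index)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.45 * len(chars), 1.0 + 0.28 * len(taxa))
    )
    for yi, t in enumerate(taxa):
        for xi, c in enumerate(chars):
            v = matrix.counts.loc[t, c]
            if pd.isna(v):
                ax.text(xi, yi, "?", ha="center", va="center", fontsize=7)
            elif v == 0:
                ax.text(xi, yi, "-", ha="center", va="center", fontsize=7)
            else:
                ax.add_patch(plt.Circle((xi, yi), 0.32, color="#3b6ea5"))
                if v > 1:
                    ax.text(
                        xi, yi, str(int(v)), ha="center", va="center",
                        fontsize=6, color="white",
                    )
    ax.set_xlim(-0.6, len(chars) - 0.4)
    ax.set_ylim(len(taxa) - 0.4, -0.6)
    ax.set_xticks(range(len(chars)), chars, rotation=90, fontsize=7)
    starred = [
        t + ("*" if matrix.taxa[t].transcriptome else "") for t in taxa
    ]
    ax.set_yticks(range(len(taxa)), starred, fontsize=7)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
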