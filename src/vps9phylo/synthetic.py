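"""Synthetic gene-family evolution with known ground truth.

Simulates subfamily histories along a rooted, labelled species tree —
per-branch loss and duplication events — and evolves protein sequences along
the resulting gene trees.  Sequences consist of slowly evolving domain
blocks (by default one "Vps9-like" block of 104 residues) embedded in
faster-evolving linker sequence, mimicking the signal structure that makes
divergent GEF families hard to classify.

The substitution process is deliberately simple: per site, a Poisson
mutation probability 1 - exp(-r*t) with uniform replacement over the other
19 residues.  The pipeline only needs tunable divergence, not empirical
exchangeabilities.  Loss and duplication are drawn per branch, not per unit
branch length, matching the per-edge event mapping used downstream.

All randomness flows from a single integer seed: the history walk draws from
a child stream keyed (seed, 1) and sequence evolution from (seed, 2), so
identical parameters reproduce byte-identical FASTA and event lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .ancestral import label_internal_nodes
from .seqs import AA20, SeqRecord
from .taxa import TaxonInfo


@dataclass(frozen=True)
class DomainBlock:
    """A conserved block: ``rel_rate`` scales the substitution rate down
    relative to linker sequence (must be <= 1)."""

    name: str
    length: int
    rel_rate: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if not 0.0 < self.rel_rate <= 1.0:
            raise ValueError("rel_rate must be in (0, 1]")


@dataclass(frozen=True)
class SpeciesTree:
    """Rooted binary species tree whose tips carry taxon labels."""

    tree: dendropy.Tree
    taxa: dict[str, TaxonInfo]

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        missing = set(labels) - set(self.taxa)
        if missing:
            raise ValueError(f"tips without TaxonInfo: {sorted(missing)}")
        label_internal_nodes(self.tree)

    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulation run."""

    subfamilies: tuple[str, ...] = (
        "Rabex5+GAPVD1", "Varp", "Alsin", "Vps9DCP1", "RIN",
    )
    root_presence: dict[str, int] = field(
        default_factory=lambda: {
            "Rabex5+GAPVD1": 1, "Varp": 1, "Alsin": 1, "Vps9DCP1": 1, "RIN": 1,
        }
    )
    loss_prob: float = 0.2
    dup_prob: float = 0.1
    rate_scale: float = 0.5
    domain_blocks: tuple[DomainBlock, ...] = (DomainBlock("Vps9", 104, 0.3),)
    linker_length: int = 75
    tip_rate_multipliers: dict[str, float] = field(default_factory=dict)
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        if not 0.0 <= self.dup_prob <= 1.0:
            raise ValueError("dup_prob must be in [0, 1]")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be > 0")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        for fam in self.subfamilies:
            if self.root_presence.get(fam) not in (0, 1):
                raise ValueError(f"root_presence missing or invalid for {fam}")

    def site_rates(self) -> np.ndarray:
        """Per-site relative rates: linker, then each block with a linker
        after it (layout: linker [block linker]...)."""
        parts = [np.ones(self.linker_length)]
        for block in self.domain_blocks:
            parts.append(np.full(block.length, block.rel_rate))
            parts.append(np.ones(self.linker_length))
        return np.concatenate(parts) if parts else np.ones(0)

    def block_spans(self) -> dict[str, tuple[int, int]]:
        """0-based half-open span of each domain block in the protein."""
        spans = {}
        pos = self.linker_length
        for block in self.domain_blocks:
            spans[block.name] = (pos, pos + block.length)
            pos += block.length + self.linker_length
        return spans


@dataclass(frozen=True)
class Event:
    character: str
    edge_parent: str
    edge_child: str
    event: str  # "loss" or "duplication"


@dataclass
class SimTruth:
    """Ground truth of one simulated history."""

    gene_trees: dict[str, dendropy.Tree | None]
    tip_subfamily: dict[str, str]             # sequence id -> subfamily
    tip_taxon: dict[str, str]                 # sequence id -> species tip
    presence: dict[str, dict[str, int]]       # node label -> subfamily -> 0/1
    events: list[Event]
    seed: int


def simulate_history(species: SpeciesTree, params: SimParams) -> SimTruth:
    """Walk each root-present subfamily down the species tree.

    On every branch each surviving gene lineage is first tested for loss
    (prob ``loss_prob``); survivors are tested for duplication (prob
    ``dup_prob``), which forks the lineage into two copies continuing from
    the child node.  Deterministic given the seed: subfamilies are processed
    in declared order and the species tree in preorder.
    """
    rng = np.random.default_rng([params.seed, 1])
    node_labels = [_label(nd) for nd in species.tree.preorder_node_iter()]
    presence = {lbl: {fam: 0 for fam in params.subfamilies} for lbl in node_labels}
    gene_trees: dict[str, dendropy.Tree | None] = {}
    tip_subfamily: dict[str, str] = {}
    tip_taxon: dict[str, str] = {}
    events: list[Event] = []
    for fam in params.subfamilies:
        if params.root_presence[fam] != 1:
            gene_trees[fam] = None
            continue
        root_gene = dendropy.Node()
        root_gene.edge.length = 0.0
        counters: dict[str, int] = {}
        presence[_label(species.tree.seed_node)][fam] = 1
        stack = [(species.tree.seed_node, [root_gene])]
        # iterative preorder walk carrying the surviving copies at each node
        while stack:
            snode, lineages = stack.pop()
            if not lineages:
                continue
            if snode.is_leaf():
                taxon = snode.taxon.label
                for gnode in lineages:
                    counters[taxon] = counters.get(taxon, 0) + 1
                    sid = f"{taxon}|{fam}|{counters[taxon]}"
                    gnode.taxon_label_ = sid
                    tip_subfamily[sid] = fam
                    tip_taxon[sid] = taxon
                continue
            pending: list[tuple[dendropy.Node, list[dendropy.Node]]] = []
            for child in snode.child_nodes():
                survivors: list[dendropy.Node] = []
                for gnode in lineages:
                    if rng.random() < params.loss_prob:
                        events.append(
                            Event(fam, _label(snode), _label(child), "loss")
                        )
                        continue
                    if rng.random() < params.dup_prob:
                        events.append(
                            Event(fam, _label(snode), _label(child), "duplication")
                        )
                        copies = 2
                    else:
                        copies = 1
                    blen = child.edge.length or 0.0
                    for _ in range(copies):
                        gchild = dendropy.Node()
                        gchild.edge.length = blen
                        gnode.add_child(gchild)
                        survivors.append(gchild)
                if survivors:
                    presence[_label(child)][fam] = 1
                pending.append((child, survivors))
            stack.extend(reversed(pending))
        gene_trees[fam] = _finalise_gene_tree(root_gene)
    return SimTruth(gene_trees, tip_subfamily, tip_taxon, presence, events, params.seed)


def _label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _finalise_gene_tree(root: dendropy.Node) -> dendropy.Tree | None:
    """Strip extinct branches and unifurcations; None if nothing survives."""
    def alive(node) -> bool:
        if not node.child_nodes():
            return hasattr(node, "taxon_label_")
        for child in list(node.child_nodes()):
            if not alive(child):
                node.remove_child(child)
        return bool(node.child_nodes()) or hasattr(node, "taxon_label_")

    if not alive(root):
        return None
    labels = []

    def collect(node):
        if not node.child_nodes():
            labels.append(node.taxon_label_)
        for c in node.child_nodes():
            collect(c)

    collect(root)
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for nd in tree.leaf_node_iter():
        nd.taxon = tns.get_taxon(nd.taxon_label_)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


def mutate_sequence(
    codes: np.ndarray, rates: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """One branch of evolution: site i mutates with probability
    1 - exp(-rates[i] * t), to a uniform choice among the other 19."""
    if t < 0:
        raise ValueError("negative branch length")
    p = 1.0 - np.exp(-rates * t)
    hit = rng.random(len(codes)) < p
    out = codes.copy()
    if hit.any():
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def evolve_sequences(
    species: SpeciesTree,
    truth: SimTruth,
    params: SimParams,
    root_codes_by_subfamily: dict[str, np.ndarray] | None = None,
) -> list[SeqRecord]:
    """Evolve a random root protein per subfamily along its gene tree.

    Pendant-edge rates are additionally scaled by
    ``params.tip_rate_multipliers`` for the corresponding species tip.
    Root sequences are drawn uniformly unless supplied (e.g. to share roots
    with a separately generated curated backbone).  Returns FASTA-writable
    records carrying the true taxon labels; an extinct subfamily
    contributes no records.
    """
    rng = np.random.default_rng([params.seed, 2])
    rates = params.site_rates() * params.rate_scale
    nsites = len(rates)
    records: list[SeqRecord] = []
    for fam in params.subfamilies:
        gtree = truth.gene_trees.get(fam)
        root_codes = rng.integers(0, 20, size=nsites)
        if root_codes_by_subfamily is not None and fam in root_codes_by_subfamily:
            root_codes = root_codes_by_subfamily[fam]
        if gtree is None:
            continue
        seqs: dict[int, np.ndarray] = {id(gtree.seed_node): root_codes}
        for nd in gtree.seed_node.preorder_iter():
            if nd is gtree.seed_node:
                continue
            parent_codes = seqs[id(nd.parent_node)]
            t = nd.edge.length or 0.0
            mult = 1.0
            if not nd.child_nodes():
                taxon = truth.tip_taxon[nd.taxon.label]
                mult = params.tip_rate_multipliers.get(taxon, 1.0)
            seqs[id(nd)] = mutate_sequence(parent_codes, rates * mult, t, rng)
        for lf in gtree.leaf_node_iter():
            sid = lf.taxon.label
            taxon = truth.tip_taxon[sid]
            info = species.taxa[taxon]
            records.append(
                SeqRecord(
                    seq_id=sid,
                    residues="".join(AA20[c] for c in seqs[id(lf)]),
                    taxon_id=taxon,
                    supergroup=info.supergroup,
                    eu_domain=info.eu_domain,
                )
            )
    return records


def write_events_tsv(events: list[Event], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("character\tedge_parent\tedge_child\tevent\n")
        for ev in events:
            fh.write(f"{ev.character}\t{ev.edge_parent}\t{ev.edge_child}\t{ev.event}\n")
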