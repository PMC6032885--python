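"""Desk-scale tree inference: corrected distances, neighbor joining,
bootstrap supports and long-branch pruning.

This stands in for full Bayesian/ML phylogenetics: distances are
Poisson-corrected mismatch fractions over masked alignment columns, trees are
built by canonical Saitou–Nei neighbor joining with deterministic
tie-breaking, and node supports come from column-resampling bootstrap
replicates.  Trees computed by external engines can be imported as newick
(:func:`read_tree`) and are first-class inputs downstream.

Trees are :class:`dendropy.Tree` objects whose internal nodes may carry a
``support`` attribute in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .profile import ProfileAlignment

DISTANCE_CAP = 5.0
MIN_SHARED_COLUMNS = 10
SATURATION_P = 0.95
DEFAULT_BOOTSTRAPS = 100
DEFAULT_PRUNE_FACTOR = 3.0


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray          # symmetric, zero diagonal, entries >= 0
    shared: np.ndarray          # per-pair shared (both non-gap, masked) columns
    warned: np.ndarray          # True where the cap rule fired

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise TreeError("distance matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise TreeError("non-zero diagonal")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise TreeError("distances must be finite and non-negative")


def pairwise_distance(
    row_i: str,
    row_j: str,
    mask: np.ndarray,
    cap: float = DISTANCE_CAP,
) -> tuple[float, int, bool]:
    """Poisson-corrected distance over masked columns where both rows are
    non-gap: ``d = -ln(1 - p)`` with p the mismatch fraction.  Saturated
    pairs (p >= 0.95) or pairs sharing < 10 columns get the cap with a
    warning flag.  Returns ``(d, shared, warned)``.
    """
    if len(row_i) != len(mask) or len(row_j) != len(mask):
        raise TreeError("rows must have the same width as the mask")
    if not mask.any():
        raise TreeError("zero masked columns")
    a = np.frombuffer(row_i.encode(), dtype=np.uint8)
    b = np.frombuffer(row_j.encode(), dtype=np.uint8)
    gap = ord("-")
    valid = mask & (a != gap) & (b != gap)
    shared = int(valid.sum())
    if shared < MIN_SHARED_COLUMNS:
        return cap, shared, True
    p = float((a[valid] != b[valid]).sum()) / shared
    if p >= SATURATION_P:
        return cap, shared, True
    return -math.log(1.0 - p), shared, False


def distance_matrix(
    rows: dict[str, str], mask: np.ndarray, cap: float = DISTANCE_CAP
) -> DistanceMatrix:
    """All-pairs :func:`pairwise_distance`, vectorised over the alignment."""
    ids = tuple(rows)
    if not mask.any():
        raise TreeError("zero masked columns")
    enc = np.stack(
        [np.frombuffer(rows[i].encode(), dtype=np.uint8) for i in ids]
    )[:, mask]
    gap = ord("-")
    nongap = enc != gap
    valid = nongap[:, None, :] & nongap[None, :, :]
    shared = valid.sum(axis=2)
    mism = ((enc[:, None, :] != enc[None, :, :]) & valid).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, mism / np.maximum(shared, 1), 1.0)
    warned = (shared < MIN_SHARED_COLUMNS) | (p >= SATURATION_P)
    d = np.where(warned, cap, -np.log(np.clip(1.0 - p, 1e-300, 1.0)))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(warned, False)
    return DistanceMatrix(ids, d, shared, warned)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei agglomeration with the Q criterion.

    Ties in Q are broken by the lexicographically smallest joined pair
    (clusters are named by their smallest member label).  Negative estimated
    branch lengths are clamped to 0 with the deficit moved to the sister
    branch.  Returns an unrooted tree (trifurcating seed node).
    """
    n = len(D.ids)
    if n < 3:
        raise TreeError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace(list(D.ids))
    nodes: list[dendropy.Node] = []
    labels: list[str] = list(D.ids)
    for lbl in D.ids:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lbl)
        nodes.append(nd)
    M = D.matrix.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = M.sum(axis=0)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q[i,j] and Q[j,i] can differ by an ulp (summation order), so
        # normalise candidate cells to i < j before tie-breaking
        best = None
        for i, j in np.argwhere(Q == qmin):
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            pair = tuple(sorted((labels[i], labels[j])))
            if best is None or pair < best[0]:
                best = (pair, i, j)
        _, i, j = best
        d = M[i, j]
        li = d / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d - li
        if li < 0:
            li, lj = 0.0, d
        elif lj < 0:
            li, lj = d, 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_d = np.maximum((M[i, :] + M[j, :] - d) / 2.0, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        M = np.vstack([M[keep][:, keep], new_d[keep]])
        M = np.hstack([M, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
    a, b, c = nodes
    dab, dac, dbc = M[0, 1], M[0, 2], M[1, 2]
    a.edge.length = max((dab + dac - dbc) / 2.0, 0.0)
    b.edge.length = max((dab + dbc - dac) / 2.0, 0.0)
    c.edge.length = max((dac + dbc - dab) / 2.0, 0.0)
    center = dendropy.Node()
    for nd in (a, b, c):
        center.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# newick import/export with support dialect handling


def read_tree(source: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Parse newick; internal node labels become supports in [0, 1].

    Both the 0-1 and 0-100 support dialects are accepted: when any label
    exceeds 1, all are divided by 100.  Negative branch lengths are clamped
    to 0.  ``source`` may be newick text or a path to a newick file.
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    rooting = {True: "force-rooted", False: "force-unrooted", None: "default-unrooted"}[
        rooted
    ]
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting=rooting,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc
    supports: list[tuple[dendropy.Node, float]] = []
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None and nd.edge.length < 0:
            nd.edge.length = 0.0
        nd.support = None
        if not nd.is_leaf() and nd.label is not None:
            try:
                supports.append((nd, float(nd.label)))
            except ValueError:
                pass
    scale = 100.0 if any(v > 1.0 for _, v in supports) else 1.0
    for nd, v in supports:
        nd.support = v / scale
        if not 0.0 <= nd.support <= 1.0:
            raise TreeError(f"support {v} outside both dialect ranges")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise to newick with supports as internal labels and branch
    lengths to 6 decimals; optionally write to ``path``."""
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            sup = getattr(nd, "support", None)
            nd.label = None if sup is None else f"{sup:.6g}"
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def clone_tree(tree: dendropy.Tree, rooted: bool | None = None) -> dendropy.Tree:
    """Deep copy preserving lengths and supports (newick round trip)."""
    if rooted is None:
        rooted = tree.is_rooted
    return read_tree(write_tree(tree), rooted=rooted)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartition_keys(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal-edge bipartitions keyed by the tip side not containing the
    lexicographically smallest leaf label."""
    all_labels = set(leaf_labels(tree))
    ref = min(all_labels)
    keys: dict[frozenset, dendropy.Node] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(below) <= 1 or len(below) >= len(all_labels) - 1:
            continue  # trivial bipartition
        key = below if ref not in below else frozenset(all_labels - below)
        keys[key] = nd
    return keys


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: ProfileAlignment,
    n_reps: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
    cap: float = DISTANCE_CAP,
) -> dendropy.Tree:
    """NJ tree from the full masked alignment, with internal-node supports
    set to the frequency of each bipartition among ``n_reps`` column
    bootstrap replicates.  Deterministic given the seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = aln.rows()
    mask = aln.effective_mask()
    ids = tuple(rows)
    enc = np.stack(
        [np.frombuffer(rows[i].encode(), dtype=np.uint8) for i in ids]
    )[:, mask]
    main = neighbor_joining(_matrix_from_encoded(ids, enc, cap))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncols = enc.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = neighbor_joining(_matrix_from_encoded(ids, enc[:, cols], cap))
        for key in bipartition_keys(rep):
            counts[key] = counts.get(key, 0) + 1
    for key, node in bipartition_keys(main).items():
        node.support = counts.get(key, 0) / n_reps
    return main


def _matrix_from_encoded(ids, enc, cap) -> DistanceMatrix:
    gap = ord("-")
    nongap = enc != gap
    valid = nongap[:, None, :] & nongap[None, :, :]
    shared = valid.sum(axis=2)
    mism = ((enc[:, None, :] != enc[None, :, :]) & valid).sum(axis=2)
    p = np.where(shared > 0, mism / np.maximum(shared, 1), 1.0)
    warned = (shared < MIN_SHARED_COLUMNS) | (p >= SATURATION_P)
    d = np.where(warned, cap, -np.log(np.clip(1.0 - p, 1e-300, 1.0)))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(warned, False)
    return DistanceMatrix(tuple(ids), d, shared, warned)


# ---------------------------------------------------------------------------
# long-branch pruning


def prune_long_branches(
    tree: dendropy.Tree,
    factor: float = DEFAULT_PRUNE_FACTOR,
    protected: frozenset[str] | set[str] = frozenset(),
) -> tuple[dendropy.Tree, list[str], list[str]]:
    """Iteratively remove tips whose midpoint-rooted root-to-tip path
    exceeds ``factor`` times the median; recompute after each removal.

    Because midpoint rooting bisects the diameter, a rogue tip drags the
    root toward itself and would mask its own excess; each tip's depth is
    therefore compared to the median depth of the tree with that tip left
    out (re-midpoint-rooted).  Backbone-anchor tips (``protected``) are
    never removed (a warning is logged instead).  Stops with a warning
    rather than pruning below 3 tips.  Returns
    ``(pruned_tree, removed_labels, warnings)``.
    """
    if factor <= 1.0:
        raise ValueError("factor must be > 1")
    tree = clone_tree(tree)
    removed: list[str] = []
    warnings: list[str] = []
    warned_protected: set[str] = set()
    while True:
        depths = _midpoint_depths(tree)
        if len(depths) <= 3:
            break
        offenders = []
        for lbl in sorted(depths, key=lambda x: (-depths[x], x)):
            rest = clone_tree(tree)
            rest.prune_taxa_with_labels([lbl])
            loo = _midpoint_depths(rest)
            med = float(np.median(list(loo.values())))
            if med > 0.0 and depths[lbl] > factor * med:
                offenders.append(lbl)
        for lbl in offenders:
            if lbl in protected and lbl not in warned_protected:
                warnings.append(f"anchor tip {lbl} is long-branching but retained")
                warned_protected.add(lbl)
        offenders = [lbl for lbl in offenders if lbl not in protected]
        if not offenders:
            break
        if len(depths) - 1 < 3:
            warnings.append("pruning stopped: would leave fewer than 3 tips")
            break
        tree.prune_taxa_with_labels([offenders[0]])
        removed.append(offenders[0])
    return tree, removed, warnings


def _midpoint_depths(tree: dendropy.Tree) -> dict[str, float]:
    work = clone_tree(tree, rooted=True)
    work.reroot_at_midpoint(update_bipartitions=False)
    work.calc_node_root_distances(return_leaf_distances_only=False)
    return {lf.taxon.label: lf.root_distance for lf in work.leaf_node_iter()}


def write_distance_tsv(D: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(D.ids) + "\n")
        for i, sid in enumerate(D.ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in D.matrix[i]) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        ids = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        rows = [
            [float(v) for v in line.rstrip("\n").split("\t")[1:]]
            for line in fh
            if line.strip()
        ]
    mat = np.array(rows)
    return DistanceMatrix(
        ids, mat, np.zeros_like(mat, dtype=int), np.zeros_like(mat, dtype=bool)
    )
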