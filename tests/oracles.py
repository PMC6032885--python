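"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: alignments are
scored by enumerating all monotone matchings, parsimony counts by
enumerating all internal labelings, and additive distances come from path
lengths on explicitly constructed trees.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from vps9phylo.align import CODES, profile_scores


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    """Affine gap of ``length`` residues: open + extend per residue."""
    return 0.0 if length == 0 else gap_open + gap_extend * length


def sw_brute(a, b, sub, gap_open=11.0, gap_extend=1.0):
    """Best local alignment score by enumerating monotone matchings.

    A local alignment is determined by its matched index pairs
    (i1<...<ik, j1<...<jk); between consecutive matches each sequence
    contributes one affine gap run.  Terminal gaps do not exist in local
    alignments.  Score floor is 0 (empty alignment).
    """
    ca = [CODES[c] for c in a]
    cb = [CODES[c] for c in b]
    m, n = len(ca), len(cb)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for ii in combinations(range(m), k):
            for jj in combinations(range(n), k):
                score = sum(sub[ca[i], cb[j]] for i, j in zip(ii, jj))
                for t in range(k - 1):
                    score -= _gap_cost(ii[t + 1] - ii[t] - 1, gap_open, gap_extend)
                    score -= _gap_cost(jj[t + 1] - jj[t] - 1, gap_open, gap_extend)
                best = max(best, score)
    return best


def profile_brute(residues, backbone_rows, sub, gap_open=11.0, gap_extend=1.0):
    """Best global sequence-vs-profile score by matching enumeration.

    Unmatched residues are dropped (affine runs), unmatched columns are
    skipped (affine runs); terminal runs are charged.
    """
    P = profile_scores(backbone_rows, sub, gap_extend)
    codes = [CODES[c] for c in residues]
    m, W = len(codes), P.shape[0]
    best = -(_gap_cost(m, gap_open, gap_extend) + _gap_cost(W, gap_open, gap_extend))
    for k in range(1, min(m, W) + 1):
        for ii in combinations(range(m), k):
            for jj in combinations(range(W), k):
                score = sum(P[j, codes[i]] for i, j in zip(ii, jj))
                score -= _gap_cost(ii[0], gap_open, gap_extend)
                score -= _gap_cost(jj[0], gap_open, gap_extend)
                score -= _gap_cost(m - 1 - ii[-1], gap_open, gap_extend)
                score -= _gap_cost(W - 1 - jj[-1], gap_open, gap_extend)
                for t in range(k - 1):
                    score -= _gap_cost(ii[t + 1] - ii[t] - 1, gap_open, gap_extend)
                    score -= _gap_cost(jj[t + 1] - jj[t] - 1, gap_open, gap_extend)
                best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# random additive trees


def random_additive_tree(n_tips: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (newick string, distance dict {(a, b): d}) where distances are
    exact path lengths; tip labels t0..t{n-1}.
    """
    labels = [f"t{i}" for i in range(n_tips)]
    # adjacency list: node -> list of (node, length); tips are labels,
    # internal nodes are negative ints
    adj: dict = {}
    nxt = [-1]

    def connect(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = nxt[0]
    nxt[0] -= 1
    for lbl in labels[:3]:
        connect(center, lbl, blen())
    edges = [(center, lbl) for lbl in labels[:3]]
    for lbl in labels[3:]:
        u, v = edges[rng.integers(0, len(edges))]
        w = next(wt for x, wt in adj[u] if x == v)
        mid = nxt[0]
        nxt[0] -= 1
        adj[u] = [(x, wt) for x, wt in adj[u] if x != v]
        adj[v] = [(x, wt) for x, wt in adj[v] if x != u]
        cut = float(rng.uniform(0.25, 0.75)) * w
        connect(u, mid, cut)
        connect(mid, v, w - cut)
        connect(mid, lbl, blen())
        edges.remove((u, v))
        edges += [(u, mid), (mid, v), (mid, lbl)]
    # exact path lengths by DFS from each tip
    dist: dict = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in labels:
            dist[(src, dst)] = seen[dst]

    def to_newick(u, parent):
        if isinstance(u, str):
            return u
        parts = [
            f"{to_newick(v, u)}:{w:.6f}" for v, w in adj[u] if v != parent
        ]
        return "(" + ",".join(parts) + ")"

    return to_newick(center, None) + ";", dist


# ---------------------------------------------------------------------------
# parsimony brute force


def _tree_arrays(tree):
    """Postorder node list with parent indices and tip labels."""
    nodes = list(tree.seed_node.preorder_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parents = [
        None if nd.parent_node is None else index[id(nd.parent_node)]
        for nd in nodes
    ]
    return nodes, parents


def dollo_brute(tree, states, force_root_gain=False):
    """Minimal loss count over all single-gain labelings; None if the
    character is never present."""
    nodes, parents = _tree_arrays(tree)
    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    tips = [(i, states.get(nd.taxon.label)) for i, nd in enumerate(nodes) if nd.is_leaf()]
    if not any(s == 1 for _, s in tips):
        return None
    best = None
    for bits in product([0, 1], repeat=len(internal)):
        lab = {}
        for i, s in zip(internal, bits):
            lab[i] = s
        ok = True
        for i, s in tips:
            lab[i] = s if s is not None else None
        # unknown tips: choose the parent's state (never forces an event)
        gains = losses = 0
        root_idx = 0
        if force_root_gain and lab[root_idx] != 1:
            continue
        if lab[root_idx] == 1:
            gains += 1
        for i, p in enumerate(parents):
            if p is None:
                continue
            child = lab[i] if lab[i] is not None else lab[p]
            if lab[i] is None:
                lab[i] = child
            if lab[p] == 0 and child == 1:
                gains += 1
            elif lab[p] == 1 and child == 0:
                losses += 1
        if gains <= 1 and all(
            lab[i] == s for i, s in tips if s is not None
        ):
            if best is None or losses < best:
                best = losses
    return best


def fitch_brute(tree, states):
    """Minimal change count over all internal labelings, with UNKNOWN tips
    free to take either state."""
    nodes, parents = _tree_arrays(tree)
    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    unknown = [
        i for i, nd in enumerate(nodes)
        if nd.is_leaf() and states.get(nd.taxon.label) is None
    ]
    fixed = {
        i: states[nd.taxon.label]
        for i, nd in enumerate(nodes)
        if nd.is_leaf() and states.get(nd.taxon.label) is not None
    }
    best = None
    for bits in product([0, 1], repeat=len(internal) + len(unknown)):
        lab = dict(fixed)
        for i, s in zip(internal + unknown, bits):
            lab[i] = s
        changes = sum(
            1
            for i, p in enumerate(parents)
            if p is not None and lab[i] != lab[p]
        )
        if best is None or changes < best:
            best = changes
    return best
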