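"""Homology screening: reciprocal best hits and domain-architecture scans.

The screen mirrors a classical comparative-genomic search stage: candidate
family members are picked up by local alignment against a query set with an
E-value gate (default 0.05), confirmed by a reciprocal search back into the
query's proteome, and annotated with domain architectures by sliding a
position-specific scoring matrix (PSSM) over the protein.  The PSSM is a
gapless stand-in for a profile HMM; the fixture Vps9 model is 104 columns
long, the length of the Vps9 catalytic GEF domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import CODES, E_MAX, HitRecord, blosum62, evalue, bit_score, smith_waterman
from .seqs import AA20, SeqRecord

BACKGROUND = 1.0 / 20.0
#: default acceptance threshold for a PSSM window, in half-bits per column.
THRESHOLD_PER_COLUMN = 0.5


@dataclass(frozen=True)
class DomainModel:
    """Per-column log-odds scores (half-bits) for one protein domain."""

    name: str
    scores: np.ndarray  # (L, 20) half-bit log-odds
    threshold: float    # minimum window score (half-bits) to call a hit

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20 or self.scores.shape[0] < 1:
            raise ValueError("scores must be an (L, 20) matrix with L >= 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DomainHit:
    name: str
    start: int  # 0-based half-open on the protein
    end: int
    score: float


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping domain hits on one protein."""

    hits: tuple[DomainHit, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for h in self.hits:
            if h.start < prev_end:
                raise ValueError("overlapping or unsorted domain hits")
            prev_end = h.end

    def __str__(self) -> str:
        return "-".join(h.name for h in self.hits)


def build_pssm(
    aligned_block: list[str],
    pseudocount: float = 1.0,
    name: str = "model",
    threshold: float | None = None,
) -> DomainModel:
    """Turn an aligned block (rows of equal width, ``-`` for gaps) into a
    PSSM of half-bit log-odds against a uniform 1/20 background.

    score(r, c) = 2 * log2((freq_rc + pc * bg) / (bg * (1 + pc)))
    with freq taken over the column's non-gap residues.
    """
    if len(aligned_block) < 2:
        raise ValueError("need at least 2 rows to build a PSSM")
    width = len(aligned_block[0])
    if any(len(r) != width for r in aligned_block):
        raise ValueError("ragged aligned block")
    scores = np.zeros((width, 20))
    for c in range(width):
        counts = np.zeros(20)
        for row in aligned_block:
            ch = row[c]
            if ch == "-":
                continue
            if ch == "X":
                continue  # unknown residues carry no count
            counts[CODES[ch]] += 1.0
        n = counts.sum()
        if n == 0:
            raise ValueError(f"all-gap column {c} in aligned block")
        freq = counts / n
        scores[c] = 2.0 * np.log2(
            (freq + pseudocount * BACKGROUND) / (BACKGROUND * (1.0 + pseudocount))
        )
    if threshold is None:
        threshold = THRESHOLD_PER_COLUMN * width
    return DomainModel(name=name, scores=scores, threshold=threshold)


def window_scores(model: DomainModel, residues: str) -> np.ndarray:
    """Score of every length-L window of ``residues`` under the model.

    X scores 0 at every column.  Returns an empty array if the sequence is
    shorter than the model.
    """
    L = model.length
    codes = np.array([CODES[c] for c in residues], dtype=np.intp)
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    padded = np.hstack([model.scores, np.zeros((L, 1))])  # X column
    out = np.zeros(n)
    for k in range(L):
        out += padded[k, codes[k : k + n]]
    return out


def scan_domains(seq: SeqRecord, models: list[DomainModel]) -> Architecture:
    """Greedy non-overlapping domain annotation by PSSM sliding windows.

    Every window scoring at or above the model threshold is a candidate;
    candidates are kept highest score first (ties: leftmost, then model
    name), discarding overlaps; the result is coordinate-sorted.
    """
    candidates: list[DomainHit] = []
    for model in models:
        ws = window_scores(model, seq.residues)
        for off in np.nonzero(ws >= model.threshold)[0]:
            off = int(off)
            candidates.append(
                DomainHit(model.name, off, off + model.length, float(ws[off]))
            )
    candidates.sort(key=lambda h: (-h.score, h.start, h.name))
    kept: list[DomainHit] = []
    for h in candidates:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return Architecture(hits=tuple(kept))


# ---------------------------------------------------------------------------
# reciprocal best hits


def _search(
    query: SeqRecord, targets: list[SeqRecord], sub, gap_open, gap_extend
) -> list[HitRecord]:
    hits = []
    for t in targets:
        raw, span_q, span_t = smith_waterman(
            query.residues, t.residues, sub, gap_open, gap_extend
        )
        e = evalue(raw, len(query.residues), len(t.residues))
        hits.append(
            HitRecord(query.seq_id, t.seq_id, raw, bit_score(raw), e, span_q, span_t)
        )
    return hits


def _top(hits: list[HitRecord]) -> HitRecord:
    # ties on E broken by higher raw score, then lexicographic target id
    return min(hits, key=lambda h: (h.evalue, -h.raw_score, h.target_id))


def reciprocal_best_hits(
    queries: list[SeqRecord],
    source: list[SeqRecord],
    target: list[SeqRecord],
    e_max: float = E_MAX,
    ortho_sets: dict[str, set[str]] | None = None,
    sub: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit orthology screen.

    A target sequence is retained iff (i) some query hits it with E < e_max
    (the candidate is paired with its best such query) and (ii) searching the
    candidate back against the *source* proteome returns that query — or a
    member of the query's designated orthologue set — as the top hit with
    E < e_max.  Orthologue sets are explicit (``ortho_sets[query_id]``),
    never inferred.

    Returns ``(candidate_id, query_id)`` pairs sorted by candidate id.
    """
    if not source or not target or not queries:
        return []
    sub = blosum62() if sub is None else sub
    ortho_sets = ortho_sets or {}
    # forward: best query per candidate among hits passing the gate
    best_query: dict[str, HitRecord] = {}
    for q in queries:
        for hit in _search(q, target, sub, gap_open, gap_extend):
            if hit.evalue >= e_max:
                continue
            prev = best_query.get(hit.target_id)
            key = (hit.evalue, -hit.raw_score, hit.query_id)
            if prev is None or key < (prev.evalue, -prev.raw_score, prev.query_id):
                best_query[hit.target_id] = hit
    by_id = {t.seq_id: t for t in target}
    retained: list[tuple[str, str]] = []
    for cand_id in sorted(best_query):
        fwd = best_query[cand_id]
        back = _search(by_id[cand_id], source, sub, gap_open, gap_extend)
        top = _top(back)
        if top.evalue >= e_max:
            continue
        accepted = {fwd.query_id} | ortho_sets.get(fwd.query_id, set())
        if top.target_id in accepted:
            retained.append((cand_id, fwd.query_id))
    return retained


# ---------------------------------------------------------------------------
# TSV serialisation


def write_model_tsv(model: DomainModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={model.name}\tlength={model.length}\tthreshold={model.threshold:g}\n")
        fh.write("column\t" + "\t".join(AA20) + "\n")
        for c in range(model.length):
            fh.write(
                str(c) + "\t" + "\t".join(f"{v:.4f}" for v in model.scores[c]) + "\n"
            )


def read_model_tsv(path: str | Path) -> DomainModel:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(tok.split("=", 1) for tok in header.split("\t"))
        fh.readline()  # column header
        rows = [
            [float(v) for v in line.split("\t")[1:]] for line in fh if line.strip()
        ]
    scores = np.array(rows)
    if scores.shape[0] != int(meta["length"]):
        raise ValueError("model length mismatch")
    return DomainModel(meta["name"], scores, float(meta["threshold"]))


def write_hits_tsv(hits: list[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\traw\tbits\tevalue\tq_start\tq_end\tt_start\tt_end\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.raw_score:g}\t{h.bit_score:.3f}\t"
                f"{h.evalue:.4g}\t{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.target_span[0]}\t{h.target_span[1]}\n"
            )
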