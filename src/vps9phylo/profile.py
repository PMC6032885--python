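"""Backbone profile alignments: iterative augmentation and column masking.

The curated backbone alignment (in the original study, well-classified
metazoan Vps9 sequences) is immutable: every candidate sequence is aligned
independently against the *original* backbone profile, so the result does not
depend on input order, and backbone columns are never split.  An occupancy
mask over the backbone rows then selects the columns trusted for distance
computation, an automated surrogate for manual masking of non-homologous
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import GAP_EXTEND, GAP_OPEN, global_profile_align
from .seqs import SeqRecord

DEFAULT_MIN_OCCUPANCY = 0.5


@dataclass
class ProfileAlignment:
    """Fixed-width backbone rows plus augmented query rows and a column mask."""

    backbone_ids: tuple[str, ...]
    backbone_rows: tuple[str, ...]
    augmented: list[tuple[SeqRecord, str, int]] = field(default_factory=list)
    mask: np.ndarray | None = None  # True = column retained

    def __post_init__(self) -> None:
        if not self.backbone_rows:
            raise ValueError("backbone must be non-empty")
        w = self.width
        if any(len(r) != w for r in self.backbone_rows):
            raise ValueError("ragged backbone rows")
        if len(self.backbone_ids) != len(self.backbone_rows):
            raise ValueError("backbone ids/rows length mismatch")

    @property
    def width(self) -> int:
        return len(self.backbone_rows[0])

    def rows(self) -> dict[str, str]:
        """All rows (backbone first, then augmented) keyed by sequence id."""
        out = dict(zip(self.backbone_ids, self.backbone_rows))
        for rec, row, _ in self.augmented:
            out[rec.seq_id] = row
        return out

    def effective_mask(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        return np.ones(self.width, dtype=bool)


def align_to_profile(
    seq: SeqRecord,
    backbone: ProfileAlignment,
    sub: np.ndarray | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[str, int]:
    """Align one sequence to the backbone profile; returns the width-W
    augmented row and the count of dropped (inserted) query residues."""
    row, dropped, _score = global_profile_align(
        seq.residues, list(backbone.backbone_rows), sub, gap_open, gap_extend
    )
    return row, dropped


def iterative_augment(
    backbone: ProfileAlignment,
    seqs: list[SeqRecord],
    sub: np.ndarray | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> ProfileAlignment:
    """Augment the backbone with each sequence independently.

    Each query is aligned against the original backbone rows only, so the
    result is order-independent and the backbone rows are untouched.
    """
    out = ProfileAlignment(
        backbone_ids=backbone.backbone_ids,
        backbone_rows=backbone.backbone_rows,
        mask=None if backbone.mask is None else backbone.mask.copy(),
    )
    for seq in seqs:
        row, dropped = align_to_profile(seq, backbone, sub, gap_open, gap_extend)
        out.augmented.append((seq, row, dropped))
    return out


def mask_columns(
    aln: ProfileAlignment, min_occupancy: float = DEFAULT_MIN_OCCUPANCY
) -> np.ndarray:
    """Column retained iff the non-gap fraction among *backbone* rows is
    >= min_occupancy (augmented rows never influence the mask)."""
    if not 0.0 < min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in (0, 1]")
    n = len(aln.backbone_rows)
    occ = np.zeros(aln.width)
    for row in aln.backbone_rows:
        occ += np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")
    return occ / n >= min_occupancy


# ---------------------------------------------------------------------------
# file formats: aligned FASTA and single-line 0/1 mask


def write_afa(aln: ProfileAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in aln.rows().items():
            fh.write(f">{sid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def read_afa(path: str | Path, n_backbone: int | None = None) -> ProfileAlignment:
    """Read an aligned FASTA.  All rows are treated as backbone unless
    ``n_backbone`` says how many leading rows form the backbone."""
    ids: list[str] = []
    rows: list[str] = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            else:
                cur.append(line)
    if cur:
        rows.append("".join(cur))
    if n_backbone is None:
        n_backbone = len(rows)
    aln = ProfileAlignment(
        backbone_ids=tuple(ids[:n_backbone]), backbone_rows=tuple(rows[:n_backbone])
    )
    for sid, row in zip(ids[n_backbone:], rows[n_backbone:]):
        aln.augmented.append(
            (SeqRecord(seq_id=sid, residues=row.replace("-", "") or "X"), row, 0)
        )
    return aln


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("".join("1" if m else "0" for m in mask) + "\n")


def read_mask(path: str | Path) -> np.ndarray:
    text = Path(path).read_text().strip()
    return np.array([c == "1" for c in text], dtype=bool)
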