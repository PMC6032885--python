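"""Protein sequence records and FASTA input/output.

A :class:`SeqRecord` carries, besides the residues, the taxonomic labels the
classification pipeline needs: the source taxon, its supergroup (Holozoa,
Fungi, Amoebozoa, Excavata, ...) and the high-level eukaryote domain
(Amorphea / Diaphoretickes / Excavata).  The labels are round-tripped through
FASTA description fields as ``key=value`` tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Full residue alphabet: the 20 amino acids plus X for unknown residues.
ALPHABET = AA20 + "X"

_ALPHABET_SET = frozenset(ALPHABET)

EU_DOMAINS = ("Amorphea", "Diaphoretickes", "Excavata")


class SequenceError(ValueError):
    """Raised for residues outside the 20-letter alphabet (plus X)."""


def validate_residues(residues: str) -> None:
    if not residues:
        raise SequenceError("empty sequence")
    bad = set(residues) - _ALPHABET_SET
    if bad:
        raise SequenceError(
            f"non-amino-acid characters {sorted(bad)!r}; only {ALPHABET} allowed"
        )


@dataclass(frozen=True)
class SeqRecord:
    """One protein sequence with its taxonomic labels."""

    seq_id: str
    residues: str
    taxon_id: str = ""
    supergroup: str = ""
    eu_domain: str = ""

    def __post_init__(self) -> None:
        validate_residues(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "SeqRecord":
        return replace(self, residues=residues)


def _description(rec: SeqRecord) -> str:
    parts = []
    if rec.taxon_id:
        parts.append(f"taxon={rec.taxon_id}")
    if rec.supergroup:
        parts.append(f"supergroup={rec.supergroup}")
    if rec.eu_domain:
        parts.append(f"eu_domain={rec.eu_domain}")
    return " ".join(parts)


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as wrapped (60-column) FASTA with label tokens."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.seq_id, description=_description(r))
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA, recovering ``taxon= supergroup= eu_domain=`` labels."""
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, _, val = token.partition("=")
                fields[key] = val
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(
            SeqRecord(
                seq_id=rec.id,
                residues=str(rec.seq).upper(),
                taxon_id=fields.get("taxon", ""),
                supergroup=fields.get("supergroup", ""),
                eu_domain=fields.get("eu_domain", ""),
            )
        )
    return out
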