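"""Taxon-level metadata shared across modules.

Eukaryotes are organised here by the tripartite domain scheme: Amorphea
(Amoebozoa + Opisthokonta + Apusozoa), Diaphoretickes (Archaeplastida, SAR,
haptophytes, cryptophytes) and Excavata.  Each supergroup maps to exactly
one eukaryote domain.
"""

from __future__ import annotations

from dataclasses import dataclass

EU_DOMAIN_OF_SUPERGROUP: dict[str, str] = {
    "Holozoa": "Amorphea",
    "Fungi": "Amorphea",
    "Apusozoa": "Amorphea",
    "Amoebozoa": "Amorphea",
    "Excavata": "Excavata",
    "Archaeplastida": "Diaphoretickes",
    "Cryptophyta": "Diaphoretickes",
    "SAR": "Diaphoretickes",
    "Haptophyta": "Diaphoretickes",
}


@dataclass(frozen=True)
class TaxonInfo:
    """Labels for one sampled taxon; ``transcriptome`` marks datasets for
    which absence of a gene cannot be claimed."""

    taxon_id: str
    supergroup: str
    eu_domain: str
    transcriptome: bool = False

    def __post_init__(self) -> None:
        expected = EU_DOMAIN_OF_SUPERGROUP.get(self.supergroup)
        if expected is not None and expected != self.eu_domain:
            raise ValueError(
                f"supergroup {self.supergroup} implies eu_domain {expected}, "
                f"got {self.eu_domain}"
            )


def taxon_info(taxon_id: str, supergroup: str, transcriptome: bool = False) -> TaxonInfo:
    return TaxonInfo(
        taxon_id=taxon_id,
        supergroup=supergroup,
        eu_domain=EU_DOMAIN_OF_SUPERGROUP[supergroup],
        transcriptome=transcriptome,
    )
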