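"""Hard-coded study fixtures: the sampled eukaryote species tree, the
per-taxon Vps9 subfamily presence matrix, the backbone catalog, and the
ankyrin+Vps9 architecture characters.

The presence matrix encodes the reported classification of Vps9
domain-containing proteins across eukaryote genomes and amoebozoan
transcriptomes.  Cells stated explicitly in the study text (e.g. the three
Vps9-free taxa, the holozoan restriction of RIN, the amorphean restriction
of the resolved Rabex5 and GAPVD1 subclades, the excavate Alsin orthologues)
are fixed; the remaining cells (marked EDITABLE below) are plausible
encodings of the figure-level distribution and may be adjusted as better
per-taxon counts become available.  Transcriptome-only amoebozoan taxa are
flagged so their zero counts read as UNKNOWN, never as absence.
"""

from __future__ import annotations

import pandas as pd

from .ancestral import PresenceMatrix
from .scrollsaw import BackboneCatalog
from .synthetic import SpeciesTree
from .taxa import TaxonInfo, taxon_info
from .treebuild import read_tree

#: taxon -> (supergroup, transcriptome-only?)
_TAXA: list[tuple[str, str, bool]] = [
    ("Homo_sapiens", "Holozoa", False),
    ("Drosophila_melanogaster", "Holozoa", False),
    ("Monosiga_brevicollis", "Holozoa", False),
    ("Capsaspora_owczarzaki", "Holozoa", False),
    ("Saccharomyces_cerevisiae", "Fungi", False),
    ("Fonticula_alba", "Fungi", False),
    ("Thecamonas_trahens", "Apusozoa", False),
    ("Amastigomonas_sp", "Apusozoa", False),
    ("Dictyostelium_discoideum", "Amoebozoa", False),
    ("Acanthamoeba_castellanii", "Amoebozoa", False),
    ("Trichosphaerium_sp", "Amoebozoa", True),
    ("Mayorella_sp", "Amoebozoa", True),
    ("Sexangularia_sp", "Amoebozoa", True),
    ("Trypanosoma_brucei", "Excavata", False),
    ("Bodo_saltans", "Excavata", False),
    ("Naegleria_gruberi", "Excavata", False),
    ("Giardia_intestinalis", "Excavata", False),
    ("Arabidopsis_thaliana", "Archaeplastida", False),
    ("Chlamydomonas_reinhardtii", "Archaeplastida", False),
    ("Cyanidioschyzon_merolae", "Archaeplastida", False),
    ("Galdieria_sulphuraria", "Archaeplastida", False),
    ("Ectocarpus_siliculosus", "SAR", False),
    ("Aureococcus_anophagefferens", "SAR", False),
    ("Plasmodium_falciparum", "SAR", False),
    ("Emiliania_huxleyi", "Haptophyta", False),
]

# Rooted with an agnostic root between Amorphea and Diaphoretickes+Excavata;
# branch lengths are nominal expected substitutions/site.
# Amastigomonas_sp balances the Apusozoa clade to two tips and carries no
# presence data.  Composed from named sub-clades to keep the nesting legible.
_HOLOZOA = ("((Homo_sapiens:0.15,Drosophila_melanogaster:0.18):0.08,"
            "(Monosiga_brevicollis:0.22,Capsaspora_owczarzaki:0.20):0.06)")
_FUNGI = "(Saccharomyces_cerevisiae:0.30,Fonticula_alba:0.25)"
_APUSOZOA = "(Thecamonas_trahens:0.28,Amastigomonas_sp:0.30)"
_AMOEBOZOA = ("((Dictyostelium_discoideum:0.30,Acanthamoeba_castellanii:0.28):0.06,"
              "(Trichosphaerium_sp:0.25,"
              "(Mayorella_sp:0.22,Sexangularia_sp:0.24):0.05):0.07)")
_ARCHAEPLASTIDA = ("((Arabidopsis_thaliana:0.25,Chlamydomonas_reinhardtii:0.28):0.08,"
                   "(Cyanidioschyzon_merolae:0.30,Galdieria_sulphuraria:0.28):0.10)")
_SAR_HAPTO = ("(((Ectocarpus_siliculosus:0.22,Aureococcus_anophagefferens:0.26):0.08,"
              "Plasmodium_falciparum:0.35):0.06,Emiliania_huxleyi:0.30)")
_EXCAVATA = ("((Trypanosoma_brucei:0.30,Bodo_saltans:0.26):0.12,"
             "(Naegleria_gruberi:0.32,Giardia_intestinalis:0.40):0.06)")
_OPISTHOKONTA = f"({_HOLOZOA}:0.08,{_FUNGI}:0.12)"
_OBAZOA = f"({_OPISTHOKONTA}:0.08,{_APUSOZOA}:0.12)"
_AMORPHEA = f"({_OBAZOA}:0.08,{_AMOEBOZOA}:0.15)"
_DIAPHORETICKES = f"({_ARCHAEPLASTIDA}:0.12,{_SAR_HAPTO}:0.10)"
_TREE_NEWICK = (
    f"({_AMORPHEA}:0.05,({_DIAPHORETICKES}:0.06,{_EXCAVATA}:0.15):0.05);"
)

_COLUMNS = [
    "Rabex5", "GAPVD1", "Rabex5+GAPVD1", "Varp", "Alsin", "Vps9DCP1", "RIN",
    "unclassified",
]

# Paralogue counts per taxon.  None = UNKNOWN (transcriptome rows only).
# Text-fixed cells: Giardia/Cyanidioschyzon/Galdieria all-zero rows; human
# counts (RIN1-3, ALS2+ALS2CL); Rabex5/GAPVD1 subclades confined to
# Amorphea; trypanosomatid+Bodo Alsin; yeast and Fonticula Varp; Thecamonas
# Varp; Ectocarpus/Aureococcus megaclade members incl. the Vps9+ankyrin
# proteins; Vps9DCP1 in Holozoa/Amoebozoa/stramenopiles/Emiliania;
# Dictyostelium DdVarpL2 as unclassified.  EDITABLE cells: Monosiga,
# Acanthamoeba, Chlamydomonas, Plasmodium, Emiliania megaclade counts and
# Drosophila Vps9DCP1.
_MATRIX: dict[str, list[int | None]] = {
    #                          Rbx GAP  R+G Varp Als DCP RIN  uncl
    "Homo_sapiens":            [1,  1,  0,  1,  2,  1,  3,  0],
    "Drosophila_melanogaster": [1,  1,  0,  1,  1,  0,  1,  0],
    "Monosiga_brevicollis":    [1,  1,  0,  1,  0,  0,  0,  0],
    "Capsaspora_owczarzaki":   [1,  0,  0,  1,  1,  1,  1,  0],
    "Saccharomyces_cerevisiae":[1,  0,  0,  1,  0,  0,  0,  0],
    "Fonticula_alba":          [1,  1,  0,  1,  0,  0,  0,  0],
    "Thecamonas_trahens":      [0,  0,  1,  1,  0,  0,  0,  0],
    "Dictyostelium_discoideum":[1,  1,  1,  1,  0,  0,  0,  1],
    "Acanthamoeba_castellanii":[0,  0,  1,  1,  0,  0,  0,  0],
    "Trichosphaerium_sp":      [None, 1, None, None, 1, 1, None, None],
    "Mayorella_sp":            [None, None, None, None, 1, None, None, None],
    "Sexangularia_sp":         [None, 1, None, None, None, None, None, 1],
    "Trypanosoma_brucei":      [0,  0,  1,  0,  1,  0,  0,  0],
    "Bodo_saltans":            [0,  0,  1,  0,  1,  0,  0,  0],
    "Naegleria_gruberi":       [0,  0,  1,  0,  0,  0,  0,  2],
    "Giardia_intestinalis":    [0,  0,  0,  0,  0,  0,  0,  0],
    "Arabidopsis_thaliana":    [0,  0,  1,  1,  0,  0,  0,  0],
    "Chlamydomonas_reinhardtii":[0, 0,  1,  0,  0,  0,  0,  0],
    "Cyanidioschyzon_merolae": [0,  0,  0,  0,  0,  0,  0,  0],
    "Galdieria_sulphuraria":   [0,  0,  0,  0,  0,  0,  0,  0],
    "Ectocarpus_siliculosus":  [0,  0,  2,  1,  0,  1,  0,  0],
    "Aureococcus_anophagefferens":[0, 0, 1,  0,  0,  1,  0,  0],
    "Plasmodium_falciparum":   [0,  0,  1,  0,  0,  0,  0,  0],
    "Emiliania_huxleyi":       [0,  0,  1,  0,  0,  1,  0,  0],
}

# Independent acquisitions of the combined ankyrin-repeat + Vps9
# architecture, one character per phylogenetically distinct subfamily
# context: opisthokont Varp orthologues; the Dictyostelium ankyrin-ankyrin-
# Vps9 protein excluded from the Varp clade; and the stramenopile sequences
# grouping in the Rabex5+GAPVD1 clade.
ANK_VPS9_CHARACTERS: dict[str, set[str]] = {
    "Varp|ANK+Vps9": {
        "Homo_sapiens", "Drosophila_melanogaster",
        "Capsaspora_owczarzaki", "Fonticula_alba",
    },
    "Dictyostelium-specific|ANK+Vps9": {"Dictyostelium_discoideum"},
    "Rabex5+GAPVD1|ANK+Vps9": {
        "Ectocarpus_siliculosus", "Aureococcus_anophagefferens",
    },
}


def fixture_taxa() -> dict[str, TaxonInfo]:
    return {
        name: taxon_info(name, sg, transcriptome)
        for name, sg, transcriptome in _TAXA
    }


def fixture_eukaryote_tree() -> SpeciesTree:
    """The sampled eukaryote phylogeny with supergroup and eukaryote-domain
    tip labels; deterministic (hard-coded newick)."""
    tree = read_tree(_TREE_NEWICK, rooted=True)
    return SpeciesTree(tree=tree, taxa=fixture_taxa())


def fixture_presence_matrix() -> PresenceMatrix:
    """Per-taxon Vps9 subfamily paralogue counts (the Coulson-matrix
    encoding); UNKNOWN for transcriptome-only absences."""
    taxa = fixture_taxa()
    rows = {t: _MATRIX[t] for t in _MATRIX}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_COLUMNS)
    matrix_taxa = {t: taxa[t] for t in df.index}
    return PresenceMatrix(df, matrix_taxa)


def fixture_architecture_characters() -> dict[str, dict[str, int | None]]:
    """ANK+Vps9 architecture presence, one Dollo character per subfamily
    context; taxa not listed are absent (genomes) or UNKNOWN
    (transcriptomes)."""
    taxa = fixture_taxa()
    out: dict[str, dict[str, int | None]] = {}
    for char, present in ANK_VPS9_CHARACTERS.items():
        states: dict[str, int | None] = {}
        for t, info in taxa.items():
            if t in present:
                states[t] = 1
            elif info.transcriptome:
                states[t] = None
            else:
                states[t] = 0
        out[char] = states
    return out


def fixture_backbone_catalog() -> BackboneCatalog:
    """Human query sequences and their subfamilies, with the HsRIN2/RIN
    branch-length normalisation anchor."""
    return BackboneCatalog(
        subfamily_of={
            "HsRabex5": "Rabex5",
            "HsGAPVD1": "GAPVD1",
            "HsVarp": "Varp",
            "HsAlsin": "Alsin",
            "HsVps9DCP1": "Vps9DCP1",
            "HsRIN1": "RIN",
            "HsRIN2": "RIN",
            "HsRIN3": "RIN",
        },
        anchor_id="HsRIN2",
        anchor_clade="RIN",
    )
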