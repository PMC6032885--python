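# vps9phylo

Comparative-phylogenomic classification of the Vps9-domain family of Rab5
GEFs (guanine nucleotide exchange factors) across eukaryotes, and
reconstruction of the family's presence in the LECA (last eukaryotic common
ancestor).

Divergent gene families like the Vps9 GEFs (Rabex5, GAPVD1, Varp, Alsin,
Vps9DCP1, RIN) resist naive phylogenetics: the shared catalytic domain is
short (~104 residues) and evolves fast in many lineages, so global trees
collapse. This package implements the workflow evolutionary cell biologists
use instead:

1. **Homology screen** — candidate family members are found by local
   alignment (Smith–Waterman, BLOSUM62, affine gaps) against characterized
   queries with a Karlin–Altschul E-value gate (`E < 0.05`), confirmed as
   reciprocal best hits back into the query proteome, and annotated with
   domain architectures by sliding position-specific scoring matrices.
2. **Backbone profile alignment** — each candidate is aligned independently
   onto a fixed, curated backbone alignment of confidently classified
   sequences; backbone columns are never split, and an occupancy mask picks
   the columns trusted for distances.
3. **Tree building** — Poisson-corrected distances
   `d = -ln(1 - p)` over masked columns, neighbor joining, column-bootstrap
   supports (100 replicates), and long-branch pruning. Trees from external
   engines are imported as newick (0-1 and 0-100 support dialects).
4. **Scrollsaw classification** — a query is assigned to a subfamily when
   the smallest supported clade (over all rootings) containing it holds
   backbone members of exactly that subfamily; queries grouping with Rabex5
   and GAPVD1 together fall back to the Rabex5+GAPVD1 megaclade. For deep
   phylogenies, the shortest-branching member of each (lineage, subfamily)
   cell is selected, with depths normalised against a reference anchor
   (HsRIN2 to the base of the RIN clade).
5. **Ancestral reconstruction** — presence/absence matrices (tri-state:
   transcriptome-only taxa yield UNKNOWN, never absence), a root-agnostic
   LECA rule (presence in ≥ 2 of Amorphea / Diaphoretickes / Excavata;
   strict Amorphea+Excavata mode available), and Dollo parsimony gain/loss
   mapping cross-checked by Fitch parsimony.

A synthetic gene-family generator (per-branch loss and duplication along a
labelled species tree; slow domain blocks inside fast linkers) provides
ground-truthed data so the whole pipeline can be scored for recovery.

## Worked example

Emit the built-in study fixtures (the sampled eukaryote tree and the
per-taxon subfamily matrix) and reconstruct the ancestral complement:

```
$ vps9phylo fixtures --out-dir fx
fixtures written to fx
$ vps9phylo ancestors --matrix fx/presence_matrix.tsv --tree fx/eukaryote_tree.nwk
LECA complement: Alsin, Rabex5+GAPVD1, Varp, Vps9DCP1
37 events written to events.tsv
```

The LECA complement line says four subfamily characters were present in
taxa of at least two of the three eukaryote domains and are therefore
inferred ancestral; RIN is excluded (holozoan only), as are the resolved
Rabex5 and GAPVD1 subclades (Amorphea only — their split post-dates the
LECA, only the Rabex5+GAPVD1 megaclade is ancestral). `events.tsv` maps
each character's single Dollo gain and its minimal loss edges onto the
species tree, e.g.

```
character  node_or_edge                  event
Alsin      N1                            gain
Alsin      N7->Monosiga_brevicollis      loss
...
```

The synthetic recovery benchmark simulates a five-subfamily history over
the fixture tree (loss 0.2 and duplication 0.1 per branch, one tip at 5x
rate), runs the full pipeline, and scores it against the known truth:

```
$ vps9phylo benchmark --seed 17 --out-dir bench
...
 "metrics": {
  "accuracy": 1.0,
  "wrong_rate": 0.0,
  "fast_tip_picked": false,
  "ancestral_exact": true, ...
```

## Layout

- `src/vps9phylo/` — `screen` (RBH + PSSM scans), `profile` (backbone
  augmentation), `treebuild` (distances/NJ/bootstrap/newick), `scrollsaw`
  (assignment + reduction), `ancestral` (matrices, LECA rule, Dollo/Fitch),
  `synthetic` (simulator), `fixtures` (study tree/matrix), `pipeline` +
  `cli` (orchestration).
- `tests/` — unit and property tests with independent brute-force oracles
  for every dynamic program (alignment enumeration, exhaustive parsimony,
  additive-matrix NJ consistency).
- `docs/methods.md` — model assumptions, parameter defaults, and known
  limitations.
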