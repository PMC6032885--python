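# Methods

This note documents the models, defaults and numerical choices behind
`vps9phylo`, and what the synthetic benchmark does and does not show.

## Homology screen

Local alignment is Smith–Waterman with affine gaps (open 11, extend 1 —
a gap of length L costs 11 + L) over BLOSUM62; unknown residues (X) score 0
against everything. Significance uses Karlin–Altschul statistics with the
conventional gapped-BLOSUM62 parameters λ = 0.267, K = 0.041:
S′ = (λS − ln K)/ln 2 and E = m·n·2^(−S′). The retention gate is E < 0.05
on both the forward and the reciprocal search, and a candidate is kept only
when its reciprocal top hit is the query or a member of the query's
explicitly configured orthologue set — orthologue sets are never inferred.
Alignment ties are broken toward the smallest (start_a, start_b).

Domain models are gapless PSSMs rather than profile HMMs: per-column
half-bit log-odds 2·log₂((f + c/20)/((1 + c)/20)) with pseudocount c = 1
against a uniform background. The default window-acceptance threshold is
0.5 half-bits per column (52 half-bits for the 104-column Vps9 model);
at domain scale this sits several standard deviations above the random-
window score while retaining substantially diverged true copies. It is
deliberately too permissive for toy models of ~10 columns, where callers
should set an explicit threshold. Hits are kept greedily by score (ties:
leftmost, then model name) without overlaps. Truncated domains are not
modelled (no half-model scans).

## Profile alignment and masking

Queries are aligned one at a time against the original backbone only, so
augmentation is order-independent and backbone rows are byte-identical
before and after. The DP is global with affine gaps over backbone columns:
the match score of residue r at column c is the average substitution score
against the column's characters, a backbone gap contributing −gap_extend to
that average. Backbone columns are never split; query residues that would
insert between columns are dropped and counted, and high drop counts are a
useful divergence warning. Traceback prefers match, then the
residue-consuming gap, then the column-consuming gap.

Column masking is an automated surrogate for manual alignment curation:
a column is retained when its non-gap fraction among backbone rows is
≥ `min_occupancy` (default 0.5, inclusive at the boundary); augmented rows
never influence the mask.

## Distances, NJ, bootstrap, pruning

Distances are Poisson-corrected mismatch fractions, d = −ln(1 − p), over
masked columns where both rows are non-gap. Saturated pairs (p ≥ 0.95) or
pairs sharing fewer than 10 columns are capped at 5.0 with a warning flag;
the cap keeps matrices finite while preserving "very far" ordering.

Neighbor joining follows Saitou–Nei with the Q criterion. Two numerical
rules make it deterministic and metric: ties in Q are broken by the
lexicographically smallest joined pair (clusters named by their smallest
member), with candidate argmin cells normalised to i < j because Q[i,j]
and Q[j,i] can differ by one ulp from summation order; negative estimated
branch lengths are clamped to 0 with the deficit moved to the sister
branch.

Bootstrap supports are bipartition frequencies over column resampling
replicates (default 100), mapped onto the full-data NJ tree; a bipartition
absent from every replicate has support 0. NJ and Poisson distances stand
in for Bayesian/ML inference deliberately: the package's claims concern the
classification and ancestral-reconstruction layers, which consume trees,
and externally computed newick trees are first-class inputs.

Long-branch pruning removes tips whose midpoint-rooted root-to-tip depth
exceeds `factor` (default 3.0) times the median. Because midpoint rooting
bisects the tree diameter, a rogue tip drags the root toward itself and
would mask its own excess; each tip is therefore judged against the median
depth of the tree with that tip left out (re-midpoint-rooted), one removal
per round, recomputing after each. Backbone anchors are never removed, and
pruning stops rather than leave fewer than three tips. The 3× threshold is
a declared default, not an inherited rule.

## Scrollsaw classification

The "smallest clade over all rootings" is computed directly on the
unrooted tree via edge cuts: cutting any edge yields the query-side
component, which is exactly the clade some rooting would create, and the
edge's bipartition support applies to either side. A query is assigned to
the subfamily of the smallest such side (ties: traversal order) that
contains backbone members of exactly one subfamily with support ≥
`min_support` (default 0.80; unannotated edges are treated as resolved).
When no pure side exists, the smallest adequately supported side whose
backbone members are exactly Rabex5 and GAPVD1 gives the megaclade
fallback, flagged as such. This formulation avoids committing to a working
root; an earlier rooting-based implementation could tie between the true
inter-subfamily edge and an edge inside a subfamily's backbone clade,
stranding that subfamily's queries.

Branch-length depths are measured from the tip to the base of its
subfamily's clade (the smallest side containing all of that subfamily's
backbone tips and no other backbone), so depths are comparable between
members of one subfamily; a single-tip clade's depth is its pendant edge.
Depths are normalised by the anchor sequence's depth within the anchor
clade (default HsRIN2 within RIN — a clade whose branch lengths stay
comparatively stable between trees); when the anchor is absent the raw
depth is used and flagged. Representative selection takes the minimal
normalised depth per (group, subfamily), ties broken by sequence id, and is
idempotent on its own output.

## Presence matrices and ancestral reconstruction

Counts are tri-state: transcriptome-only taxa (flagged per taxon) report
UNKNOWN instead of 0, and UNKNOWN never counts as presence for the LECA
rule, never forces a Dollo loss, and is marginalised over both states in
Fitch counts.

The default LECA rule is root-agnostic: a character is ancestral when
present in at least two of the three eukaryote domains (Amorphea,
Diaphoretickes, Excavata). The strict Amorphea+Excavata rule is preserved
as an audit mode; the generalisation is the package default because
subfamilies with Amorphea+Diaphoretickes distributions (Varp, Vps9DCP1)
are credited to the LECA in the underlying comparative analysis even
without excavate representatives, which only the two-of-three rule
reproduces.

Dollo mapping places the single gain at the MRCA of the present tips (or
at the root when forced per character) and emits the minimal loss-edge
set: an edge to a maximal presence-free subtree is a loss only if that
subtree contains a known-absent tip. Minimality is property-tested against
exhaustive single-gain labelings. Independent acquisitions of a domain
architecture are counted as one Dollo gain per phylogenetically distinct
subfamily context, cross-context identity being already excluded by the
phylogeny.

## Fixtures

The fixture species tree samples 25 taxa across seven major clade groups
with an agnostic root between Amorphea and Diaphoretickes+Excavata; branch
lengths are nominal. A second apusozoan tip exists only to keep every
clade group at two or more representatives and carries no presence data
(matrix-absent tips are UNKNOWN to the Dollo mapper). In the presence
matrix, cells stated in the comparative analysis's text are fixed — the
three Vps9-free taxa, the holozoan restriction of RIN, the amorphean
restriction of resolved Rabex5/GAPVD1, excavate Alsin, the stramenopile
ankyrin+Vps9 proteins inside the Rabex5+GAPVD1 megaclade — while
figure-level cells without verbatim textual support are marked editable in
the source.

## Synthetic generator and benchmark

The generator's defaults are the benchmark's study conditions: five
root-present subfamilies; loss probability 0.2 and duplication probability
0.1 per branch (per edge, not per unit length, matching the per-edge event
mapping downstream); substitution rate scale 0.5 on nominal branch
lengths; one 104-residue "Vps9-like" domain block at relative rate 0.3
inside 75-residue linkers (sequence length 254); and one deliberately
fast-evolving tip (Plasmodium at 5× on its pendant edge) to exercise the
shortest-branch rule. Substitution is per-site Poisson with uniform
replacement over the other 19 residues — no empirical exchangeability
matrix, no indels, no rate heterogeneity beyond the per-block scaling; the
pipeline needs tunable divergence, not realism. All randomness derives from
one integer seed through fixed child streams (history, sequences, backbone),
so identical parameters reproduce byte-identical FASTA, event lists and
run reports.

The benchmark's curated backbone emulates the study's metazoan backbone:
four sequences per subfamily evolved independently from the subfamily root
sequence along short (0.25) branches, with known labels. Under the default
conditions on the 25-taxon fixture tree this yields a family of ~60
surviving sequences plus 20 backbone rows. Because subfamily root
sequences are mutually random, between-subfamily identity is at chance and
the deep splits are unambiguous; the benchmark therefore demonstrates that
the pipeline's plumbing (screen, augmentation, masking, trees, supports,
edge-cut assignment, depth normalisation, LECA recovery) is correct and
deterministic, not that the method resolves genuinely marginal homology
— real Vps9 subfamilies share ancestry and real alignments contain indels,
so real-data accuracy will be lower than the benchmark's. The
representative-choice metric counts only Scrollsaw cells with two or more
candidates; a cell whose only member is the fast tip offers no choice to
get wrong.

## Known limitations

- The PSSM scan is gapless; indel-containing or truncated domains lose
  score linearly and very divergent domain copies may fall below
  threshold.
- Bootstrap supports on NJ trees are not posterior probabilities; the 0.80
  support threshold is calibrated only in the sense that it is exposed and
  auditable.
- The Dollo model forbids re-gain; convergent architecture assembly is
  handled by splitting characters per subfamily context, which requires
  the phylogenetic contexts to be known.
- Midpoint-based long-branch detection judges one tip at a time; clades of
  jointly long branches shift the leave-one-out baseline and may escape
  pruning.
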