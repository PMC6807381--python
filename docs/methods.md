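# Methods

This note documents the models, conventions and design choices behind
`isfamily`, in the spirit of the methods documentation of distance-based
phylogenetics and sequence-simulation packages.

## Records and coordinates

An IS record is a nucleotide sequence over {A, C, G, T, N} with a single
transposase CDS. Metadata files use 1-based inclusive CDS coordinates (the
GenBank convention of the accessions such catalogues cite); internally all
coordinates are 0-based half-open. Sequences are upper-cased and U is
mapped to T on load. Translation uses the bacterial/archaeal code (table
11) with three conventions: the initiators ATG/GTG/TTG are rendered M, a
terminal stop is dropped, and any codon containing N translates to X —
deliberately stricter than ambiguity-resolving translators (GGN is X here,
not G), because a conservative X can never fake a catalytic residue.
Internal stops are preserved as `*` so that curation, not I/O, decides a
record's fate. N never matches any base in comparisons, itself included.

## Curation and the isoform rule

Records are excluded, in a fixed precedence (transposase length < 150 aa →
`truncated_tnp`; any internal stop → `internal_stop`; then the triad check,
which reports `missing_E`, `missing_D2` or `missing_D1`), so a defective
record always carries exactly one, deterministic reason.

The isoform rule is threshold-based and comparator-relative: record X is an
isoform of reference R when identity(X, R) exceeds 95 % at the nucleotide
level and/or similarity exceeds 98 % at the amino-acid level. "Similarity"
is operationalised as the fraction of aligned columns whose residue pair
scores > 0 in BLOSUM62 (identity is a subset, since diagonal entries are
positive); the nucleotide criterion is plain identity. Because the
published tables distinguish the two statements — DNA *identity* versus
transposase *similarity* — the two matrices are kept separate and the
combination is configurable (`combine` = `any` | `all` | `nt` | `aa`, with
`any`, the literal and/or reading, as the default).

Comparator mode answers "what is an isoform of R"; it cannot partition a
set, which is exactly the instability the comparator-dependence analysis
demonstrates (the IS257/IS431 group partitions differently under IS257R1
than under IS257-1). For a reference-free partition the transitive mode
single-links the same pairwise predicate (connected components). A flips
report lists the records whose status differs between two chosen
comparators. One caveat found while reproducing the published
comparator-dependence statements: under the plain `any` combination the
printed amino-acid similarities alone would qualify every group member
against either comparator, so the demonstration is run with `combine="all"`
(or `"nt"`), the reading consistent with the published table shading that
keys isoform calls to nucleotide identity.

## Alignment

Pairwise alignment is global (Needleman–Wunsch) with affine gaps under the
three-state Gotoh recursion: BLOSUM62 for proteins, +5/−4 for nucleotides,
gap open 10, gap extend 0.1, a run of L gap columns costing
`open + extend·(L−1)`. All four transitions between the two gap states are
admitted, so the dynamic program scores exactly the same alignment space as
a brute-force enumeration that charges each maximal gap run once — the
equivalence is asserted against that enumeration in the tests for every
input up to length 5. Traceback ties are resolved deterministically:
diagonal, then up (gap in the second sequence), then left. Floating-point
equality in the traceback uses a 1e-6 tolerance, far below the 0.1 gap
extension quantum.

Percent identity divides identical columns by all columns *excluding
terminal-overhang gap columns* (internal gap columns remain in the
denominator): end-trimmed comparison matches how near-equal-length IS pairs
are scored in the published matrices, and leaves close pairs insensitive to
ragged ends. A degenerate optimum with no aligned core columns (possible
only for very short unrelated inputs, where two gap runs outscore a run of
mismatches) yields NaN percentages on the alignment object and an error
from the explicit percentage functions.

Identity matrices are built from independent pairwise alignments rather
than induced from one master MSA: the near-identical pairs that drive
isoform calling are insensitive to the choice, and pairwise alignments are
reproducible without replicating any specific progressive-alignment engine.

The progressive MSA uses a neighbour-joining guide tree on
(100 − identity)/100 pairwise distances and merges profiles in post-order
with the same affine dynamic program on column-average substitution scores
(gap mass contributes zero to a column's score — the classic simplification).
Output row order equals input order, and every row de-gaps to its source
sequence by construction.

Column conservation follows the 100 / 80–99 / 60–79 / below shading
convention: the majority residue is the plurality over non-gap rows
(alphabetical tie-break), the similarity fraction counts rows identical or
BLOSUM62-positive against it, and the separate `all_but_k` flag counts
exact residue matches over *all* rows, so a gap row counts as a difference
(k = 0 is complete conservation, k = 3 the "no more than 3 differences"
criterion).

## Distances, trees, bootstrap

Distances between aligned rows delete gap columns per pair (not globally),
take the mismatch fraction p over the retained columns, and apply the
Jukes–Cantor correction d = −((a−1)/a)·ln(1 − a·p/(a−1)) with a = 4 for
nucleotides or the a = 20 generalisation for proteins — the form standard
distance software applies to protein alignments. The correction is
undefined for p ≥ (a−1)/a; that saturation is an error by default, with an
opt-in cap (5 substitutions/site) used inside the bootstrap, where
individual column resamples routinely cross the boundary and a fatal error
would be wrong.

Neighbour joining is the Saitou–Nei algorithm. Q-criterion ties break on
the smallest (i, j) index pair in the current matrix order, so repeated
runs are identical; a negative branch length at a join is clamped to zero
with the deficit moved to the sibling branch, preserving the pair's summed
length. On additive matrices the algorithm provably recovers the
generating tree; the tests check this exactly against an exhaustive
least-squares oracle over all unrooted topologies for n ≤ 6.

The bootstrap draws B column resamples with replacement (one multinomial
draw per replicate), rebuilds the NJ tree on each, and summarises with the
strict-majority (>50 %) consensus; supports are percentages attached as
internal node labels. Strict-majority bipartitions are pairwise
compatible, so the consensus follows from their containment forest. The
per-pair mismatch/usable column masks are precomputed once, which makes a
500-replicate bootstrap on a 20-taxon protein alignment a matter of
seconds. Outgroup rooting splits the outgroup's pendant edge at its
midpoint. Clade assignment is reference-seeded: a clade is the smallest
rooted subtree (MRCA) spanning its reference leaves, leaves in no clade
subtree are "solo", and overlapping clade subtrees are reported as
monophyly violations rather than silently resolved — published clade
labels are membership claims, not a numeric criterion, so violations are
for the analyst to see.

## TIR analysis

Both ends are read outer-to-inner: the left end as the first k bases and
the right end as the reverse complement of the last k (k = 20 by default,
wide enough to span the 14–18 bp consensus region). Left and right ends
are pooled into one profile — the family consensus is a property of both
ends jointly — with per-side profiles available for reporting. The
consensus takes the plurality base per position (alphabetical tie-break,
with an explicit ambiguity flag); `conserved_all` and `conserved_all_but_1`
record complete and all-but-one conservation over the pooled ends. The
perfect-TIR length is the largest k with the first k bases equal to the
reverse complement of the last k. End redefinition is a pure candidate
generator: when an element does not begin GG, trimming exactly one base
from each end is proposed and accepted only if the result begins GG and
ends CC; the original record is never mutated, and corroborating the trim
against independent genomic sequence remains manual evidence outside the
function.

## Motif logic

Signature patterns are ordered residue constraints at positive offsets
from an anchoring E, with the dash notation decoded as single-residue
wildcards: E-DH---K is E·x·D·H·x·x·x·K (the K six residues from the E),
E-SH---R likewise with S/R, and the archaeal E--F---K-R is
E·x·x·F·x·x·x·K·x·R. The triad locator anchors on the first signature
match in the C-terminal half of the protein, takes D2 as the D nearest the
anchor within 25–45 residues upstream (a window bracketing the observed
spacings around 33–34), and D1 as a D 50–130 residues above D2, preferring
a candidate immediately followed by E (the conserved D-E(T) feature) and
otherwise the candidate nearest D2. The windows are configuration, not
biology claims. Census assignment uses first-match precedence
(bacterial DHK, then SHR, then archaeal) so the per-pattern classes are
disjoint. The N-terminal scan reports the first (p, p+5) pair with F at p
and F or Y at p+5 inside a 15-residue window.

## The synthetic-data generator

The generator's defaults are the study conditions: 65 elements of 820 bp
with a 234 aa transposase (the reference element's dimensions), 14 bp TIRs
drawn around the GGTTCTGTTGCAAA consensus with 5 % per-position noise,
DD(34)E with the bacterial signature, two injected isoform copies at ~2 %
target divergence, and a pure-birth (Yule) tree rescaled to unit height.
An archaeal mode swaps in the archaeal signature and an 18 bp TIR.

The ancestral element is left TIR + spacer + ORF + spacer + reverse
complement of the left TIR. The ancestral transposase plants the initiator
M, the F/F pair at positions 3 and 8, D1 with its D-E-T feature, D2, the
anchoring E 32 residues before the C-terminus at the configured spacing,
the signature residues, and conserved G/P residues between the two Ds.

Evolution is per-nucleotide-site substitution with **no indels** — the true
alignment is the stacked leaf sequences, which isolates distance and
topology behaviour from aligner behaviour and keeps every truth quantity
exact. Each tree edge applies one substitution round at the configured
per-site probability (default 0.05). Applying the probability per edge
rather than per unit branch length is deliberate: every split then carries
the same expected signal, so topology recovery measures the method rather
than the luck of short internal edges, and sister leaves sit ~2 edge-rounds
(≈ 7–9 % nucleotide divergence) apart — comfortably outside the >95 %
isoform threshold, as distinct catalogued elements are, since a real
catalogue has its isoforms already collapsed. Branch lengths still define
the truth tree's time scale for length-aware consumers.

Three bookkeeping rules keep the planted truth identifiable and the
generated records valid by construction:

* ORF substitutions are proposed per nucleotide but accepted per codon:
  proposals creating a stop codon or a D or E are redirected to another
  base. Together with an ancestral protein drawn from the 18 non-D/E
  amino acids, the planted triad is the *unique* solution of the locator's
  search rule, and no record can acquire an internal stop.
* The triad, signature, initiator and stop positions are locked (rate 0).
  A leaked substitution at ~0.001/site/edge would otherwise break the
  "every generated record passes curation" and "triad recovered exactly"
  guarantees a few times per large simulation, which would make ground
  truth a moving target rather than add realism.
* A conserved-site mask (default 10 % of codons, matching the couple of
  dozen highly conserved residues per domain seen in real alignments) and
  the F/Y pair evolve at a 50-fold suppressed rate, so "no more than k
  differences" columns arise naturally at realistic family sizes.

Isoform copies are appended after the tree walk by re-mutating a chosen
leaf at the target divergence; TIR noise is applied independently per leaf
and per side at the leaves (TIRs are under selection, not drifting along
the tree). The truth object records the generating tree (Newick), clade
labels (subtrees cut at a configured depth, default 2), isoform pairs,
planted triad positions, per-record realised TIR ends and boundaries, and
the full pairwise nucleotide-divergence matrix for oracle checks.

What the generator does *not* emulate — indels, codon/rate heterogeneity
beyond the conserved mask, horizontal transfer, genomic flanking context
and TSDs, and length variation between family members — bounds what
passing tests show: they validate the pipeline's logic and statistics on
families whose alignment is unambiguous, not the behaviour of any aligner
on length-variable real data.

## Problem sizes and numerical choices

Simulation-based checks run at family sizes of 20–65 taxa with 50
replicates for topology recovery and 200 proteins for triad recovery, and
the bootstrap summary uses 500 column resamples — sizes at which every
check completes in seconds to a couple of minutes on one CPU while leaving
the measured rates far from their thresholds. Deterministic seeding flows
from a single integer: the simulator, the bootstrap and the acceptance
script all derive their generators from explicit seeds, and identical
seeds give byte-identical outputs (the pipeline's provenance block echoes
the configuration without the output path for that reason).

## Known limitations

* Comparator-dependence of the isoform rule is reported, not resolved; the
  package never auto-selects a "best" comparator and never renames records.
* The aligner's percentages are defined by this package's conventions
  (end-trimmed denominator, BLOSUM62-positive similarity); other software
  applies slightly different denominators and will differ in the second
  decimal for distant pairs.
* Clade delimitation requires reference membership; there is no de novo
  numeric clade criterion, by design.
* Secondary-structure annotation (H-HTH, zinc-finger extents) is accepted
  only as optional user-supplied input; no structure prediction is done.
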