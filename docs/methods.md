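# Methods

## The model

A circular-intermediate duplication is parameterized by a donor interval
A..D, an opening point B/C strictly inside it, an acceptor point α/β
outside it, an orientation (parallel or reverse-complement insertion), and
three junction scars. Conceptually the donor is excised-by-copy into a
circle (fusing D to A at the A/D junction), the circle opens at B/C, and
the linearized fragment (C..D)(A..B) integrates at the acceptor, creating
junctions β-C and B-α. The derivative therefore carries the donor blocks
in swapped order with unchanged relative orientation — the A-B/C-D →
B-A/D-C flip — which is the detection target throughout the package.
Copy number is fixed at two (one reintegration, no rolling circle).

Competing mechanisms map onto decoys: a tandem duplication gives plain
(unswapped) adjacency, and a transposition followed by a single inversion
gives B-A/C-D with *mixed* orientation flags between the two block pairs.
Both fail the flip predicate by construction; the predicate's three
clauses (donor adjacency, swapped derivative adjacency, equal orientation
flags) are each what excludes one alternative.

## Coordinates and data model

All coordinates are 0-based half-open. SD records carry one *relative*
orientation flag ('+' parallel / '−' inverted), matching the
genomicSuperDups `strand` column; no absolute per-side strand is modeled
because the flip predicate only consumes relative orientation. Annotation
tables list each duplication from both anchors; parsing keeps the mirror
rows (lossless) and the filter cascade collapses them with a
side-order-invariant pair key.

The `bedpe_min` dialect is defined as 1-based fully-closed on disk and
converted at parse time, keeping a single internal convention.

## Filtering

Stages run in a fixed order (low homology < 0.93, strict; non-canonical
chromosomes; exclusion overlap; density; repetition; mirror collapse), so
reports are deterministic and re-filtering is idempotent. Two stages
needed concrete definitions:

- **Density**: windows of 1 Mb tiling each chromosome at half-window
  steps; a record is masked when either side's midpoint lies in a window
  holding more than 10 SD side midpoints. This formalizes "avoid SD
  jungles" with a standard windowing scheme; both parameters are exposed.
- **Repetition**: SD sides clustered by ≥ 50% reciprocal overlap
  (union-find over a per-chromosome sweep); a record is masked when its
  side's cluster pairs with more than 4 distinct partner clusters. This
  counts how often a duplicon recurs rather than how many raw rows
  mention it.

Telomere pads of 500 kb per chromosome end are added only when the
supplied exclusion BED has no entry anchored at that end; a
centromere/gap BED is used verbatim.

## Flip scan and extension

The scan tests both side assignments of every record (donor/derivative
labelling is symmetric at detection time; polarity comes later from
cross-species evidence), indexes donor sides per chromosome, and collapses
mirror hits to one candidate per record pair with a deterministic
representative. Junction gap tolerance defaults to 10 kb with 100 bp
permitted overlap: scars themselves are bp-scale, but annotation endpoints
are imprecise and SD callers double-count junction-spanning homology.
Candidates are ranked by |donor gap| + |derivative gap| — tight junctions
first — replacing manual curation with an auditable ordering; nothing is
auto-rejected.

Extension absorbs a record only when its donor side *and* its mate lie
within 50 kb of the current spans (the both-sides condition), assigning it
to the A-B or C-D block by which side of B/C its donor midpoint falls on.
The loop runs to a fixed point; donor–derivative distance is the gap
between the final hulls (0 when they touch), reported in Mb, with
inter-chromosomal clusters flagged instead.

## Dot-matrix classification

Exact k-mer seeding (default k=16; k=12 recommended below ~95% identity)
with words containing N or occurring more than 10 times in either
sequence excluded; forward and reverse-complement seeds are merged into
maximal runs along their (anti)diagonal when separated by ≤ 2k bp.

Classification groups forward runs by diagonal offset before judging
geometry: substitution divergence fragments a block's diagonal into many
short runs at the *same* offset, and the group hull — not the individual
fragments — is the evidence for the block. `flip_parallel` requires
significant (≥ 1 kb summed) forward groups at offsets of both signs whose
hulls jointly cover ≥ 50% of both axes and overlap each other by ≤ 25%
(the swap partitions both axes). Coverage from hulls rather than run
unions is what keeps the call stable to 7% divergence at k=12. Clusters
annotated as inverted ('−') are plotted against the reverse complement of
the derivative, which restores both block diagonals to slope +1.

## Junction resolution

A junction is resolved by choosing split points s_l ≤ s_r in the junction
read and flank deletions d_l, d_r ≤ 100 bp minimizing

    4·(mismatches of read[:s_l] vs left ref ending at break − d_l)
  + 4·(mismatches of read[s_r:] vs right ref starting at break + d_r)
  + 3·(d_l + d_r + (s_r − s_l))

in integer quarter-mismatch units, i.e. a gap base costs 0.75 of a
mismatch. The bound 0.5 < gap < 1 is load-bearing: above 0.5 a single
flank mismatch is never reinterpreted as a 1 bp deletion plus 1 bp
insertion; below 1.0 a true m-bp insertion is never absorbed as
mismatches. Ties break toward the leftmost split, then the smallest
deletion — deterministic and mirror-consistent (resolving the
reverse-complemented junction yields the mirrored scar). Alignment is
gap-free per flank (scars are short and anchored), organized by diagonal
offset so one numpy prefix-sum serves every split; reference windows must
extend past their breakpoints by the read half-window plus the indel
budget.

**Microhomology** is detected as deletion reclaim: when the optimal
assignment skips d reference bases whose sequence is present in the read
adjacent to the breakpoint — i.e. those bases align perfectly to *both*
references — the apparent deletion is reclassified as a d-bp junctional
microhomology. Reclaim is all-or-nothing: partial reclaim would turn a
deletion whose boundary base coincidentally matches into a spurious
mh+del mix, violating the microhomology-XOR-insertion invariant the scar
vocabulary is built on. Under this definition a blunt join never acquires
coincidental microhomology from the external flank.

Unresolvable junctions (N runs in a window, anchors that do not align
within a 25% mismatch budget over 20 bp) are reported as such, mirroring
the fraction of real clusters whose breakpoints sit in gaps or nested SDs.
A caveat on inputs: junction references are cut at the cluster's
breakpoint coordinates, so exact scar recovery requires
breakpoint-accurate spans (truth-derived geometry in simulations).
Geometry derived from emulated annotations instead absorbs the scar bases
into the block boundaries — an equivalent parameterization in which the
same junction legitimately reads blunt-shifted.

The flank screen computes best local-alignment score (match +1, mismatch
−1, gap −2; direct and reverse-complement) between every pair of ±500 bp
breakpoint flanks, flagging scores ≥ 50 — far above the ~20 expected for
unrelated 1 kb sequences and far below a genuine shared element — and
scans each flank for inverted repeats (exact ≥ 10 bp arms, spacer
≤ 100 bp). A positive screen is NAHR-compatible evidence *against* the
circular-intermediate call.

## Timing

The species ladder is linear (human, chimpanzee, gorilla, orangutan,
gibbon, green monkey, marmoset): the age call is "nearest species lacking
the derivative", which a ladder captures fully without tree structure.
Presence is an input ("locus alignable in that assembly"), not computed
from primate genomes. Unknown entries are skipped, never read as absence
— assembly gaps caused most unresolvable cases in practice — and a table
with no informative outgroup entry raises rather than returning a
misleading sentinel. Polarization takes the locus present in strictly
more outgroup species as ancestral; ties stay unpolarized. A helper
checks that pair identity decreases weakly with origin age and reports
(never fails on) violations.

## Synthetic data

The generator is first-class, tested code; its defaults *are* the study
conditions: donors 20–500 kb (log-uniform), opening point uniform in the
central 30–70% of the donor, divergence 0–7% (pair identity 93–100%),
both orientations, 25% inter-chromosomal acceptors, scars drawn per
junction uniformly over {blunt, microhomology 1–2 bp, insertion 1–27 bp,
deletion 1–27 bp}, and as many decoys (alternating tandem duplication and
transposition+inversion) as planted events. Default genomes are four
12 Mb chromosomes at GC 0.41 with ≥ 260 kb spacing between loci (clear of
the density mask) and 600 kb clear of chromosome ends (clear of telomere
pads).

Two generator properties make single-base ground truth well-defined:

- **Scar canonicality.** Microhomology motifs are written onto both
  flanks before extraction; a deleted boundary base is mutated (in the
  ancestral copy only) whenever it equals the base joined across it.
  Without this, a drawn deletion can be byte-identical to a microhomology
  junction and no resolver could recover "the" truth.
- **Scar-core protection.** Divergence mutations never land inside a
  microhomology motif or an inserted sequence: a mutated motif is, by
  definition, no longer a microhomology, so mutating it would silently
  change the observable truth rather than add noise.

Divergence is substitutions only, keeping truth coordinates exact; the
annotation emulator reports the *aligned* block pairs (scar bases
trimmed), frac_match = 1 − divergence, and optional endpoint jitter.
Multi-event datasets pre-plan non-overlapping loci and shift all
downstream coordinates after each insertion.

What the simulations do not emulate: repeat landscapes (Alu/LINE
density), indel divergence, alignment-caller endpoint bias beyond uniform
jitter, assembly gaps, and SD "jungles". Passing tests therefore
demonstrate correctness of the detection geometry, scar algebra and
statistics on clean annotations, not robustness to every artifact of real
SD tables.

## Problem sizes and numerical choices

The shipped study dataset uses 20 planted events + 20 decoys on 48 Mb of
genome, 500 simulated junctions with flank divergence ≤ 2%, and k=12
dot plots; exhaustive-oracle comparisons run at ≤ 500 records (pair
scan), ≤ 10 kb (dot matrix) and ≤ 200 bp reads (junction splits). All
randomness flows from explicit integer seeds; every derived seed stays
below 2³¹. Degenerate inputs have defined behaviour: empty tables filter
and scan to empty outputs, empty cluster lists refuse to summarize,
single-cluster summaries return that cluster's values, and pipeline
stages lacking their optional inputs mark outputs "not computed" rather
than failing.

## Known limitations

- Exact junction scars require breakpoint-accurate cluster spans (see
  above); jittered annotations degrade scars gracefully toward
  blunt/approximate rather than failing.
- The density and repetition filter definitions are declared
  formalizations; on real genomicSuperDups tables their parameters may
  need tuning to match any particular published working-set size.
- No NHEJ-vs-MMBIR verdict is attempted: junction sequence features are
  insufficient to distinguish the pathways, so only the scar vocabulary
  is reported.
- Deletions co-occurring with microhomology/insertion at one seam are
  representable but not canonicalized; the resolver reports such
  junctions faithfully as its cost optimum sees them.
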