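# Methods

`bcenmap` reconstructs, on synthetic data, the chain of methods used to
build a molecular map of the maize B chromosome centromere: transposon
display (TD) against the CRM2 centromeric retroelement, deletion mapping
across centromere-misdivision derivatives, assembly of the marker
"minimal map" pseudocontig, CENH3 ChIP-seq enrichment scoring on that
map, and the strict multi-library rule that identifies the functional
centromere core.  This note records the model behind each stage, the
parameters that matter, and the design decisions taken where the
procedure left genuine freedom.

All coordinates are 0-based, half-open.  Every stochastic operation is a
pure function of its inputs and a seed; a master seed fans out to
per-operation child generators through a fixed CRC32-tagged
`SeedSequence` derivation, so whole experiments are reproducible from a
single integer.

## The synthetic repeat landscape (`repeatscape`)

**Repeat library.** Consensus sequences are drawn uniformly at random:
a 156-bp CentC-like satellite monomer, a B-repeat-like unit (1.1 kb), two
filler retroelements, and a CRM2-like element composed of a 5' LTR
(160 bp), an internal domain (280 bp) and a 3' LTR.  The 5' LTR carries
the two primer-annealing segments of the TD assay at fixed offsets
(selective at 92–112, primary at 130–150) and is kept free of the BfaI
recognition site so that the first cut site downstream of a primer is
always the planted one.  The 3' LTR is an unrelated variant without the
annealing segments, so each insertion yields exactly one display band;
this models the empirical fact that a single LTR primer family recovers
one tag per insertion point.  Distinct units are verified to share no
exact 40-mer, which is what makes junctions resolvable at seed length.

**Centromere.** The centromere is a CentC tandem backbone interspersed
with five B-repeat blocks (~36 kb of backbone by default), into which 40
CRM2-like copies are inserted one at a time at random positions —
possibly nested inside an earlier insertion's body, the arrangement that
generates unique junctions in real centromeres.  Each placed copy is an
independently mutated copy of its consensus: 8 % per-base substitution
for satellite monomers, element bodies and LTRs (the two primer islands
stay exact).  Two copies of a family therefore differ by ~15 %, which is
the regime in which 150-nt reads from one copy cannot be mistaken for
another, while copies still share most of their sequence.  This is the
deliberately "old, diverged" end of what maize centromeric repeat
families show; the consequence for interpretation is discussed under
*Limitations*.

**Planted bands.** For each insertion a BfaI site (C^TAG) is planted on
the outward side of the 5' LTR at the distance that makes the amplified
band exactly the prescribed size, and every stray recognition site
inside the band window is removed by point changes.  Default band sizes
are the study system's 40 printed band sizes rescaled by
largest-remainder apportionment to a 10,100-bp total (printed gel sizes
include adapter/primer tails, and the minimal map is reported as
10.1 kb of sequence; the rescaling reconciles the two while preserving
the size profile).  Band windows are kept ≥ 260 bp apart (reservation
padding at insertion time) so that one marker's ChIP enrichment can
never bleed measurable coverage onto a neighbour — 260 bp is the
smallest gap at which no read can both start in one marker's enriched
zone and retain a seedable (≥ 40 bp) overlap with the next marker.
The layout records every junction and verifies, before returning, that
each planted band is recovered at exactly its prescribed size; an
infeasible request (too many insertions for the backbone) raises.

**B chromosome, arms, background, miniB.** The full B chromosome is
two 15-kb arms flanking the centromere; the arms carry 21 further
insertions (sizes 450–650 bp, disjoint from the centromeric size grid),
modelling the TD markers that later prove extracentromeric.  The B-less
background genome (~33 kb) contains unique DNA, filler-element copies, a
diverged CentC array of its own — the role the reference genome's
centromeres play for control reads — and two CRM2 copies shared by both
genotypes, whose bands cancel in the display comparison.  The miniB is
the centromere sequence alone.

**Misdivision pedigree.** Misdivision is modelled as one terminal-side
excision per event: a derivative's sequence is its parent's minus a
prefix (or suffix), so retained intervals are nested down the pedigree
by construction.  Ring derivatives are not modelled.  The default
pedigree mirrors the study design — root, then four successive
left-side excisions cut midway between marker footprints so that 5, 1,
1 and 2 markers are lost per generation — plus two side branches: one
carrying the same excision as its sibling (the Telo4-11 analog, built
with excision fraction 0 from the Telo2-2 analog) and one whose
excision removes the entire CENH3 core (the Telo3-3 analog).  A
fraction of exactly 1.0 in a pedigree spec means "cut through the far
edge of the CENH3 domain".

**ChIP-seq read model.** Single-end, fixed-length (150 nt, matching the
longer real libraries), error-free by default with a configurable
substitution rate, no indels — the downstream analysis needs only
placement and depth.  Read start positions are drawn with density 1
outside and *f* inside each enriched interval; reads come off either
strand with probability 0.5.  Enriched intervals are the marker
footprints padded by read_length − k = 110 bp on each side: exactly the
start positions whose reads can still seed on the marker, so the
measured marker coverage is not artificially depleted at the edges,
while the padding adds no coverage anywhere else that is mappable.  For
the inactive-centromere role the CENH3 domain is forced back to fold 1
(the chromosome is present, the centromere silent); the
fragmented-control role ignores the fold map entirely.  With ≥ 200×
background coverage the realized per-base coverage ratio over a planted
interval reproduces the requested fold within ±15 % (tested at folds 1,
6 and 36).

## Transposon display (`td_sim`)

Digestion cuts at every recognition occurrence on either strand (BfaI's
CTAG is its own reverse complement; non-palindromic enzymes are handled
by mapping minus-strand cut offsets).  Amplification scans both strands
for exact occurrences of the selective LTR primer (20 nt; no
thermodynamic model) and extends to the first downstream cut site; a
band longer than 1 kb is considered gel-unresolvable and dropped.  The
selective triplet of a band is defined as the three genomic bases
immediately 5' of the recognition site on the amplified strand — the
bases the adapter primer's +NNN extension reads; the study's marker
names include triplets unconstrained by the recognition sequence, which
fixes this convention.  Weak selectivity of the adapter bases is a
Hamming mismatch tolerance (default 0; at tolerance ≥ 1 one fragment
amplifies in several lanes, which is how multi-triplet marker names
arise).  `run_display` always produces 64 lanes per genotype; a band is
B-specific iff no band of the same size (± a configurable bin
tolerance) occurs in the B− lane of the same triplet.  Identical band
sequences collapse to one marker named
`CRM2-<triplet>-…-<size>` with triplets in lexicographic lane-scan
order of first amplification (the discovery order is not recorded in
the original naming; lane order is the deterministic stand-in), and the
name parses back to its triplets and size.  The miniB screen keeps a
marker iff its full band sequence occurs (either strand) in the
centromere-only chromosome.

## Deletion mapping and the minimal map (`deletion_map`)

Presence of a marker in a derivative is full-band substring occurrence,
the in-silico analog of the band amplifying from that chromosome.
Nestedness validation reports every (marker, derivative) pair where a
child shows a band its parent lacks; the check is pedigree-driven and
invariant to column order.  Markers sharing a presence pattern form one
group; groups are ordered by the generation of first loss along the
main pedigree chain (the matrix's column order restricted to the
parent path), never-lost markers last.  A non-nested matrix is still
partitioned, with violations attached, because real gel scoring can
produce such rows.  Within a group the true marker order is unknowable
from deletion data; discovery id fixes it deterministically.  The
pseudocontig joins marker sequences in that order with literal 200-N
spacers; marker intervals and LTR/flank junction offsets (always 112 bp
into a band) are carried along for the ChIP stage.

## Unique mapping and enrichment (`chipmap`)

The mapping reference is the background genome plus the pseudocontig —
the centromere itself is represented only by its markers, as in the
real analysis where the B chromosome is absent from the reference
assembly.  The aligner indexes every N-free 40-mer (the seed length
used in the original alignment protocol), seeds each read at three
offsets on both strands, and scores every candidate by ungapped
extension with mismatch penalties (match +1, mismatch −4; reference Ns
are clipped: they neither match nor penalize, so a read overhanging a
spacer competes with its exact overlap only).  A read is kept iff a
single best placement exists, it clears the runner-up by a margin of 5,
and its identity over aligned non-N positions is ≥ 0.95.  This triple
rule is the desk-scale counterpart of "unique hits only / MAPQ ≥ 30":
the margin enforces uniqueness, the penalties make a clipped exact
placement beat a full-length alignment to a diverged repeat copy (what
a soft-clipping aligner would do), and the identity floor discards
reads whose true locus is absent from the reference rather than letting
them land on a 90 %-similar copy.  Placements starting inside an
N-separator are attributed to the reference holding their aligned
content.  Coverage is per-base depth of clipped aligned spans, scaled
per million mapped reads per library; a marker's fold enrichment is its
scaled mean coverage divided by the scaled genome-wide mean of the
background reference (the analog of comparing to the whole-genome
average).  Junction coverage requires every base of the marker at depth
≥ 1 and at least one read spanning the LTR/flank junction with ≥ 10 nt
on both sides.  Through this whole chain a planted fold is recovered
within ±15 % (tested at folds 1, 6, 36); the systematic part of the
residual (~5–10 % low) is edge loss — reads overlapping a marker end
by less than a seed length, or whose off-marker half aligns better to a
repeat copy elsewhere, cannot contribute — which is a property of any
unique-mapping analysis of junction markers, not of the simulation.

## Core classification and PCR conversion (`coreclass`)

A marker is CENH3-core iff fold > 2 in **every** active replicate, fold
≤ 2 in every inactive replicate, **zero** uniquely mapped coverage in
every negative/fragmented control, and junction-spanning coverage in
every active replicate.  The active threshold is exposed as `t_active`
(default 2.0): the study never states its active cutoff, but a marker
with threefold enrichment is scored positive, so the default sits below
3.  "No enrichment" for controls is implemented as the strictest
reading — zero unique coverage — which the simulation makes structural:
control reads come from the B-less genome, every locus of which is in
the reference, so no control read can ever win a placement on the map.
The classifier is monotone in both thresholds.

The core-domain span combines the calls with transmission biology,
which is an input, not a computation: given the set of derivatives with
unreduced transmission, the span is the marker suffix retained by the
smallest of them (it must retain at least one called marker).  On the
packaged published table with {TB-9Sb, PI, Telo2-1, Iso3} functional,
this yields TD8–TD40, 33 markers.  Note the span deliberately need not
contain every CENH3-positive marker: a marker lost by a
still-functional derivative (TD7) is excluded even though it binds
CENH3 — that is the point of the rule.  CENH3 interaction and
PCR-convertibility are independent marker attributes in the packaged
table (bold vs asterisk); the synthetic pipeline designs its junction
pairs for the CENH3-called markers, whose amplicons its Telo3-3 analog
must lack.

Junction-junction PCR pairs put one 20-nt primer straddling the
LTR/flank junction (≥ 5 nt each side, reverse-complemented) and slide
the forward primer along the LTR tag until in-silico PCR — convergent
primer sites within 2 kb, zero mismatches, both pair orientations
scanned — yields exactly one product from the B+ genome and none from
B−.  Because the amplicon lies inside the band, a pair amplifies from a
derivative exactly when the marker's band survives there, so PCR
genotyping reproduces the presence matrix row-for-row.

## Default study conditions

| parameter | default | rationale |
|---|---|---|
| centromere backbone / final size | 36 kb / ~60 kb | desk-scale stand-in for the 700-kb core; all sizes configurable |
| centromeric insertions | 40 | one per mapped marker; the true copy number is unknown |
| arm insertions | 21 | the markers later shown extracentromeric (61 − 40) |
| marker lengths | printed sizes rescaled to Σ = 10,100 bp | see *Planted bands* |
| read length / seed k | 150 nt / 40 | the longer real libraries; the alignment protocol's seed |
| uniqueness margin / identity floor | 5 / 0.95 | unique-hit filter analog |
| active coverage | 30× background per replicate | puts the threefold marker ~4 s.d. above the twofold threshold |
| inactive/control coverage | 15× | ceilings and zero-checks need less depth |
| libraries | 3 active + 2 inactive + 1 CENH3 control + 1 fragmented control | the seven-library design |
| planted folds | 36, 3, 18, 12, 23, 6, 31 at map slots 7, 9, 10, 15, 18, 21, 29 | the printed per-marker enrichment values, used as simulation parameters |
| `t_active` / `t_inactive` | 2.0 / 2.0 | see *Core classification* |

With these conditions one full experiment runs in ~3 s and the 20-seed
classifier-recovery study in under a minute on one CPU.

## What the generator does and does not emulate

It emulates: unique junction creation by nested transposon insertion in
a satellite/retroelement landscape; restriction-site polymorphism as
the source of band-size variation; terminal nested deletions from
misdivision; a reference genome lacking the chromosome of interest; the
seven-library ChIP design with an epigenetically inactive centromere;
per-copy repeat divergence that makes junctions — but not repeat
interiors — uniquely mappable.

It does not emulate: sequencing errors or quality variation (reads are
error-free by default; trimming is reduced to a length filter), indels
and structural variation within repeat copies, PCR amplification biases
and heteroduplex artifacts of real AFLP gels, chromatin-level
variability of ChIP (enrichment is a clean two-level step function),
partially informative gel scoring, or ring-chromosome derivatives.
Passing tests therefore show the *logic* of the marker pipeline is
sound — counts, partitions, folds and calls follow from the planted
structure — not that the procedure is robust to the noise sources of
real gels and libraries.  In particular, real repeat families that are
younger (less diverged) than the 8 % used here would lose more edge
coverage to multi-mapping than the calibration tests show.

## Numerical choices and degenerate inputs

Band sizes are exact integers (gels resolve integers); the adapter tail
constant defaults to 0 so size equals sequence length.  Zero digestion
sites yield one fragment, not an error; a selective primer absent from
a genome yields an empty band list.  Collapse of an empty band list,
pseudocontigs from an empty marker list, non-positive read counts,
fold intervals outside the genome, zero genome coverage, a pedigree
that is not a tree, and deletions outside the parent all raise
`ValueError` with a specific message.  Ties in mapping (two equal best
placements) are discarded as ambiguous rather than broken arbitrarily.
Group-order ties in partitioning are broken by the pattern tuple for
determinism.

## Known limitations

* The recovered fold systematically underestimates the planted fold by
  ~5–10 % (edge loss, see above); the calibration contract is ±15 %.
* Exactly-one-band-per-insertion relies on the 3' LTR lacking the
  primer sites; with identical LTRs each insertion would give two
  bands and marker counts would double.
* The in-silico PCR has no thermodynamics and tolerates zero primer
  mismatches; real primer pairs would need empirical validation.
* The smallest-functional-derivative rule takes "functional" as given;
  it cannot itself detect a transmission drop.
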