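# bcenmap

A desk-scale, fully synthetic reconstruction of how a molecular map of
the maize B chromosome centromere is built and interpreted — for people
who work on centromere genomics and want the complete marker pipeline
(transposon display → deletion mapping → minimal map → CENH3 ChIP-seq →
core classification) as small, tested, seedable code.

## The problem

Centromeres are satellite- and retroelement-rich, so short reads cannot
be placed in them — unless one exploits the junctions that transposon
insertions create.  The maize B chromosome's centromere is a prime
example: absent from the reference assembly, but rich in CRM2
retroelement insertions whose LTR/flank junctions are effectively
unique.  The mapping strategy this package reconstructs is:

1. **CRM2 transposon display (TD).** Digest genomic DNA with BfaI
   (C^TAG), amplify between a CRM2-LTR primer and an adapter primer
   with 3 selective bases (all 64 lanes), and keep bands present with
   the B chromosome and absent without it.  Each marker is ~112 bp of
   CRM2 LTR plus flanking DNA out to the cut site.
2. **Deletion mapping.** Score each marker across centromere
   misdivision derivatives (TB-9Sb → PI → Telo2-1(−) → Iso3(−) →
   Telo2-2(−)).  Because misdivision removes nested terminal segments,
   loss patterns partition markers into ordered groups.
3. **Minimal map.** Concatenate the markers in that order with 200-N
   spacers into a pseudocontig that serves as an alignment reference.
4. **CENH3 ChIP-seq.** Map seven libraries (3 active-centromere ChIP
   replicates, 2 inactive-centromere replicates, CENH3 and
   fragmented-DNA controls from the B-less line) to genome + minimal
   map, unique hits only, and compute per-marker fold enrichment
   F(m) = cov_SPMR(m) / cov_SPMR(genome).
5. **Core call.** A marker interacts with CENH3 iff

   F(m) > t_active in *every* active replicate, F(m) ≤ 2 in every
   inactive replicate, zero unique control coverage, and reads span the
   marker's junction in every active replicate.

   Combining the calls with which derivatives still transmit normally
   gives the functional core domain: the marker suffix retained by the
   smallest fully functional derivative.

There are no downloads: a first-class synthetic-data module
(`bcenmap.repeatscape`) builds a CentC/B-repeat/CRM2 landscape with
planted junctions and band sizes, the misdivision pedigree, and ChIP
read sets, so every downstream stage is testable end to end.  The
published 40-marker presence/absence table ships as a packaged fixture
(`bcenmap.fixtures`).

## Worked example

The `analysis/` scripts run the five stages as a narrative; each is a
thin driver over `bcenmap.pipeline`:

```bash
python analysis/01_simulate_genomes.py   --seed 1
python analysis/02_transposon_display.py --seed 1
python analysis/03_deletion_map.py       --seed 1
python analysis/04_chip_enrichment.py    --seed 1
python analysis/05_core_classification.py --seed 1
```

Stage 2 and 3 print (seed 1):

```
B-specific markers after duplicate collapse: 61
markers surviving the miniB screen: 40 (21 lie outside the centromere-proximal region)
...
synthetic pedigree (seed 1):
  partition group sizes: [5, 1, 1, 2, 31] (violations: 0)
  minimal map: 40 markers, 10,100 bp of sequence, 17,900 bp with 200-N spacers
```

i.e. of 61 B-specific TD markers, 21 drop out on the centromere-only
miniB chromosome; the surviving 40 markers partition 5/1/1/2/31 across
the misdivision series, and the minimal map is 17,900 bp (10,100 bp of
marker sequence + 39 × 200 Ns).  Stage 5 closes the loop:

```
core markers called (7): TD7, TD9, TD10, TD15, TD18, TD21, TD29
planted CENH3 occupancy:    TD7, TD9, TD10, TD15, TD18, TD21, TD29
core-domain span (smallest functional derivative rule): TD8-TD40 (33 markers)
```

The classifier recovers exactly the seven markers whose CENH3 occupancy
was planted (at folds 36, 3, 18, 12, 23, 6, 31), and the
smallest-functional-derivative rule puts the core domain at TD8–TD40 —
33 markers, excluding TD7, which binds CENH3 but is dispensable because
a still-functional derivative lost it.  The junction-junction PCR pairs
designed for the seven core markers amplify nothing from the Telo3-3
analog (whose core is fully deleted) and give identical genotype
vectors for the Telo2-2 and Telo4-11 analogs.

`docs/methods.md` describes the models, parameters and design decisions
in detail.

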