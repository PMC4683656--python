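"""In-silico CRM2 transposon display.

Transposon display is an AFLP-derived assay: genomic DNA is digested with
a restriction enzyme (BfaI, C^TAG), adapters are ligated at the cut ends,
and fragments are amplified between a primer anchored in the CRM2 LTR and
an adapter primer carrying three selective bases.  A band therefore spans
the conserved LTR tag plus the flanking DNA out to the nearest cut site,
and its identity is the (selective triplet, size) pair on a lane of a gel.

This module reproduces that assay on synthetic genomes: digestion,
LTR-anchored amplification with selective-base matching, comparison of
B-carrying vs B-less banding profiles, duplicate collapse, and marker
naming in the ``CRM2-<triplets>-<size>`` convention (a marker's name lists
every selective triplet that amplified it, then its band size).

Conventions (fixed here, configurable via EnzymeSpec/PrimerSet):

* the selective primer must match its annealing segment exactly; weak
  selectivity of the adapter's three bases is modelled by a Hamming
  mismatch tolerance (0 = fully selective);
* the selective triplet of a band is the 3 genomic bases immediately 5'
  of the recognition site on the amplified strand (band[-4:-1]);
* band size = sequence length + a fixed adapter tail constant (default 0).
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

from .repeatscape import CUT_OFFSET, RECOGNITION, RepeatLibrary
from .sequtils import find_all, hamming, revcomp, seq_occurs

#: all 64 selective triplets, in the lexicographic lane-scan order used
#: for discovery ordering of marker names.
ALL_TRIPLETS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise ValueError("recognition must be non-empty over {A,C,G,T}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")


BFAI = EnzymeSpec("BfaI", RECOGNITION, CUT_OFFSET)


@dataclass
class PrimerSet:
    primary_ltr: str
    selective_ltr: str
    adapter_core: str = "GACGATGAGTCCTGAGTAG"
    selective_bases: str = ""

    def __post_init__(self):
        if len(self.selective_bases) not in (0, 3):
            raise ValueError("selective_bases must be empty or length 3")

    @classmethod
    def from_library(cls, lib: RepeatLibrary, selective_bases: str = "") -> "PrimerSet":
        """Primers targeting the library's 5' LTR annealing sites.

        The primers are the reverse complements of the annealing segments,
        so amplification runs from inside the LTR outward into flanking
        DNA; the selective primer sits nested inside the primary product.
        """
        return cls(
            primary_ltr=revcomp(lib.primary_annealing),
            selective_ltr=revcomp(lib.selective_annealing),
            selective_bases=selective_bases,
        )


@dataclass
class TDBand:
    size: int
    sequence: str  # LTR tag first, out to the cut site
    selective_triplets: list[str]  # lanes that amplified it, discovery order
    source_positions: tuple[str, int, int]  # (strand, plus_start, plus_end)
    true_triplet: str = ""

    def key(self) -> tuple[str, int]:
        return (self.sequence, self.size)


@dataclass
class TDMarker:
    id: str  # TD1..TDn
    name: str  # CRM2-<triplets>-<size>
    band: TDBand

    @property
    def sequence(self) -> str:
        return self.band.sequence

    @property
    def size(self) -> int:
        return self.band.size

    def __len__(self) -> int:
        return len(self.band.sequence)


def digest(sequence: str, enzyme: EnzymeSpec = BFAI) -> list[tuple[int, int]]:
    """Fragment intervals after cutting at every recognition site.

    Both strands are scanned; for a site on the minus strand the cut maps
    to ``start + len(recognition) - cut_offset`` on the plus strand.  With
    no site the whole sequence is a single fragment.
    """
    n = len(sequence)
    cuts = set()
    for h in find_all(enzyme.recognition, sequence):
        cuts.add(h + enzyme.cut_offset)
    rc_rec = revcomp(enzyme.recognition)
    if rc_rec != enzyme.recognition:
        for h in find_all(rc_rec, sequence):
            cuts.add(h + len(enzyme.recognition) - enzyme.cut_offset)
    borders = [0] + sorted(c for c in cuts if 0 < c < n) + [n]
    return list(zip(borders[:-1], borders[1:]))


def _scan_strand(seq: str, strand: str, enzyme: EnzymeSpec, primer: str,
                 max_band: int, adapter_constant: int, n_plus: int) -> list[TDBand]:
    """All potential bands on one strand (no selectivity applied)."""
    plen = len(primer)
    cuts = sorted(h + enzyme.cut_offset for h in find_all(enzyme.recognition, seq))
    out = []
    for i in find_all(primer, seq):
        # first cut downstream of the primer, leaving room for a triplet
        j = bisect.bisect_left(cuts, i + plen + 3 + enzyme.cut_offset)
        if j >= len(cuts):
            continue
        cut = cuts[j]
        band_seq = seq[i:cut]
        if len(band_seq) > max_band:
            continue
        rec_start = cut - enzyme.cut_offset
        triplet = seq[rec_start - 3 : rec_start]
        if strand == "+":
            src = ("+", i, cut)
        else:
            src = ("-", n_plus - cut, n_plus - i)
        out.append(
            TDBand(
                size=len(band_seq) + adapter_constant,
                sequence=band_seq,
                selective_triplets=[],
                source_positions=src,
                true_triplet=triplet,
            )
        )
    return out


def amplify(
    genome: str,
    enzyme: EnzymeSpec,
    primers: PrimerSet,
    mismatch_tolerance: int = 0,
    *,
    max_band: int = 1000,
    adapter_constant: int = 0,
) -> list[TDBand]:
    """Selective amplification: LTR primer out to the nearest cut site.

    Emits one band per outward-facing occurrence of the selective primer
    annealing site (either strand) whose selective triplet matches
    ``primers.selective_bases`` within the mismatch tolerance.  An empty
    ``selective_bases`` disables selectivity (preamplification).
    """
    if mismatch_tolerance < 0:
        raise ValueError("mismatch_tolerance must be >= 0")
    bands = all_potential_bands(genome, enzyme, primers, max_band=max_band,
                                adapter_constant=adapter_constant)
    sel = primers.selective_bases
    if not sel:
        return bands
    out = []
    for b in bands:
        if hamming(b.true_triplet, sel) <= mismatch_tolerance:
            b.selective_triplets.append(sel)
            out.append(b)
    return out


def all_potential_bands(
    genome: str,
    enzyme: EnzymeSpec = BFAI,
    primers: Optional[PrimerSet] = None,
    *,
    max_band: int = 1000,
    adapter_constant: int = 0,
) -> list[TDBand]:
    """Every LTR-anchored band regardless of selective bases."""
    if primers is None:
        raise ValueError("primers required")
    n = len(genome)
    fwd = _scan_strand(genome, "+", enzyme, primers.selective_ltr, max_band, adapter_constant, n)
    rev = _scan_strand(revcomp(genome), "-", enzyme, primers.selective_ltr, max_band, adapter_constant, n)
    return fwd + rev


@dataclass
class DisplayProfiles:
    """64 triplet lanes of band multisets per genotype."""

    lanes: dict[str, dict[str, list[TDBand]]]  # genotype -> triplet -> bands
    tolerance: int

    def lane_sizes(self, genotype: str, triplet: str) -> list[int]:
        return sorted(b.size for b in self.lanes[genotype][triplet])


def run_display(
    b_plus: str,
    b_minus: str,
    enzyme: EnzymeSpec = BFAI,
    primers: Optional[PrimerSet] = None,
    tolerance: int = 0,
    *,
    max_band: int = 1000,
    adapter_constant: int = 0,
) -> DisplayProfiles:
    """Run all 64 selective lanes on a B-carrying and a B-less genotype."""
    lanes: dict[str, dict[str, list[TDBand]]] = {}
    for genotype, genome in [("B+", b_plus), ("B-", b_minus)]:
        bands = all_potential_bands(genome, enzyme, primers, max_band=max_band,
                                    adapter_constant=adapter_constant)
        lanes[genotype] = {t: [] for t in ALL_TRIPLETS}
        for t in ALL_TRIPLETS:
            for b in bands:
                if hamming(b.true_triplet, t) <= tolerance:
                    b.selective_triplets.append(t)
                    lanes[genotype][t].append(b)
    return DisplayProfiles(lanes=lanes, tolerance=tolerance)


def call_b_specific(profiles: DisplayProfiles, size_bin_tolerance: int = 0) -> list[TDBand]:
    """Bands present in a B+ lane with no size-matched band in the B- lane.

    A band co-amplified in several lanes is B-specific if it is called in
    at least one of them; the returned bands are deduplicated by sequence,
    in lexicographic lane-scan order of first call.
    """
    called: list[TDBand] = []
    seen: set[tuple[str, int]] = set()
    for t in ALL_TRIPLETS:
        minus_sizes = {b.size for b in profiles.lanes["B-"][t]}
        for band in profiles.lanes["B+"][t]:
            matched = any(
                abs(band.size - ms) <= size_bin_tolerance for ms in minus_sizes
            )
            if not matched and band.key() not in seen:
                seen.add(band.key())
                called.append(band)
    return called


def collapse_and_name(bands: Sequence[TDBand], prefix: str = "CRM2") -> list[TDMarker]:
    """Merge identical-sequence bands into named markers.

    Duplicates (the same fragment amplified in several lanes) collapse to
    one marker whose name lists every selective triplet in discovery
    order, then the band size; ids are assigned TD1..TDn in input order.
    Collapsing already-collapsed bands is a fixed point.
    """
    if not bands:
        raise ValueError("no bands to collapse")
    by_seq: dict[str, TDBand] = {}
    order: list[str] = []
    for b in bands:
        if b.sequence not in by_seq:
            rep = TDBand(
                size=b.size,
                sequence=b.sequence,
                selective_triplets=[],
                source_positions=b.source_positions,
                true_triplet=b.true_triplet,
            )
            by_seq[b.sequence] = rep
            order.append(b.sequence)
        rep = by_seq[b.sequence]
        for t in b.selective_triplets or [b.true_triplet]:
            if t not in rep.selective_triplets:
                rep.selective_triplets.append(t)
    markers = []
    for i, seq in enumerate(order):
        band = by_seq[seq]
        name = f"{prefix}-" + "-".join(band.selective_triplets) + f"-{band.size}"
        markers.append(TDMarker(id=f"TD{i + 1}", name=name, band=band))
    return markers


def parse_marker_name(name: str) -> tuple[list[str], int]:
    """Recover (selective triplets, size) from a marker name."""
    parts = name.split("-")
    if len(parts) < 3:
        raise ValueError(f"unparseable marker name {name!r}")
    size = int(parts[-1])
    triplets = parts[1:-1]
    if any(len(t) != 3 or set(t) - set("ACGT") for t in triplets):
        raise ValueError(f"unparseable marker name {name!r}")
    return triplets, size


def filter_by_genome(markers: Sequence[TDMarker], retained_genome: str) -> list[TDMarker]:
    """Markers whose full band sequence occurs in the retained genome.

    This is the miniB screen: a marker flanking an insertion outside the
    centromere-proximal region is absent from a centromere-only
    chromosome and is dropped from the map.
    """
    return [m for m in markers if seq_occurs(m.band.sequence, retained_genome)]
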