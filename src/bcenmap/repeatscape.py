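"""Synthetic repeat landscape: a B-like centromere and its misdivision series.

This module fabricates everything the downstream stages need so the whole
pipeline is testable without any external data:

* a repeat library (a 156-bp CentC-like satellite monomer, a CRM2-like LTR
  retroelement whose 5' LTR carries the transposon-display primer annealing
  sites, a B-repeat-like unit, and filler retroelements);
* a centromere built as a CentC tandem backbone interspersed with B-repeat
  blocks, into which CRM2-like elements are inserted at random positions
  (possibly nested inside earlier insertions).  Every insertion creates two
  junctions; on the outward side of its 5' LTR a restriction site is
  planted at a chosen distance so that transposon display recovers exactly
  one band of a prescribed size per insertion;
* nested deletion derivatives modelling centromere misdivision (one
  terminal-side excision per event);
* ChIP-seq-like read sets with per-interval fold enrichment.

Every repeat copy placed in a genome is an independently mutated copy of
its library consensus (satellite monomers ~5 %, element bodies ~2 %), so
junction-proximal sequence is effectively unique at read scale while
copies of a family still share most of their sequence -- the property that
makes junction markers informative in real centromeres.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequtils import (
    COMP_LUT,
    child_rng,
    encode,
    find_all,
    mutate,
    random_dna,
    revcomp,
)

#: bp of LTR carried at the start of every transposon-display band.
LTR_TAG_LEN = 112
#: annealing site of the selective LTR primer within the 5' LTR.
SELECTIVE_SITE = (92, 112)
#: annealing site of the primary LTR primer within the 5' LTR (nested
#: outside the selective product).
PRIMARY_SITE = (130, 150)
#: restriction recognition sequence planted at band ends (BfaI, C^TAG).
RECOGNITION = "CTAG"
CUT_OFFSET = 1

CENTC_LEN = 156  # the canonical CentC monomer length


class LayoutError(ValueError):
    """Raised when a requested layout cannot be hosted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RepeatLibrary:
    """Named consensus sequences used to compose genomes."""

    units: dict[str, str]
    ltr_5p: str
    ltr_3p: str
    centc_monomer: str
    b_repeat: str
    fillers: dict[str, str]

    @property
    def crm2_internal(self) -> str:
        return self.units["crm2_internal"]

    def crm2_element(self) -> str:
        return self.ltr_5p + self.crm2_internal + self.ltr_3p

    @property
    def selective_annealing(self) -> str:
        return self.ltr_5p[SELECTIVE_SITE[0] : SELECTIVE_SITE[1]]

    @property
    def primary_annealing(self) -> str:
        return self.ltr_5p[PRIMARY_SITE[0] : PRIMARY_SITE[1]]


@dataclass
class Feature:
    start: int
    end: int
    unit: str
    depth: int


@dataclass
class Insertion:
    """Bookkeeping for one planted CRM2-like insertion."""

    index: int
    orientation: str  # '+' or '-'
    start: int  # element span in current coordinates
    end: int
    band_start: int  # plus-strand span of the TD band this insertion yields
    band_end: int
    band_size: int

    @property
    def band_span(self) -> tuple[int, int]:
        return (self.band_start, self.band_end)


@dataclass
class CentromereLayout:
    sequence: str
    features: list[Feature]
    cenh3_domain: tuple[int, int]
    planted_junctions: list[int]
    insertions: list[Insertion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def check_tiling(self) -> None:
        pos = 0
        for f in self.features:
            if f.start != pos:
                raise AssertionError(f"feature gap at {pos} vs {f.start}")
            pos = f.end
        if pos != len(self.sequence):
            raise AssertionError("features do not tile the sequence")


@dataclass
class DerivativeGenome:
    """A misdivision derivative: its parent minus one terminal excision."""

    name: str
    parent: Optional[str]
    deletions: list[tuple[int, int]]  # in the parent's coordinates
    sequence: str
    root_interval: tuple[int, int] = (0, 0)  # retained slice of the root


@dataclass
class ReadSet:
    library_name: str
    role: str  # active_chip | inactive_chip | negative_chip | fragmented_control
    sequences: np.ndarray  # (n_reads, read_length) uint8 ASCII
    read_length: int
    seed: int
    source_starts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    source_strands: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))

    @property
    def n_reads(self) -> int:
        return int(self.sequences.shape[0])

    @property
    def reads(self) -> list[tuple[str, str]]:
        qual = "I" * self.read_length
        return [(row.tobytes().decode(), qual) for row in self.sequences]

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i, row in enumerate(self.sequences):
                fh.write(f"@{self.library_name}.{i}\n{row.tobytes().decode()}\n+\n{qual}\n")


VALID_ROLES = {"active_chip", "inactive_chip", "negative_chip", "fragmented_control"}


# ---------------------------------------------------------------------------
# repeat library
# ---------------------------------------------------------------------------


def _strip_recognition(seq: str, protect=()) -> str:
    """Remove every occurrence of the recognition site by point changes,
    never touching a base inside a protected interval."""
    protected = list(protect)
    while True:
        hits = find_all(RECOGNITION, seq)
        if not hits:
            return seq
        h = hits[0]
        for off in (1, 2, 0, 3):
            p = h + off
            if not any(s <= p < e for s, e in protected):
                repl = "G" if seq[p] != "G" else "C"
                seq = seq[: p] + repl + seq[p + 1 :]
                break
        else:  # pragma: no cover - protected islands are themselves site-free
            raise LayoutError("recognition site pinned inside a protected region")


def build_repeat_library(
    seed: int,
    *,
    ltr_len: int = 160,
    internal_len: int = 280,
    b_repeat_len: int = 1100,
    filler_lens: Sequence[int] = (900, 700),
    max_shared_k: int = 40,
) -> RepeatLibrary:
    """Generate the named repeat consensus sequences.

    The 5' LTR is built CTAG-free (so a band's first cut site is always the
    planted one) and carries the two primer annealing subsequences at fixed
    offsets; the 3' LTR is an unrelated variant without them, so each
    insertion yields exactly one display band.
    """
    if ltr_len < PRIMARY_SITE[1]:
        raise ValueError(
            f"ltr_len must be >= {PRIMARY_SITE[1]} to host the primer annealing sites"
        )
    for name, n in [("internal", internal_len), ("b_repeat", b_repeat_len)] + [
        (f"filler{i}", n) for i, n in enumerate(filler_lens)
    ]:
        if n <= 0:
            raise ValueError(f"unit length {name} must be positive")

    rng = child_rng(seed, "repeat_library")
    ltr_5p = _strip_recognition(random_dna(rng, ltr_len))
    ltr_3p = random_dna(rng, ltr_len)
    centc = random_dna(rng, CENTC_LEN)
    b_rep = random_dna(rng, b_repeat_len)
    internal = random_dna(rng, internal_len)
    fillers = {f"retro_{chr(ord('a') + i)}": random_dna(rng, n) for i, n in enumerate(filler_lens)}

    units = {
        "ltr_5p": ltr_5p,
        "ltr_3p": ltr_3p,
        "centc": centc,
        "b_repeat": b_rep,
        "crm2_internal": internal,
        **fillers,
    }
    lib = RepeatLibrary(
        units=units,
        ltr_5p=ltr_5p,
        ltr_3p=ltr_3p,
        centc_monomer=centc,
        b_repeat=b_rep,
        fillers=fillers,
    )
    _check_kmer_sharing(lib, max_shared_k)
    return lib


def _check_kmer_sharing(lib: RepeatLibrary, k: int) -> None:
    """Distinct units must share no exact k-mer (junction resolvability)."""
    names = list(lib.units)
    kmer_sets = {}
    for n in names:
        s = lib.units[n]
        both = s + "#" + revcomp(s)
        kmer_sets[n] = {both[i : i + k] for i in range(len(both) - k + 1) if "#" not in both[i : i + k]}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if kmer_sets[a] & kmer_sets[b]:
                raise LayoutError(f"units {a} and {b} share a {k}-mer")


# ---------------------------------------------------------------------------
# assembly engine
# ---------------------------------------------------------------------------


class Assembly:
    """A growing sequence with tiling features and planted insertions.

    Insertion points are sampled outside *reserved* intervals (LTRs, band
    windows and planted cut sites of earlier insertions, plus edge
    margins), so nested insertions land in element bodies or backbone and
    never disrupt an existing band.
    """

    def __init__(self, sequence: str, features: list[Feature], rng: np.random.Generator):
        self.seq = sequence
        self.features = features
        self.rng = rng
        self.insertions: list[Insertion] = []
        self.reserved: list[tuple[int, int]] = []
        self.junctions: list[int] = [
            f.end for a, f in zip(features[1:], features[:-1]) if a.unit != f.unit
        ]

    # -- coordinate shifting -------------------------------------------------

    def _shift(self, p: int, m: int) -> None:
        for f in self.features:
            if f.start >= p:
                f.start += m
            if f.end > p:
                f.end += m
        self.junctions = [j + m if j >= p else j for j in self.junctions]
        self.reserved = [
            (s + m if s >= p else s, e + m if e > p else e) for s, e in self.reserved
        ]
        for ins in self.insertions:
            if ins.start >= p:
                ins.start += m
                ins.end += m
            if ins.band_start >= p:
                ins.band_start += m
                ins.band_end += m

    def _split_feature(self, p: int) -> int:
        """Split the feature containing p; return its nesting depth."""
        for i, f in enumerate(self.features):
            if f.start < p < f.end:
                self.features[i : i + 1] = [
                    Feature(f.start, p, f.unit, f.depth),
                    Feature(p, p, f.unit, f.depth),  # placeholder, fixed below
                ]
                return f.depth
            if f.start == p or f.end == p:
                return f.depth if f.start <= p < f.end else f.depth
        raise LayoutError(f"position {p} outside assembly")

    # -- sampling ------------------------------------------------------------

    def _allowed_intervals(self, lo: int, hi: int, left_need: int, right_need: int):
        """Free intervals within [lo, hi) whose points keep the new band
        window (left_need bp to the left / right_need to the right) clear of
        reserved zones."""
        blocks = sorted((max(lo, s - right_need), min(hi, e + left_need)) for s, e in self.reserved)
        out = []
        pos = lo
        for s, e in blocks:
            if s > pos:
                out.append((pos, min(s, hi)))
            pos = max(pos, e)
            if pos >= hi:
                break
        if pos < hi:
            out.append((pos, hi))
        return [(s, e) for s, e in out if e > s]

    def sample_point(self, left_need: int, right_need: int, margin: int) -> int:
        lo = margin + left_need
        hi = len(self.seq) - margin - right_need
        if hi <= lo:
            raise LayoutError("assembly too small for requested insertion")
        ivs = self._allowed_intervals(lo, hi, left_need, right_need)
        if not ivs:
            raise LayoutError("no free space left for insertion")
        lens = np.array([e - s for s, e in ivs], dtype=float)
        i = int(self.rng.choice(len(ivs), p=lens / lens.sum()))
        s, e = ivs[i]
        return int(self.rng.integers(s, e))

    # -- planting ------------------------------------------------------------

    def _sanitize_window(self, w0: int, w1: int, planted: tuple[int, int],
                         no_touch: list[tuple[int, int]]) -> None:
        """Remove stray recognition sites overlapping [w0, w1).

        The planted site is left alone; sites straddling a no-touch zone
        (an LTR) are destroyed by mutating one of their bases outside it.
        """
        while True:
            lo = max(0, w0 - 3)
            region = self.seq[lo : w1 + 3]
            hits = [
                h + lo
                for h in find_all(RECOGNITION, region)
                if not (h + lo < planted[1] and planted[0] < h + lo + 4)
            ]
            if not hits:
                return
            h = hits[0]
            for off in (1, 2, 0, 3):
                p = h + off
                if not any(s <= p < e for s, e in no_touch):
                    old = self.seq[p]
                    repl = "G" if old != "G" else "C"
                    self.seq = self.seq[:p] + repl + self.seq[p + 1 :]
                    break
            else:  # pragma: no cover - an LTR never covers a stray site fully
                raise LayoutError("cannot sanitize recognition site")

    def insert_element(self, lib: RepeatLibrary, band_size: int, ltr_div: float,
                       body_div: float, res_pad: int = 15) -> Insertion:
        """Insert one mutated CRM2-like copy and plant its band cut site."""
        if band_size <= LTR_TAG_LEN + len(RECOGNITION):
            raise LayoutError(f"band size {band_size} too small for the LTR tag")
        rng = self.rng
        orientation = "+" if rng.random() < 0.5 else "-"
        ltr5 = mutate(lib.ltr_5p, ltr_div, rng, protect=[SELECTIVE_SITE, PRIMARY_SITE])
        ltr5 = _strip_recognition(ltr5, protect=[SELECTIVE_SITE, PRIMARY_SITE])
        internal = mutate(lib.crm2_internal, body_div, rng)
        ltr3 = mutate(lib.ltr_3p, body_div, rng)
        elem = ltr5 + internal + ltr3
        elen = len(elem)
        flank = band_size - LTR_TAG_LEN  # bp of flank in the band
        pad = 25

        if orientation == "+":
            left_need, right_need = flank + len(RECOGNITION) + pad, pad
        else:
            left_need, right_need = pad, flank + len(RECOGNITION) + pad

        p = self.sample_point(left_need, right_need, margin=max(pad, 50))
        depth = self._split_or_probe_depth(p)

        ins_seq = elem if orientation == "+" else revcomp(elem)
        self._splice(p, ins_seq, depth, orientation)

        # locate band window and plant the cut site
        if orientation == "+":
            # amplification runs on the minus strand into the upstream flank
            band_start = p + LTR_TAG_LEN - band_size
            band_end = p + LTR_TAG_LEN
            rec_at = band_start - 3
        else:
            b = p + elen
            band_start = b - LTR_TAG_LEN
            band_end = b - LTR_TAG_LEN + band_size
            rec_at = band_end - 1

        ltr5_span = (p, p + len(ltr5)) if orientation == "+" else (p + elen - len(ltr5), p + elen)
        planted = (rec_at, rec_at + 4)
        self.seq = self.seq[:rec_at] + RECOGNITION + self.seq[rec_at + 4 :]
        self._sanitize_window(
            min(band_start, rec_at), max(band_end, rec_at + 4), planted,
            no_touch=[ltr5_span, planted],
        )

        ins = Insertion(
            index=len(self.insertions),
            orientation=orientation,
            start=p,
            end=p + elen,
            band_start=band_start,
            band_end=band_end,
            band_size=band_size,
        )
        self.insertions.append(ins)
        self.junctions.extend([p, p + elen])
        self.reserved.append((min(band_start, rec_at) - res_pad, max(band_end, rec_at + 4) + res_pad))
        self.reserved.append((p, p + len(ltr5)) if orientation == "+" else (p + elen - len(ltr5), p + elen))
        self.reserved.append((p + elen - len(ltr3), p + elen) if orientation == "+" else (p, p + len(ltr3)))
        return ins

    def _split_or_probe_depth(self, p: int) -> int:
        for f in self.features:
            if f.start <= p < f.end or (f.start == p == f.end):
                return f.depth
        if p == len(self.seq):
            return 0
        raise LayoutError(f"position {p} outside assembly")

    def _splice(self, p: int, ins_seq: str, host_depth: int, orientation: str) -> None:
        m = len(ins_seq)
        # split the host feature at the insertion point
        new_feats: list[Feature] = []
        for f in self.features:
            if f.start < p < f.end:
                new_feats.append(Feature(f.start, p, f.unit, f.depth))
                new_feats.append(Feature(p, f.end, f.unit, f.depth))
            else:
                new_feats.append(f)
        self.features = new_feats
        self.seq = self.seq[:p] + ins_seq + self.seq[p:]
        self._shift(p, m)
        self._add_element_features(p, m, host_depth + 1, orientation)

    def _add_element_features(self, p: int, m: int, depth: int, orientation: str) -> None:
        ltr_len = _LTR_LEN_CACHE[0]
        if orientation == "+":
            spans = [
                (p, p + ltr_len, "ltr_5p"),
                (p + ltr_len, p + m - ltr_len, "crm2_internal"),
                (p + m - ltr_len, p + m, "ltr_3p"),
            ]
        else:
            spans = [
                (p, p + ltr_len, "ltr_3p"),
                (p + ltr_len, p + m - ltr_len, "crm2_internal"),
                (p + m - ltr_len, p + m, "ltr_5p"),
            ]
        elem_feats = [Feature(s, e, u, depth) for s, e, u in spans]
        out = []
        placed = False
        for f in self.features:
            if not placed and f.start >= p + m:
                out.extend(elem_feats)
                placed = True
            if f.start == f.end:
                continue
            out.append(f)
        if not placed:
            out.extend(elem_feats)
        out.sort(key=lambda f: (f.start, f.end))
        self.features = out


# module-level cache of the LTR length used when adding element features;
# set by simulate_centromere / pipeline assemblers from the library in use.
_LTR_LEN_CACHE = [160]


# ---------------------------------------------------------------------------
# centromere simulation
# ---------------------------------------------------------------------------


def _backbone(lib: RepeatLibrary, rng: np.random.Generator, target_bp: int, n_b_blocks: int,
              centc_div: float, b_div: float) -> tuple[str, list[Feature]]:
    """CentC tandem arrays interspersed with B-repeat blocks."""
    n_arrays = n_b_blocks + 1
    b_total = n_b_blocks * len(lib.b_repeat)
    centc_total = max(target_bp - b_total, n_arrays * CENTC_LEN)
    monomers_per_array = max(2, int(round(centc_total / (n_arrays * CENTC_LEN))))
    parts: list[str] = []
    feats: list[Feature] = []
    pos = 0

    def add(unit: str, seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        feats.append(Feature(pos, pos + len(seq), unit, 0))
        pos += len(seq)

    for i in range(n_arrays):
        for _ in range(monomers_per_array):
            add("centc", mutate(lib.centc_monomer, centc_div, rng))
        if i < n_b_blocks:
            add("b_repeat", mutate(lib.b_repeat, b_div, rng))
    return "".join(parts), feats


def simulate_centromere(
    lib: RepeatLibrary,
    n_crm_insertions: int,
    seed: int,
    *,
    backbone_bp: int = 30_000,
    n_b_blocks: int = 5,
    band_sizes: Optional[Sequence[int]] = None,
    centc_divergence: float = 0.08,
    body_divergence: float = 0.08,
    ltr_divergence: float = 0.08,
    cenh3_fraction: float = 0.5,
    min_band_gap: int = 260,
) -> CentromereLayout:
    """Build a B-like centromere with `n_crm_insertions` planted elements.

    Each insertion carries a copy-specific mutated element, creates two
    junctions, and has a restriction site planted on the outward side of
    its 5' LTR so that transposon display yields one band of the requested
    size.  `band_sizes` defaults to sizes drawn uniformly from 131-405 bp.
    """
    if n_crm_insertions < 0:
        raise ValueError("n_crm_insertions must be >= 0")
    rng = child_rng(seed, "centromere")
    _LTR_LEN_CACHE[0] = len(lib.ltr_5p)
    seq, feats = _backbone(lib, rng, backbone_bp, n_b_blocks, centc_divergence, body_divergence)
    asm = Assembly(seq, feats, rng)
    if band_sizes is None:
        band_sizes = [int(rng.integers(131, 406)) for _ in range(n_crm_insertions)]
    if len(band_sizes) != n_crm_insertions:
        raise ValueError("band_sizes length must equal n_crm_insertions")
    res_pad = max(15, min_band_gap - 25)
    for size in band_sizes:
        asm.insert_element(lib, size, ltr_div=ltr_divergence, body_div=body_divergence,
                           res_pad=res_pad)
    n = len(asm.seq)
    half = int(n * cenh3_fraction / 2)
    layout = CentromereLayout(
        sequence=asm.seq,
        features=asm.features,
        cenh3_domain=(n // 2 - half, n // 2 + half),
        planted_junctions=sorted(asm.junctions),
        insertions=sorted(asm.insertions, key=lambda i: i.band_start),
    )
    layout.check_tiling()
    _verify_planted_bands(lib, layout)
    return layout


def _verify_planted_bands(lib: RepeatLibrary, layout: CentromereLayout) -> None:
    """Every planted insertion must yield exactly its prescribed band."""
    primer = revcomp(lib.selective_annealing)
    for ins in layout.insertions:
        band = band_sequence(layout.sequence, ins)
        if len(band) != ins.band_size:
            raise LayoutError(
                f"insertion {ins.index}: band length {len(band)} != planted {ins.band_size}"
            )
        if not band.startswith(primer):
            raise LayoutError(f"insertion {ins.index}: band does not start at the primer site")
        # the planted recognition site must be the first one downstream of
        # the primer on the amplification strand
        if ins.orientation == "+":
            ext = band + revcomp(layout.sequence[ins.band_start - 3 : ins.band_start])
        else:
            ext = band + layout.sequence[ins.band_end : ins.band_end + 3]
        if ext[ins.band_size - 1 : ins.band_size + 3] != RECOGNITION:
            raise LayoutError(f"insertion {ins.index}: planted cut site missing")
        if RECOGNITION in ext[len(primer) : ins.band_size - 1]:
            raise LayoutError(f"insertion {ins.index}: stray cut site inside the band")


def band_sequence(genome: str, ins: Insertion) -> str:
    """The amplified band of an insertion, LTR tag first."""
    s = genome[ins.band_start : ins.band_end]
    return revcomp(s) if ins.orientation == "+" else s


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


@dataclass
class PedigreeNode:
    name: str
    parent: Optional[str]
    fraction: float  # of the parent's length, removed from `side`
    side: str = "left"
    cut_at: Optional[int] = None  # absolute cut in parent coords (overrides fraction)


def derive_pedigree(root, spec: Sequence, seed: int = 0) -> list[DerivativeGenome]:
    """Derive nested misdivision genomes from a root.

    `root` needs `.sequence` and `.cenh3_domain`.  `spec` entries are
    PedigreeNode or (name, parent, fraction[, side]) tuples; fraction is
    the portion of the parent removed from the given terminal side.  A
    fraction of exactly 1.0 means "remove through the far edge of the
    CENH3 core" (the Telo3-3 case: the whole functional domain is lost).
    Fraction 0 copies the parent unchanged (the Telo4-11 case).
    """
    del seed  # excision endpoints are fully specified; kept for API symmetry
    nodes: list[PedigreeNode] = []
    for entry in spec:
        if isinstance(entry, PedigreeNode):
            nodes.append(entry)
        else:
            name, parent, fraction = entry[:3]
            side = entry[3] if len(entry) > 3 else "left"
            nodes.append(PedigreeNode(name, parent, fraction, side))

    root_len = len(root.sequence)
    out: dict[str, DerivativeGenome] = {}
    root_name = None
    for node in nodes:
        if node.parent is None:
            root_name = node.name
            out[node.name] = DerivativeGenome(
                name=node.name, parent=None, deletions=[], sequence=root.sequence,
                root_interval=(0, root_len),
            )
    if root_name is None:
        raise ValueError("pedigree spec must contain exactly one root")

    remaining = [n for n in nodes if n.parent is not None]
    guard = 0
    while remaining:
        guard += 1
        if guard > len(nodes) ** 2 + 10:
            raise ValueError("pedigree spec is not a tree rooted at the progenitor")
        nxt = []
        for node in remaining:
            if node.parent not in out:
                nxt.append(node)
                continue
            parent = out[node.parent]
            plen = len(parent.sequence)
            r0, r1 = parent.root_interval
            if node.cut_at is not None:
                cut = node.cut_at
            elif node.fraction == 1.0:
                core_end = root.cenh3_domain[1] if node.side == "left" else root.cenh3_domain[0]
                cut = core_end - r0 if node.side == "left" else r1 - core_end
                if cut <= 0 or cut > plen:
                    raise ValueError(f"{node.name}: core excision outside parent bounds")
            else:
                if not 0 <= node.fraction < 1:
                    raise ValueError(f"{node.name}: fraction must be in [0, 1]")
                cut = int(round(node.fraction * plen))
            if cut < 0 or cut > plen:
                raise ValueError(f"{node.name}: deletion outside parent bounds")
            if node.side == "left":
                deletions = [(0, cut)] if cut else []
                sequence = parent.sequence[cut:]
                interval = (r0 + cut, r1)
            elif node.side == "right":
                deletions = [(plen - cut, plen)] if cut else []
                sequence = parent.sequence[: plen - cut]
                interval = (r0, r1 - cut)
            else:
                raise ValueError(f"{node.name}: side must be 'left' or 'right'")
            out[node.name] = DerivativeGenome(
                name=node.name, parent=node.parent, deletions=deletions,
                sequence=sequence, root_interval=interval,
            )
        if len(nxt) == len(remaining):
            raise ValueError("pedigree spec is not a tree rooted at the progenitor")
        remaining = nxt
    return [out[n.name] for n in nodes]


# ---------------------------------------------------------------------------
# ChIP-seq-like read simulation
# ---------------------------------------------------------------------------


def simulate_chip_reads(
    genome,
    layout: Optional[CentromereLayout],
    role: str,
    fold: dict[tuple[int, int], float] | None,
    n_reads: int,
    read_length: int = 150,
    seed: int = 0,
    *,
    library_name: Optional[str] = None,
    substitution_rate: float = 0.0,
    cenh3_domain: Optional[tuple[int, int]] = None,
) -> ReadSet:
    """Draw single-end reads with start density 1 outside and `fold` inside
    the enriched intervals.

    For ``fragmented_control`` the density is uniform regardless of the
    fold map; for ``inactive_chip`` the CENH3 domain is forced back to
    fold 1 (the centromere is present but epigenetically inactive).  Reads
    come off both strands with probability 0.5.
    """
    if role not in VALID_ROLES:
        raise ValueError(f"invalid role {role!r}")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    n = len(seq)
    if n < read_length:
        raise ValueError("genome shorter than read length")
    fold = dict(fold or {})
    for (s, e), f in fold.items():
        if f < 0:
            raise ValueError("fold values must be >= 0")
        if not (0 <= s < e <= n):
            raise ValueError(f"fold interval ({s}, {e}) outside genome")

    rng = child_rng(seed, f"chip:{library_name or role}")
    n_starts = n - read_length + 1
    weights = np.ones(n_starts, dtype=float)
    if role != "fragmented_control":
        for (s, e), f in fold.items():
            weights[max(0, s) : min(n_starts, e)] = f
    if role == "inactive_chip":
        dom = cenh3_domain or (layout.cenh3_domain if layout is not None else None)
        if dom is not None:
            weights[max(0, dom[0]) : min(n_starts, dom[1])] = 1.0

    cdf = np.cumsum(weights)
    starts = np.searchsorted(cdf, rng.random(n_reads) * cdf[-1], side="right")
    strands = (rng.random(n_reads) < 0.5).astype(np.int8)  # 1 = reverse

    arr = encode(seq)
    idx = starts[:, None] + np.arange(read_length)[None, :]
    reads = arr[idx]
    rev = strands == 1
    if rev.any():
        reads[rev] = COMP_LUT[reads[rev][:, ::-1]]
    if substitution_rate > 0:
        hit = rng.random(reads.shape) < substitution_rate
        if hit.any():
            codes = np.zeros(256, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                codes[b] = i
            shift = rng.integers(1, 4, size=int(hit.sum()))
            newc = (codes[reads[hit]] + shift) % 4
            reads[hit] = np.frombuffer(b"ACGT", dtype=np.uint8)[newc]

    return ReadSet(
        library_name=library_name or role,
        role=role,
        sequences=reads,
        read_length=read_length,
        seed=seed,
        source_starts=starts.astype(np.int64),
        source_strands=strands,
    )


def concat_readsets(name: str, parts: Sequence[ReadSet]) -> ReadSet:
    """Pool several read sets (e.g. background + B-chromosome draws)."""
    if not parts:
        raise ValueError("no read sets to concatenate")
    L = parts[0].read_length
    if any(p.read_length != L for p in parts):
        raise ValueError("read lengths differ")
    return ReadSet(
        library_name=name,
        role=parts[0].role,
        sequences=np.concatenate([p.sequences for p in parts]),
        read_length=L,
        seed=parts[0].seed,
        source_starts=np.concatenate([p.source_starts for p in parts]),
        source_strands=np.concatenate([p.source_strands for p in parts]),
    )


def coverage_from_starts(starts: np.ndarray, read_length: int, n: int) -> np.ndarray:
    """Per-base coverage implied by true read start positions."""
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, np.minimum(starts + read_length, n), -1)
    return np.cumsum(diff[:-1])
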