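"""Desk-scale unique read mapping and CENH3 fold-enrichment scoring.

The mapping reference is the background genome plus the minimal-map
pseudocontig -- the B centromere itself is represented only by its marker
sequences, so a read maps to the minimal map exactly when it carries
marker sequence.  The mapper is a k-mer seed (k = 40) and ungapped-extend
aligner that keeps a read only when it has a single best placement whose
score clears the second best by a margin (the in-repo analog of a MAPQ
floor: "only unique hits") and whose identity over the aligned, non-N
reference positions is near-perfect (the analog of mismatch penalties --
without it, reads from diverged repeat copies whose true locus is not in
the reference would be retained at ~90 % identity).

Enrichment is the SPMR-style quantity the study interprets: per-library
coverage scaled to per-million-mapped-reads, averaged over each marker
interval, divided by the scaled genome-wide average of the background
reference.  Spacer Ns never seed, never count as aligned length, and
never accumulate coverage of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .repeatscape import ReadSet
from .sequtils import COMP_LUT, encode

N_BYTE = ord("N")


@dataclass
class ReferenceIndex:
    names: list[str]
    offsets: np.ndarray  # global start of each reference
    lengths: np.ndarray
    array: np.ndarray  # concatenated uint8 ASCII, N-separated, N-padded
    k: int
    seeds: dict[bytes, np.ndarray]  # k-mer -> global start positions

    def ref_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    @property
    def total_real_length(self) -> int:
        return int(self.lengths.sum())


def build_index(references: dict[str, str], k: int = 40, *, separator: int = 256) -> ReferenceIndex:
    """Index every N-free k-mer of the references with all its placements.

    References are concatenated with runs of Ns longer than any read so a
    window never aligns across two references; the array is N-padded at
    both ends so extension needs no bounds checks.
    """
    if not references:
        raise ValueError("references must be non-empty")
    names = list(references)
    if k < 1:
        raise ValueError("k must be >= 1")
    shortest = min(len(s) for s in references.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest reference ({shortest} bp)")

    sep = "N" * separator
    cat = sep + sep.join(references[n] for n in names) + sep
    offsets = []
    pos = separator
    for n in names:
        offsets.append(pos)
        pos += len(references[n]) + separator
    arr = encode(cat)

    seeds: dict[bytes, list[int]] = {}
    raw = cat.encode()
    for off, name in zip(offsets, names):
        seq = references[name]
        # positions of Ns inside this reference (spacers in the pseudocontig)
        n_pos = np.frombuffer(seq.encode(), dtype=np.uint8) == N_BYTE
        bad = np.convolve(n_pos.astype(int), np.ones(k, dtype=int), mode="valid") > 0
        for i in range(len(seq) - k + 1):
            if bad[i]:
                continue
            key = raw[off + i : off + i + k]
            seeds.setdefault(key, []).append(off + i)
    packed = {key: np.asarray(v, dtype=np.int64) for key, v in seeds.items()}
    return ReferenceIndex(
        names=names,
        offsets=np.asarray(offsets, dtype=np.int64),
        lengths=np.asarray([len(references[n]) for n in names], dtype=np.int64),
        array=arr,
        k=k,
        seeds=packed,
    )


@dataclass
class Placement:
    read_id: int
    ref: str
    start: int  # local, may be negative if the alignment hangs off the ref
    strand: str
    score: int  # matching bases of the chosen placement
    margin: int  # penalized-score margin over the runner-up (the score
    # itself when no rival placement was found)

    def aligned_interval(self, read_length: int, ref_length: int) -> tuple[int, int]:
        return (max(0, self.start), min(ref_length, self.start + read_length))


@dataclass
class MappingResult:
    placements: list[Placement]
    n_reads: int
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_low_identity: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.placements)


def map_reads(
    reads: ReadSet,
    index: ReferenceIndex,
    min_margin: int = 5,
    *,
    min_identity: float = 0.95,
    n_seeds: int = 3,
) -> MappingResult:
    """Seed-and-extend mapping retaining uniquely placed reads only.

    Each read is seeded at up to `n_seeds` offsets on both strands; every
    candidate placement is scored by ungapped extension with mismatch
    penalties (match +1, mismatch -4; N positions are clipped, so a
    partially overlapping read competes with its exact overlap only).  A
    read is retained iff a single best placement exists, its penalized
    score clears the runner-up by at least `min_margin`, and its identity
    (matches over aligned non-N reference positions) is at least
    `min_identity`.  Everything else is discarded and tallied.
    """
    L = reads.read_length
    k = index.k
    if L < k:
        raise ValueError(f"read length {L} shorter than seed length {k}")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    offsets = sorted({int(round(x)) for x in np.linspace(0, L - k, n_seeds)})

    arr = index.array
    fwd_all = reads.sequences
    rev_all = COMP_LUT[fwd_all[:, ::-1]]
    seeds = index.seeds

    placements: list[Placement] = []
    n_unmapped = n_ambiguous = n_low_identity = 0

    for rid in range(fwd_all.shape[0]):
        cands: set[tuple[int, int]] = set()
        for strand_i, row in enumerate((fwd_all[rid], rev_all[rid])):
            raw = row.tobytes()
            for off in offsets:
                hits = seeds.get(raw[off : off + k])
                if hits is not None:
                    for h in hits:
                        cands.add((int(h) - off, strand_i))
        if not cands:
            n_unmapped += 1
            continue

        # selection score is mismatch-penalized (match +1, mismatch -4,
        # N positions clipped), so a clipped exact placement beats a
        # full-length alignment to a diverged repeat copy
        NO_SCORE = -10 * L
        best = second = NO_SCORE
        best_cand = None
        best_matches = best_nonn = 1
        tie = False
        for g, strand_i in cands:
            window = arr[g : g + L]
            row = fwd_all[rid] if strand_i == 0 else rev_all[rid]
            matches = int(np.count_nonzero(window == row))
            nonn = int(np.count_nonzero(window != N_BYTE))
            score = 5 * matches - 4 * nonn
            if score > best:
                second = best
                best, best_cand = score, (g, strand_i)
                best_matches, best_nonn = matches, nonn
                tie = False
            elif score == best:
                tie = True
                second = score
            elif score > second:
                second = score

        margin = best - second if second > NO_SCORE else best
        if tie or margin < min_margin:
            n_ambiguous += 1
            continue
        if best_matches < min_identity * max(best_nonn, 1):
            n_low_identity += 1
            continue
        g, strand_i = best_cand
        # a clipped window may start inside the N separator before its
        # reference; attribute it to the reference holding its content
        ref_i = index.ref_of(g)
        if ref_i < 0:
            ref_i = 0
        elif g >= index.offsets[ref_i] + index.lengths[ref_i]:
            ref_i += 1
        placements.append(
            Placement(
                read_id=rid,
                ref=index.names[ref_i],
                start=int(g - index.offsets[ref_i]),
                strand="-" if strand_i else "+",
                score=best_matches,
                margin=margin,
            )
        )
    return MappingResult(
        placements=placements,
        n_reads=reads.n_reads,
        n_unmapped=n_unmapped,
        n_ambiguous=n_ambiguous,
        n_low_identity=n_low_identity,
    )


def coverage_arrays(
    placements: Sequence[Placement], index: ReferenceIndex, read_length: int
) -> dict[str, np.ndarray]:
    """Per-base depth per reference from clipped aligned spans."""
    cov = {n: np.zeros(int(l) + 1, dtype=np.int64) for n, l in zip(index.names, index.lengths)}
    lens = dict(zip(index.names, (int(x) for x in index.lengths)))
    for p in placements:
        s, e = p.aligned_interval(read_length, lens[p.ref])
        if e > s:
            cov[p.ref][s] += 1
            cov[p.ref][e] -= 1
    return {n: np.cumsum(c[:-1]) for n, c in cov.items()}


@dataclass
class EnrichmentTable:
    """Per (marker, library) scaled coverage and fold enrichment."""

    fold: pd.DataFrame  # markers x libraries
    marker_coverage: pd.DataFrame  # scaled mean coverage per marker
    marker_raw_reads: pd.DataFrame  # unscaled coverage mass (zero test)
    genome_average: pd.Series  # scaled genome-wide mean per library
    junction_ok: Optional[pd.DataFrame] = None

    @property
    def markers(self) -> list[str]:
        return list(self.fold.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.fold.columns)

    def with_junctions(self, flags: pd.DataFrame) -> "EnrichmentTable":
        self.junction_ok = flags.loc[self.fold.index, self.fold.columns]
        return self


def fold_enrichment(
    placements_by_library: dict[str, Sequence[Placement]],
    index: ReferenceIndex,
    marker_intervals: dict[str, tuple[int, int]],
    *,
    map_ref: str,
    background_refs: Sequence[str],
    read_length: int,
) -> EnrichmentTable:
    """Fold enrichment of each marker over the genome-wide average.

    Coverage is scaled per million mapped reads per library (so doubling
    a library leaves folds unchanged); a marker's fold is its scaled mean
    coverage divided by the scaled mean over the background references
    (the genome average, excluding the minimal map itself, mirroring
    comparison against the reference genome's whole-genome average).
    """
    markers = list(marker_intervals)
    fold = pd.DataFrame(index=markers, columns=list(placements_by_library), dtype=float)
    mcov = fold.copy()
    mraw = fold.copy()
    gavg = pd.Series(index=list(placements_by_library), dtype=float)

    bg_len = sum(int(index.lengths[index.names.index(r)]) for r in background_refs)
    for lib, placements in placements_by_library.items():
        n_mapped = len(placements)
        if n_mapped == 0:
            raise ValueError(f"library {lib!r} has no mapped reads")
        scale = 1e6 / n_mapped
        cov = coverage_arrays(placements, index, read_length)
        bg_mass = sum(int(cov[r].sum()) for r in background_refs)
        if bg_mass == 0:
            raise ValueError(f"library {lib!r} has zero genome coverage (degenerate)")
        g = scale * bg_mass / bg_len
        gavg[lib] = g
        mapcov = cov[map_ref]
        for m, (s, e) in marker_intervals.items():
            raw = int(mapcov[s:e].sum())
            mraw.loc[m, lib] = raw
            mcov.loc[m, lib] = scale * raw / (e - s)
            fold.loc[m, lib] = mcov.loc[m, lib] / g
    return EnrichmentTable(
        fold=fold, marker_coverage=mcov, marker_raw_reads=mraw, genome_average=gavg
    )


def junction_coverage(
    placements: Sequence[Placement],
    marker_intervals: dict[str, tuple[int, int]],
    junction_positions: dict[str, int],
    *,
    read_length: int,
    map_ref: str,
    min_overhang: int = 10,
    min_depth: int = 1,
) -> dict[str, bool]:
    """Marker-level junction coverage flags.

    A marker passes iff every base of its interval has depth >=
    `min_depth` and its recorded junction is spanned by at least one read
    with `min_overhang` bases on both sides -- reads covering the whole
    marker including the unique LTR/flank junction, not just one repeat.
    """
    for m, j in junction_positions.items():
        s, e = marker_intervals[m]
        if not s <= j < e:
            raise ValueError(f"junction of {m} outside its marker interval")

    map_placements = [p for p in placements if p.ref == map_ref]
    n = max(e for _, e in marker_intervals.values()) + 1
    diff = np.zeros(n + 1, dtype=np.int64)
    spans = []
    for p in map_placements:
        s, e = max(0, p.start), min(n, p.start + read_length)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
            spans.append((s, e))
    depth = np.cumsum(diff[:-1])
    spans.sort()
    starts = np.array([s for s, _ in spans], dtype=np.int64)
    ends = np.array([e for _, e in spans], dtype=np.int64)

    flags = {}
    for m, (s, e) in marker_intervals.items():
        j = junction_positions[m]
        deep_enough = bool((depth[s:e] >= min_depth).all())
        spanned = bool(np.any((starts <= j - min_overhang) & (ends >= j + min_overhang)))
        flags[m] = deep_enough and spanned
    return flags


def junction_flags_frame(
    placements_by_library: dict[str, Sequence[Placement]],
    marker_intervals: dict[str, tuple[int, int]],
    junction_positions: dict[str, int],
    *,
    read_length: int,
    map_ref: str,
    min_overhang: int = 10,
    min_depth: int = 1,
) -> pd.DataFrame:
    out = {}
    for lib, placements in placements_by_library.items():
        out[lib] = junction_coverage(
            placements, marker_intervals, junction_positions,
            read_length=read_length, map_ref=map_ref,
            min_overhang=min_overhang, min_depth=min_depth,
        )
    return pd.DataFrame(out)
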