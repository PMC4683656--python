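"""Small shared sequence helpers used across the pipeline."""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: uint8 complement lookup table for ASCII-encoded sequences.
COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    COMP_LUT[_a] = _b


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministically derive a per-operation generator from a master seed.

    The derivation is fixed: the tag is hashed with CRC32 and combined with
    the master seed in a SeedSequence, so every operation sees an
    independent stream that is stable across runs and platforms.
    """
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())]))


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length n."""
    arr = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=n)]
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protect: Iterable[tuple[int, int]] = (),
) -> str:
    """Substitute each base independently with probability `rate`.

    Positions inside any `protect` interval (0-based half-open) are left
    untouched; substitutions always change the base.
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    for s, e in protect:
        hit[s:e] = False
    idx = np.nonzero(hit)[0]
    if idx.size:
        # draw a shift of 1..3 in base space so the base always changes
        codes = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            codes[b] = i
        newcodes = (codes[arr[idx]] + rng.integers(1, 4, size=idx.size)) % 4
        arr[idx] = np.frombuffer(b"ACGT", dtype=np.uint8)[newcodes]
    return arr.tobytes().decode()


def seq_occurs(needle: str, haystack: str) -> bool:
    """True if needle occurs in haystack on either strand."""
    return needle in haystack or revcomp(needle) in haystack


def find_all(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) start positions of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def write_fasta(records: dict[str, str], path) -> None:
    """Write name -> sequence records as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    seqio_write(recs, str(path), "fasta")


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, name, ...) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
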