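"""Deletion mapping of markers across misdivision derivatives.

Centromere misdivision produces derivative chromosomes whose retained
centromere intervals are nested down the pedigree.  Scoring each marker's
presence across the derivative series therefore orders markers into
groups by the generation at which they were first lost; concatenating the
marker sequences in that order (200-N spacers between them) yields the
"minimal map" pseudocontig used as the ChIP-seq alignment reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .repeatscape import LTR_TAG_LEN, DerivativeGenome
from .sequtils import seq_occurs
from .td_sim import TDMarker


@dataclass
class PresenceMatrix:
    """Markers x derivatives boolean matrix with pedigree metadata."""

    marker_ids: list[str]
    derivative_names: list[str]
    values: np.ndarray  # bool, shape (n_markers, n_derivatives)
    pedigree: dict[str, Optional[str]]  # derivative -> parent (None = root/external)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.marker_ids), len(self.derivative_names)):
            raise ValueError("matrix dimensions inconsistent with labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.marker_ids, columns=self.derivative_names)

    def present_in(self, derivative: str) -> list[str]:
        j = self.derivative_names.index(derivative)
        return [m for m, v in zip(self.marker_ids, self.values[:, j]) if v]

    @classmethod
    def from_published_table(cls) -> "PresenceMatrix":
        """The packaged published marker table as a PresenceMatrix."""
        df = fixtures.load_marker_table()
        cols = fixtures.DERIVATIVE_COLUMNS
        return cls(
            marker_ids=list(df.index),
            derivative_names=list(cols),
            values=df[cols].to_numpy(),
            pedigree=dict(fixtures.PEDIGREE),
        )


@dataclass
class MarkerPartition:
    """Markers grouped by loss pattern, ordered by generation of loss."""

    groups: list[tuple[tuple[bool, ...], list[str]]]
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(ids) for _, ids in self.groups]

    def ordered_marker_ids(self) -> list[str]:
        return [m for _, ids in self.groups for m in ids]


def score_presence(markers: Sequence[TDMarker], derivatives: Sequence[DerivativeGenome]) -> PresenceMatrix:
    """Score each marker's band sequence against each derivative.

    A cell is True iff the full band sequence occurs (either strand) in
    the derivative's sequence -- the in-silico analog of the TD band being
    amplifiable from that chromosome.
    """
    values = np.zeros((len(markers), len(derivatives)), dtype=bool)
    for i, m in enumerate(markers):
        for j, d in enumerate(derivatives):
            values[i, j] = seq_occurs(m.band.sequence, d.sequence)
    return PresenceMatrix(
        marker_ids=[m.id for m in markers],
        derivative_names=[d.name for d in derivatives],
        values=values,
        pedigree={d.name: d.parent for d in derivatives},
    )


def validate_nestedness(matrix: PresenceMatrix) -> list[tuple[str, str]]:
    """Marker/derivative pairs violating pedigree nestedness.

    A violation is a marker present in a child but absent from its parent
    (derivatives with no parent in the matrix are skipped).  The report is
    driven by the pedigree, not by column order.
    """
    out = []
    col = {d: j for j, d in enumerate(matrix.derivative_names)}
    for child, parent in matrix.pedigree.items():
        if parent is None or parent not in col or child not in col:
            continue
        jc, jp = col[child], col[parent]
        for i, m in enumerate(matrix.marker_ids):
            if matrix.values[i, jc] and not matrix.values[i, jp]:
                out.append((m, child))
    return out


def _main_chain(matrix: PresenceMatrix) -> list[str]:
    """Root-to-leaf pedigree chain in matrix column order.

    The chain is the matrix's column order restricted to derivatives that
    form a parent path from the root (side branches keep their columns but
    do not define loss generations).
    """
    names = matrix.derivative_names
    chain = []
    for name in names:
        parent = matrix.pedigree.get(name, None)
        if parent is None and not chain:
            chain.append(name)
        elif chain and parent == chain[-1]:
            chain.append(name)
    return chain or list(names)


def partition_markers(matrix: PresenceMatrix) -> MarkerPartition:
    """Group markers by identical loss pattern, ordered by loss generation.

    Markers sharing a full presence pattern form one group; groups are
    ordered by the generation (along the main pedigree chain) at which the
    marker was first lost, markers never lost forming the terminal group.
    A non-nested matrix is not rejected: the partition is returned with
    the violations annotated.
    """
    violations = validate_nestedness(matrix)
    chain = _main_chain(matrix)
    chain_cols = [matrix.derivative_names.index(d) for d in chain]

    patterns: dict[tuple[bool, ...], list[str]] = {}
    order: list[tuple[bool, ...]] = []
    for i, m in enumerate(matrix.marker_ids):
        pat = tuple(bool(x) for x in matrix.values[i])
        if pat not in patterns:
            patterns[pat] = []
            order.append(pat)
        patterns[pat].append(m)

    def loss_generation(pat: tuple[bool, ...]) -> int:
        for g, j in enumerate(chain_cols):
            if not pat[j]:
                return g
        return len(chain_cols) + 1  # never lost

    ordered = sorted(order, key=lambda p: (loss_generation(p), tuple(not x for x in p)))
    return MarkerPartition(
        groups=[(p, patterns[p]) for p in ordered],
        violations=violations,
    )


def order_markers(markers: Sequence[TDMarker], partition: MarkerPartition) -> list[TDMarker]:
    """Markers in minimal-map order: partition groups, ties by discovery id.

    Within a group the true arrangement is unknowable from deletion data
    alone; discovery id keeps the order deterministic.
    """
    by_id = {m.id: m for m in markers}
    ordered = [by_id[mid] for mid in partition.ordered_marker_ids()]
    if len(ordered) != len(markers):
        raise ValueError("partition does not cover the marker set")
    return ordered


def relabel(markers: Sequence[TDMarker]) -> list[TDMarker]:
    """Reassign ids TD1..TDn in the given (map) order, keeping names."""
    return [TDMarker(id=f"TD{i + 1}", name=m.name, band=m.band) for i, m in enumerate(markers)]


@dataclass
class Pseudocontig:
    """The minimal map: ordered marker sequences joined by N spacers."""

    sequence: str
    marker_intervals: dict[str, tuple[int, int]]
    spacer_length: int

    def __len__(self) -> int:
        return len(self.sequence)

    def junction_positions(self, junction_offset: int = LTR_TAG_LEN) -> dict[str, int]:
        """Absolute position of each marker's LTR/flank junction."""
        return {m: s + junction_offset for m, (s, e) in self.marker_intervals.items()}

    def marker_sequence(self, marker_id: str) -> str:
        s, e = self.marker_intervals[marker_id]
        return self.sequence[s:e]

    def to_fasta(self, path, name: str = "B_minimal_map") -> None:
        from .sequtils import write_fasta

        write_fasta({name: self.sequence}, path)


def build_pseudocontig(markers: Sequence[TDMarker], spacer_length: int = 200) -> Pseudocontig:
    """Concatenate marker sequences in map order with N spacers."""
    if not markers:
        raise ValueError("at least one marker required")
    parts = []
    intervals = {}
    pos = 0
    spacer = "N" * spacer_length
    for i, m in enumerate(markers):
        if i:
            parts.append(spacer)
            pos += spacer_length
        seq = m.band.sequence
        parts.append(seq)
        intervals[m.id] = (pos, pos + len(seq))
        pos += len(seq)
    return Pseudocontig(sequence="".join(parts), marker_intervals=intervals, spacer_length=spacer_length)
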