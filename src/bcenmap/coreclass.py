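"""Functional centromere-core classification and junction-junction PCR.

A marker is scored as interacting with CENH3 only under the strict
multi-library rule: enrichment above threshold in *every* replicate from
the line with an active B centromere, no more than a fold ceiling in the
replicates from the inactive-centromere line, no unique coverage at all
in the negative-control libraries (CENH3 ChIP and fragmented genomic DNA
from the B-less background), and ChIP reads covering the whole marker
across its junction in every active replicate.

The core span combines those calls with which misdivision derivatives
still behave as fully functional chromosomes (a biological observation
supplied as input, not computed): the core is the marker suffix retained
by the smallest fully functional derivative.

Junction-junction PCR converts markers to simple assays: one primer
anchored in the LTR tag, the other straddling the LTR/flank junction, so
the pair amplifies exactly one product from a B-carrying genome and none
without the B chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .chipmap import EnrichmentTable
from .deletion_map import MarkerPartition, PresenceMatrix
from .repeatscape import LTR_TAG_LEN, DerivativeGenome
from .sequtils import find_all, revcomp
from .td_sim import TDMarker

ROLES = ("active_chip", "inactive_chip", "negative_chip", "fragmented_control")


@dataclass
class LibraryDesign:
    """Role of each sequencing library in the classification rule."""

    roles: dict[str, str]  # library name -> role

    def __post_init__(self):
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not self.by_role("active_chip"):
            raise ValueError("at least one active replicate required")
        if not (self.by_role("negative_chip") or self.by_role("fragmented_control")):
            raise ValueError("at least one control library required")

    def by_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    @property
    def replicate_counts(self) -> dict[str, int]:
        return {role: len(self.by_role(role)) for role in ROLES}


@dataclass
class CoreCall:
    """Per-marker core/non-core calls with the criteria behind them."""

    calls: dict[str, bool]
    reasons: dict[str, dict[str, bool]]
    core_span: Optional[tuple[str, str]] = None
    span_marker_ids: list[str] = field(default_factory=list)

    @property
    def core_ids(self) -> list[str]:
        return [m for m, c in self.calls.items() if c]

    @classmethod
    def from_flags(cls, flags: dict[str, bool]) -> "CoreCall":
        """Build a call set from externally scored CENH3 flags."""
        return cls(calls=dict(flags), reasons={m: {"external": v} for m, v in flags.items()})


def classify_core(
    table: EnrichmentTable,
    design: LibraryDesign,
    t_active: float = 2.0,
    t_inactive: float = 2.0,
) -> CoreCall:
    """Apply the strict multi-library rule to every marker.

    is_core requires fold > t_active in every active replicate, fold <=
    t_inactive in every inactive replicate, zero uniquely mapped coverage
    in every negative/fragmented control, and junction-spanning coverage
    in every active replicate.
    """
    missing = [n for n in design.roles if n not in table.libraries]
    if missing:
        raise KeyError(f"libraries missing from the enrichment table: {missing}")
    if table.junction_ok is None:
        raise ValueError("enrichment table lacks junction coverage flags")

    active = design.by_role("active_chip")
    inactive = design.by_role("inactive_chip")
    controls = design.by_role("negative_chip") + design.by_role("fragmented_control")

    calls, reasons = {}, {}
    for m in table.markers:
        ok_active = all(table.fold.loc[m, lib] > t_active for lib in active)
        ok_inactive = all(table.fold.loc[m, lib] <= t_inactive for lib in inactive)
        ok_controls = all(table.marker_raw_reads.loc[m, lib] == 0 for lib in controls)
        ok_junction = all(bool(table.junction_ok.loc[m, lib]) for lib in active)
        reasons[m] = {
            "active_enrichment": ok_active,
            "inactive_ceiling": ok_inactive,
            "control_zero": ok_controls,
            "junction_covered": ok_junction,
        }
        calls[m] = ok_active and ok_inactive and ok_controls and ok_junction
    return CoreCall(calls=calls, reasons=reasons)


def infer_core_span(
    call: CoreCall,
    partition: MarkerPartition,
    matrix: PresenceMatrix,
    functional_derivatives: Sequence[str],
) -> CoreCall:
    """Core domain = markers retained by the smallest functional derivative.

    Misdivision must break within the centromere, so markers lost by
    derivatives that still transmit normally cannot be required for
    function; the core domain is the retained marker set of the smallest
    such derivative, which must still include at least one CENH3-positive
    marker.  The span is reported in minimal-map order and always
    contains every called core marker retained on the map.
    """
    if not call.core_ids:
        raise ValueError("no core markers called")
    candidates = [d for d in functional_derivatives if d in matrix.derivative_names]
    if not candidates:
        raise ValueError("no functional derivatives present in the matrix")
    smallest = min(candidates, key=lambda d: len(matrix.present_in(d)))
    retained = set(matrix.present_in(smallest))
    if not retained & set(call.core_ids):
        raise ValueError(
            f"smallest functional derivative {smallest} retains no CENH3-positive marker"
        )
    map_order = partition.ordered_marker_ids()
    span = [m for m in map_order if m in retained]
    call.core_span = (span[0], span[-1])
    call.span_marker_ids = span
    return call


# ---------------------------------------------------------------------------
# junction-junction PCR
# ---------------------------------------------------------------------------


@dataclass
class PrimerPair:
    marker_id: str
    forward: str
    reverse: str
    expected_size: int


@dataclass
class PCRResult:
    present: bool
    sizes: list[int]


def insilico_pcr(pair: PrimerPair, genome: str, max_size: int = 2000) -> PCRResult:
    """Predict amplification: convergent primer sites within max_size.

    Both orientations of the (unordered) pair are scanned; a product is
    any interval from a forward-primer site to a downstream reverse-
    primer complement site, no longer than max_size.
    """
    sizes = []
    for left, right in ((pair.forward, pair.reverse), (pair.reverse, pair.forward)):
        rlen = len(right)
        right_rc_sites = find_all(revcomp(right), genome)
        for i in find_all(left, genome):
            for j in right_rc_sites:
                size = j + rlen - i
                if j >= i + len(left) and size <= max_size:
                    sizes.append(size)
    return PCRResult(present=bool(sizes), sizes=sorted(sizes))


def design_junction_primers(
    marker: TDMarker,
    b_plus: str,
    b_minus: str,
    *,
    primer_length: int = 20,
    min_straddle: int = 5,
    max_size: int = 2000,
    junction_offset: int = LTR_TAG_LEN,
) -> PrimerPair:
    """Design a unique junction-junction pair for a marker.

    The reverse primer straddles the marker's LTR/flank junction
    (min_straddle bases on each side); the forward primer is slid along
    the LTR tag until the pair yields exactly one product from the
    B-carrying genome and none from the B-less genome.  Raises if no such
    pair exists (the marker is reported un-convertible).
    """
    band = marker.band.sequence
    if len(band) < junction_offset + min_straddle:
        raise ValueError(f"marker {marker.id} has no junction to straddle")
    half = primer_length // 2
    straddle_start = junction_offset - max(half, min_straddle)
    straddle_start = max(0, min(straddle_start, len(band) - primer_length))
    site = band[straddle_start : straddle_start + primer_length]
    reverse = revcomp(site)
    amp_end = straddle_start + primer_length

    for f in range(0, junction_offset - primer_length + 1):
        forward = band[f : f + primer_length]
        pair = PrimerPair(
            marker_id=marker.id,
            forward=forward,
            reverse=reverse,
            expected_size=amp_end - f,
        )
        plus = insilico_pcr(pair, b_plus, max_size)
        if len(plus.sizes) != 1 or plus.sizes[0] != pair.expected_size:
            continue
        if insilico_pcr(pair, b_minus, max_size).present:
            continue
        return pair
    raise ValueError(f"marker {marker.id}: no unique junction-junction pair found")


def genotype_derivatives(
    pairs: Sequence[PrimerPair],
    derivatives: Sequence[DerivativeGenome],
    max_size: int = 2000,
) -> pd.DataFrame:
    """Amplification vector of each primer pair across derivatives."""
    out = pd.DataFrame(
        index=[p.marker_id for p in pairs],
        columns=[d.name for d in derivatives],
        dtype=bool,
    )
    for p in pairs:
        for d in derivatives:
            out.loc[p.marker_id, d.name] = insilico_pcr(p, d.sequence, max_size).present
    return out
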