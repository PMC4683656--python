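"""End-to-end synthetic B-centromere experiment.

Stages (each usable on its own; the numbered analysis scripts are thin
drivers over these functions):

1. genomes    -- repeat library; B chromosome (two arms flanking a 40-
                 insertion centromere, 21 further insertions on the arms);
                 a B-less background genome carrying its own satellite
                 array and two shared CRM2 copies; a centromere-only miniB.
2. display    -- 64-lane CRM2 transposon display of B+ vs B-, B-specific
                 band calling, duplicate collapse (61 markers), miniB
                 screen (40 markers).
3. deletion map -- misdivision pedigree with excision points placed
                 between marker footprints, presence matrix, partition,
                 minimal-map ordering and pseudocontig assembly.
4. chip       -- seven sequencing libraries (three active-centromere
                 replicates, two inactive, CENH3 and fragmented controls
                 from the B-less background), unique mapping to
                 background + minimal map, fold enrichment and junction
                 coverage.
5. classify   -- strict multi-library core calling, core-span inference,
                 junction-junction PCR conversion and derivative
                 genotyping.

The default marker sizes are the study's 40 printed band sizes scaled to
a 10,100-bp total (printed gel sizes include adapter/primer tails); the
seven planted CENH3 folds are the printed per-marker enrichment values,
used here as simulation parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import fixtures
from .chipmap import (
    EnrichmentTable,
    MappingResult,
    ReferenceIndex,
    build_index,
    fold_enrichment,
    junction_flags_frame,
    map_reads,
)
from .coreclass import (
    CoreCall,
    LibraryDesign,
    PrimerPair,
    design_junction_primers,
    classify_core,
    genotype_derivatives,
    infer_core_span,
)
from .deletion_map import (
    MarkerPartition,
    PresenceMatrix,
    Pseudocontig,
    build_pseudocontig,
    order_markers,
    partition_markers,
    relabel,
    score_presence,
)
from .repeatscape import (
    Assembly,
    CentromereLayout,
    DerivativeGenome,
    Feature,
    Insertion,
    PedigreeNode,
    ReadSet,
    RepeatLibrary,
    _LTR_LEN_CACHE,
    band_sequence,
    build_repeat_library,
    concat_readsets,
    derive_pedigree,
    simulate_centromere,
    simulate_chip_reads,
)
from .sequtils import child_rng, mutate, random_dna
from .td_sim import (
    BFAI,
    PrimerSet,
    TDMarker,
    call_b_specific,
    collapse_and_name,
    filter_by_genome,
    run_display,
)

MAP_REF = "B_minimal_map"
BACKGROUND_REF = "B73_chr1"

MAIN_CHAIN = ["TB9Sb", "PI", "Telo2_1", "Iso3", "Telo2_2"]
#: derivatives with unreduced transmission (biological observation used
#: as classifier input: Iso3(-) transmits at 53 %, Telo2-2(-) drops to 43 %)
FUNCTIONAL_DERIVATIVES = ["TB9Sb", "PI", "Telo2_1", "Iso3"]


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment."""

    backbone_bp: int = 36_000
    n_b_blocks: int = 5
    n_cen_insertions: int = 40
    arm_bp: int = 15_000
    n_arm_insertions: int = 21
    background_bp: int = 30_000
    background_centc: int = 12
    read_length: int = 150
    k: int = 40
    min_margin: int = 5
    min_identity: float = 0.95
    coverage_active: float = 30.0
    coverage_inactive: float = 15.0
    coverage_control: float = 15.0
    n_active: int = 3
    n_inactive: int = 2
    spacer: int = 200
    t_active: float = 2.0
    t_inactive: float = 2.0
    # 1-based minimal-map slots carrying planted CENH3 occupancy and the
    # per-marker fold values (the study's printed enrichment figures)
    core_slots: tuple[int, ...] = (7, 9, 10, 15, 18, 21, 29)
    core_folds: tuple[float, ...] = (36.0, 3.0, 18.0, 12.0, 23.0, 6.0, 31.0)
    arm_band_sizes: tuple[int, ...] = tuple(range(450, 660, 10))
    background_band_sizes: tuple[int, ...] = (700, 720)

    def __post_init__(self):
        if len(self.core_slots) != len(self.core_folds):
            raise ValueError("core_slots and core_folds must align")
        if len(self.arm_band_sizes) != self.n_arm_insertions:
            raise ValueError("one arm band size per arm insertion required")


def default_marker_lengths(total: int = 10_100) -> list[int]:
    """The 40 printed band sizes scaled to the reported 10.1-kb map total.

    Printed gel sizes include adapter/primer tails; largest-remainder
    apportionment proportional to the printed sizes keeps the length
    profile while making the map total exact.
    """
    sizes = fixtures.marker_sizes()
    quo = [total * s / sum(sizes) for s in sizes]
    base = [math.floor(q) for q in quo]
    rem = total - sum(base)
    order = sorted(range(len(sizes)), key=lambda i: quo[i] - base[i], reverse=True)
    out = list(base)
    for i in order[:rem]:
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# stage 1: genomes
# ---------------------------------------------------------------------------


@dataclass
class RootGenome:
    """Root B chromosome presented to the pedigree engine."""

    sequence: str
    cenh3_domain: tuple[int, int]


@dataclass
class SyntheticGenomes:
    lib: RepeatLibrary
    cen_layout: CentromereLayout
    cen_offset: int  # centromere start within the B chromosome
    bchrom: str  # arm5 + centromere + arm3
    arm_insertions: list[Insertion]  # band spans in bchrom coordinates
    background: str
    minib: str
    b_plus: str  # background || B chromosome (TD template)
    b_minus: str  # background alone

    def cen_insertions_bchrom(self) -> list[Insertion]:
        """Centromere insertions with band spans lifted to bchrom coords."""
        out = []
        for ins in self.cen_layout.insertions:
            out.append(
                Insertion(
                    index=ins.index,
                    orientation=ins.orientation,
                    start=ins.start + self.cen_offset,
                    end=ins.end + self.cen_offset,
                    band_start=ins.band_start + self.cen_offset,
                    band_end=ins.band_end + self.cen_offset,
                    band_size=ins.band_size,
                )
            )
        return out


def _filler_backbone(lib: RepeatLibrary, rng: np.random.Generator, target_bp: int,
                     unique_label: str, n_filler: int = 2) -> tuple[str, list[Feature]]:
    """Mostly-unique DNA with a few mutated filler-element copies."""
    filler_names = list(lib.fillers)
    parts, feats = [], []
    pos = 0

    def add(unit: str, seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        feats.append(Feature(pos, pos + len(seq), unit, 0))
        pos += len(seq)

    filler_bp = sum(len(lib.fillers[n]) for n in filler_names[:n_filler])
    chunk = max(1000, (target_bp - filler_bp) // (n_filler + 1))
    for i in range(n_filler):
        add(unique_label, random_dna(rng, chunk))
        name = filler_names[i % len(filler_names)]
        add(name, mutate(lib.fillers[name], 0.08, rng))
    add(unique_label, random_dna(rng, max(1000, target_bp - pos)))
    return "".join(parts), feats


def _build_arm(lib: RepeatLibrary, seed: int, tag: str, band_sizes: Sequence[int],
               arm_bp: int) -> tuple[str, list[Insertion]]:
    rng = child_rng(seed, tag)
    _LTR_LEN_CACHE[0] = len(lib.ltr_5p)
    seq, feats = _filler_backbone(lib, rng, arm_bp, "arm_dna")
    asm = Assembly(seq, feats, rng)
    for size in band_sizes:
        asm.insert_element(lib, size, ltr_div=0.08, body_div=0.08)
    return asm.seq, sorted(asm.insertions, key=lambda i: i.band_start)


def _build_background(lib: RepeatLibrary, seed: int, cfg: SimConfig) -> str:
    """B-less genome: unique DNA, its own CentC array, fillers, and two
    CRM2 copies shared with the B+ genotype (their bands cancel in the
    display comparison)."""
    rng = child_rng(seed, "background")
    _LTR_LEN_CACHE[0] = len(lib.ltr_5p)
    seq, feats = _filler_backbone(lib, rng, cfg.background_bp, "bg_dna")
    # a diverged satellite array of its own (the reference genome has
    # centromeres too; control reads from it must map there, not to the map)
    pos = len(seq)
    arr = "".join(mutate(lib.centc_monomer, 0.08, rng) for _ in range(cfg.background_centc))
    feats.append(Feature(pos, pos + len(arr), "centc", 0))
    seq += arr
    asm = Assembly(seq, feats, rng)
    for size in cfg.background_band_sizes:
        asm.insert_element(lib, size, ltr_div=0.08, body_div=0.08)
    return asm.seq


def build_genomes(seed: int, cfg: Optional[SimConfig] = None) -> SyntheticGenomes:
    cfg = cfg or SimConfig()
    lib = build_repeat_library(seed)
    cen = simulate_centromere(
        lib,
        cfg.n_cen_insertions,
        seed,
        backbone_bp=cfg.backbone_bp,
        n_b_blocks=cfg.n_b_blocks,
        band_sizes=default_marker_lengths() if cfg.n_cen_insertions == 40 else None,
    )
    n5 = cfg.n_arm_insertions // 2
    arm5, ins5 = _build_arm(lib, seed, "arm5", cfg.arm_band_sizes[:n5], cfg.arm_bp)
    arm3, ins3 = _build_arm(lib, seed, "arm3", cfg.arm_band_sizes[n5:], cfg.arm_bp)
    background = _build_background(lib, seed, cfg)

    cen_offset = len(arm5)
    bchrom = arm5 + cen.sequence + arm3
    arm_ins = [
        Insertion(i.index, i.orientation, i.start, i.end, i.band_start, i.band_end, i.band_size)
        for i in ins5
    ] + [
        Insertion(
            i.index,
            i.orientation,
            i.start + cen_offset + len(cen.sequence),
            i.end + cen_offset + len(cen.sequence),
            i.band_start + cen_offset + len(cen.sequence),
            i.band_end + cen_offset + len(cen.sequence),
            i.band_size,
        )
        for i in ins3
    ]
    b_plus = background + "N" * 50 + bchrom
    return SyntheticGenomes(
        lib=lib,
        cen_layout=cen,
        cen_offset=cen_offset,
        bchrom=bchrom,
        arm_insertions=arm_ins,
        background=background,
        minib=cen.sequence,
        b_plus=b_plus,
        b_minus=background,
    )


# ---------------------------------------------------------------------------
# stage 2: transposon display
# ---------------------------------------------------------------------------


@dataclass
class DisplayResult:
    primers: PrimerSet
    n_lanes: int
    b_specific_markers: list[TDMarker]  # the 61
    centromeric_markers: list[TDMarker]  # the 40 surviving the miniB screen


def run_td_stage(genomes: SyntheticGenomes, tolerance: int = 0) -> DisplayResult:
    primers = PrimerSet.from_library(genomes.lib)
    profiles = run_display(genomes.b_plus, genomes.b_minus, BFAI, primers, tolerance)
    called = call_b_specific(profiles)
    markers = collapse_and_name(called)
    retained = filter_by_genome(markers, genomes.minib)
    return DisplayResult(
        primers=primers,
        n_lanes=len(profiles.lanes["B+"]),
        b_specific_markers=markers,
        centromeric_markers=retained,
    )


# ---------------------------------------------------------------------------
# stage 3: deletion mapping
# ---------------------------------------------------------------------------


@dataclass
class DeletionMapResult:
    derivatives: list[DerivativeGenome]  # main chain + Telo3_3 + Telo4_11
    matrix: PresenceMatrix  # main-chain columns (the Table-1 analog)
    matrix_all: PresenceMatrix  # all derivatives
    partition: MarkerPartition
    map_markers: list[TDMarker]  # relabeled TD1..TD40 in map order
    pseudocontig: Pseudocontig
    cenh3_domain: tuple[int, int]  # bchrom coords, hull of planted core markers
    core_marker_ids: list[str]  # map ids carrying planted CENH3 occupancy
    core_fold_map: dict[tuple[int, int], float]  # bchrom intervals -> fold

    @property
    def root(self) -> DerivativeGenome:
        return self.derivatives[0]


def _marker_footprints(genomes: SyntheticGenomes, markers: Sequence[TDMarker]) -> dict[str, Insertion]:
    """Match each marker to its source insertion by band sequence."""
    by_seq = {band_sequence(genomes.bchrom, ins): ins for ins in genomes.cen_insertions_bchrom()}
    out = {}
    for m in markers:
        ins = by_seq.get(m.band.sequence)
        if ins is None:
            raise ValueError(f"marker {m.id} has no matching planted insertion")
        out[m.id] = ins
    return out


def _envelope(ins: Insertion, pad: int = 10) -> tuple[int, int]:
    return (ins.band_start - 4 - pad, ins.band_end + 4 + pad)


def run_deletion_map_stage(
    genomes: SyntheticGenomes,
    markers40: Sequence[TDMarker],
    cfg: Optional[SimConfig] = None,
) -> DeletionMapResult:
    cfg = cfg or SimConfig()
    foot = _marker_footprints(genomes, markers40)
    by_pos = sorted(markers40, key=lambda m: foot[m.id].band_start)

    def gap_cut(k: int) -> int:
        """Excision point between position-sorted markers k and k+1 (1-based)."""
        left = max(_envelope(foot[m.id])[1] for m in by_pos[:k])
        right = min(_envelope(foot[m.id])[0] for m in by_pos[k:])
        if right <= left:
            raise ValueError(f"no clean excision gap after marker {k}")
        return (left + right) // 2

    cuts = {"PI": gap_cut(5), "Telo2_1": gap_cut(6), "Iso3": gap_cut(7), "Telo2_2": gap_cut(9)}

    # main chain first: the partition defines map order and the core slots
    root = RootGenome(sequence=genomes.bchrom, cenh3_domain=(0, 1))
    chain_spec = [
        PedigreeNode("TB9Sb", None, 0.0),
        PedigreeNode("PI", "TB9Sb", 0.0, cut_at=cuts["PI"]),
        PedigreeNode("Telo2_1", "PI", 0.0, cut_at=cuts["Telo2_1"] - cuts["PI"]),
        PedigreeNode("Iso3", "Telo2_1", 0.0, cut_at=cuts["Iso3"] - cuts["Telo2_1"]),
        PedigreeNode("Telo2_2", "Iso3", 0.0, cut_at=cuts["Telo2_2"] - cuts["Iso3"]),
    ]
    chain = derive_pedigree(root, chain_spec)
    matrix0 = score_presence(list(markers40), chain)
    part0 = partition_markers(matrix0)
    map_markers = relabel(order_markers(list(markers40), part0))

    foot_new = _marker_footprints(genomes, map_markers)
    core_ids = [f"TD{slot}" for slot in cfg.core_slots]
    core_spans = [foot_new[m].band_span for m in core_ids]
    # pad by read_length - k: exactly the start positions whose reads can
    # still seed (>= k bases) on the marker
    pad = cfg.read_length - cfg.k
    hull = (
        min(s for s, _ in core_spans) - pad,
        max(e for _, e in core_spans) + pad,
    )
    core_fold_map = {
        (s - pad, e + pad): f for (s, e), f in zip(core_spans, cfg.core_folds)
    }

    # full pedigree including the side branches
    root = RootGenome(sequence=genomes.bchrom, cenh3_domain=hull)
    full_spec = chain_spec + [
        PedigreeNode("Telo3_3", "Iso3", 0.0, cut_at=hull[1] - cuts["Iso3"]),
        PedigreeNode("Telo4_11", "Telo2_2", 0.0),
    ]
    derivatives = derive_pedigree(root, full_spec)

    matrix = score_presence(map_markers, derivatives[:5])
    matrix_all = score_presence(map_markers, derivatives)
    partition = partition_markers(matrix)
    pseudocontig = build_pseudocontig(map_markers, cfg.spacer)
    return DeletionMapResult(
        derivatives=derivatives,
        matrix=matrix,
        matrix_all=matrix_all,
        partition=partition,
        map_markers=map_markers,
        pseudocontig=pseudocontig,
        cenh3_domain=hull,
        core_marker_ids=core_ids,
        core_fold_map=core_fold_map,
    )


# ---------------------------------------------------------------------------
# stage 4: ChIP libraries, mapping, enrichment
# ---------------------------------------------------------------------------


@dataclass
class ChipResult:
    design: LibraryDesign
    readsets: dict[str, ReadSet]
    index: ReferenceIndex
    mappings: dict[str, MappingResult]
    table: EnrichmentTable


def _library_reads(
    name: str,
    role: str,
    genomes: SyntheticGenomes,
    fold_map: dict[tuple[int, int], float],
    cenh3_domain: tuple[int, int],
    coverage: float,
    cfg: SimConfig,
    seed: int,
    with_b: bool,
) -> ReadSet:
    L = cfg.read_length
    parts = []
    w_bg = len(genomes.background) - L + 1
    if with_b:
        n_starts = len(genomes.bchrom) - L + 1
        w_b = float(n_starts)
        if role == "active_chip":
            for (s, e), f in fold_map.items():
                w_b += (f - 1.0) * (min(e, n_starts) - max(0, s))
    else:
        w_b = 0.0
    n_total = int(round(coverage * (w_bg + w_b) / L))
    n_bg = max(1, int(round(n_total * w_bg / (w_bg + w_b))))
    parts.append(
        simulate_chip_reads(
            genomes.background, None, role, {}, n_bg, L, seed, library_name=f"{name}.bg"
        )
    )
    if with_b:
        n_b = max(1, n_total - n_bg)
        parts.append(
            simulate_chip_reads(
                genomes.bchrom, None, role, fold_map, n_b, L, seed,
                library_name=f"{name}.b", cenh3_domain=cenh3_domain,
            )
        )
    return concat_readsets(name, parts)


def run_chip_stage(
    genomes: SyntheticGenomes,
    dmap: DeletionMapResult,
    seed: int,
    cfg: Optional[SimConfig] = None,
) -> ChipResult:
    cfg = cfg or SimConfig()
    roles = {}
    for i in range(cfg.n_active):
        roles[f"TB9Sb_rep{i + 1}"] = "active_chip"
    for i in range(cfg.n_inactive):
        roles[f"9Bic1_rep{i + 1}"] = "inactive_chip"
    roles["B73_CENH3"] = "negative_chip"
    roles["B73_fragmented"] = "fragmented_control"
    design = LibraryDesign(roles)

    readsets = {}
    for name, role in roles.items():
        with_b = role in ("active_chip", "inactive_chip")
        coverage = {
            "active_chip": cfg.coverage_active,
            "inactive_chip": cfg.coverage_inactive,
            "negative_chip": cfg.coverage_control,
            "fragmented_control": cfg.coverage_control,
        }[role]
        readsets[name] = _library_reads(
            name, role, genomes, dmap.core_fold_map, dmap.cenh3_domain,
            coverage, cfg, seed, with_b,
        )

    index = build_index(
        {BACKGROUND_REF: genomes.background, MAP_REF: dmap.pseudocontig.sequence}, k=cfg.k
    )
    mappings = {
        name: map_reads(rs, index, cfg.min_margin, min_identity=cfg.min_identity)
        for name, rs in readsets.items()
    }
    placements = {name: mr.placements for name, mr in mappings.items()}
    table = fold_enrichment(
        placements,
        index,
        dmap.pseudocontig.marker_intervals,
        map_ref=MAP_REF,
        background_refs=[BACKGROUND_REF],
        read_length=cfg.read_length,
    )
    flags = junction_flags_frame(
        placements,
        dmap.pseudocontig.marker_intervals,
        dmap.pseudocontig.junction_positions(),
        read_length=cfg.read_length,
        map_ref=MAP_REF,
    )
    table.with_junctions(flags)
    return ChipResult(design=design, readsets=readsets, index=index, mappings=mappings, table=table)


# ---------------------------------------------------------------------------
# stage 5: classification + PCR genotyping
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    call: CoreCall
    pairs: list[PrimerPair]
    genotypes: "object"  # DataFrame: pairs x derivatives


def run_classification_stage(
    genomes: SyntheticGenomes,
    dmap: DeletionMapResult,
    chip: ChipResult,
    cfg: Optional[SimConfig] = None,
) -> ClassificationResult:
    cfg = cfg or SimConfig()
    call = classify_core(chip.table, chip.design, cfg.t_active, cfg.t_inactive)
    if call.core_ids:
        infer_core_span(call, dmap.partition, dmap.matrix, FUNCTIONAL_DERIVATIVES)
    by_id = {m.id: m for m in dmap.map_markers}
    pairs = [
        design_junction_primers(by_id[mid], genomes.b_plus, genomes.b_minus)
        for mid in dmap.core_marker_ids
    ]
    genotypes = genotype_derivatives(pairs, dmap.derivatives)
    return ClassificationResult(call=call, pairs=pairs, genotypes=genotypes)


# ---------------------------------------------------------------------------
# the whole experiment
# ---------------------------------------------------------------------------


@dataclass
class Experiment:
    seed: int
    cfg: SimConfig
    genomes: SyntheticGenomes
    display: DisplayResult
    dmap: DeletionMapResult
    chip: ChipResult
    classification: ClassificationResult


def run_experiment(seed: int, cfg: Optional[SimConfig] = None) -> Experiment:
    cfg = cfg or SimConfig()
    genomes = build_genomes(seed, cfg)
    display = run_td_stage(genomes)
    dmap = run_deletion_map_stage(genomes, display.centromeric_markers, cfg)
    chip = run_chip_stage(genomes, dmap, seed, cfg)
    classification = run_classification_stage(genomes, dmap, chip, cfg)
    return Experiment(
        seed=seed, cfg=cfg, genomes=genomes, display=display, dmap=dmap,
        chip=chip, classification=classification,
    )


def classifier_trial(seed: int, cfg: Optional[SimConfig] = None) -> dict:
    """One seeded end-to-end run, summarised for recovery statistics."""
    exp = run_experiment(seed, cfg)
    called = sorted(exp.classification.call.core_ids, key=lambda s: int(s[2:]))
    expected = sorted(exp.dmap.core_marker_ids, key=lambda s: int(s[2:]))
    active = exp.chip.design.by_role("active_chip")
    folds = {
        m: float(exp.chip.table.fold.loc[m, active].mean()) for m in expected
    }
    return {
        "seed": seed,
        "called": called,
        "expected": expected,
        "exact_recovery": called == expected,
        "mean_active_fold": folds,
    }
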