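"""Core-marker classification, core-span inference, and junction PCR."""

import numpy as np
import pandas as pd
import pytest

from bcenmap.chipmap import EnrichmentTable
from bcenmap.coreclass import (
    CoreCall,
    LibraryDesign,
    PrimerPair,
    classify_core,
    design_junction_primers,
    genotype_derivatives,
    infer_core_span,
    insilico_pcr,
)
from bcenmap.deletion_map import partition_markers
from bcenmap.sequtils import random_dna, revcomp
from bcenmap.td_sim import TDBand, TDMarker

LIBS = ["act1", "act2", "act3", "in1", "in2", "neg", "frag"]
ROLES = {
    "act1": "active_chip", "act2": "active_chip", "act3": "active_chip",
    "in1": "inactive_chip", "in2": "inactive_chip",
    "neg": "negative_chip", "frag": "fragmented_control",
}


def _table(fold_rows: dict[str, list[float]], zero_controls=True, junction=True) -> EnrichmentTable:
    fold = pd.DataFrame(fold_rows, index=LIBS).T
    raw = fold * 100.0
    if zero_controls:
        raw.loc[:, ["neg", "frag"]] = 0.0
    junc = pd.DataFrame(junction, index=fold.index, columns=LIBS)
    return EnrichmentTable(
        fold=fold,
        marker_coverage=fold.copy(),
        marker_raw_reads=raw,
        genome_average=pd.Series(1.0, index=LIBS),
        junction_ok=junc,
    )


class TestLibraryDesign:
    def test_replicate_counts(self):
        d = LibraryDesign(ROLES)
        assert d.replicate_counts == {
            "active_chip": 3, "inactive_chip": 2, "negative_chip": 1, "fragmented_control": 1,
        }

    def test_missing_active_or_control_rejected(self):
        with pytest.raises(ValueError):
            LibraryDesign({"in1": "inactive_chip", "neg": "negative_chip"})
        with pytest.raises(ValueError):
            LibraryDesign({"act1": "active_chip", "in1": "inactive_chip"})


class TestClassifyCore:
    def test_printed_fold_pattern_called(self):
        """Markers planted at the study's printed folds all pass; threefold
        enrichment requires the active threshold to sit below 3."""
        folds = [36.0, 3.0, 18.0, 12.0, 23.0, 6.0, 31.0]
        rows = {f"TD{i}": [f, f, f, 1.0, 1.0, 0.0, 0.0] for i, f in zip(range(1, 8), folds)}
        rows["TDx"] = [1.0] * 7
        call = classify_core(_table(rows), LibraryDesign(ROLES))
        assert call.core_ids == [f"TD{i}" for i in range(1, 8)]

    def test_control_coverage_disqualifies(self):
        rows = {"a": [20.0, 20.0, 20.0, 1.0, 1.0, 0.5, 0.0]}
        t = _table(rows, zero_controls=False)
        call = classify_core(t, LibraryDesign(ROLES))
        assert call.calls["a"] is False
        assert call.reasons["a"]["control_zero"] is False

    def test_all_flat_zero_calls(self):
        rows = {m: [1.0] * 7 for m in ["a", "b", "c"]}
        call = classify_core(_table(rows), LibraryDesign(ROLES))
        assert call.core_ids == []

    def test_single_failing_active_replicate_disqualifies(self):
        rows = {"a": [10.0, 1.5, 10.0, 1.0, 1.0, 0.0, 0.0]}
        call = classify_core(_table(rows), LibraryDesign(ROLES))
        assert call.calls["a"] is False

    def test_inactive_above_ceiling_disqualifies(self):
        rows = {"a": [10.0, 10.0, 10.0, 2.5, 1.0, 0.0, 0.0]}
        call = classify_core(_table(rows), LibraryDesign(ROLES))
        assert call.reasons["a"]["inactive_ceiling"] is False

    def test_junction_gap_disqualifies(self):
        rows = {"a": [10.0, 10.0, 10.0, 1.0, 1.0, 0.0, 0.0]}
        t = _table(rows)
        t.junction_ok.loc["a", "act2"] = False
        call = classify_core(t, LibraryDesign(ROLES))
        assert call.reasons["a"]["junction_covered"] is False

    def test_missing_library_named_in_error(self):
        rows = {"a": [10.0] * 7}
        t = _table(rows)
        t.fold = t.fold.drop(columns=["frag"])
        with pytest.raises(KeyError, match="frag"):
            classify_core(t, LibraryDesign(ROLES))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        rows = {
            f"m{i}": list(rng.uniform(0, 8, 5)) + [0.0, 0.0] for i in range(30)
        }
        t = _table(rows)
        design = LibraryDesign(ROLES)
        base = set(classify_core(t, design, 2.0, 2.0).core_ids)
        higher_active = set(classify_core(t, design, 3.0, 2.0).core_ids)
        lower_inactive = set(classify_core(t, design, 2.0, 1.0).core_ids)
        assert higher_active <= base
        assert lower_inactive <= base


class TestInferCoreSpan:
    def _call_from_published_table(self, published_matrix):
        from bcenmap import fixtures

        df = fixtures.load_marker_table()
        return CoreCall.from_flags(dict(df["cenh3"]))

    def test_smallest_functional_derivative_gives_33_markers(self, published_matrix):
        call = self._call_from_published_table(published_matrix)
        part = partition_markers(published_matrix)
        infer_core_span(call, part, published_matrix, ["TB9Sb", "PI", "Telo2_1", "Iso3"])
        assert call.core_span == ("TD8", "TD40")
        assert len(call.span_marker_ids) == 33

    def test_all_core_spans_whole_map(self, published_matrix):
        call = CoreCall.from_flags({m: True for m in published_matrix.marker_ids})
        part = partition_markers(published_matrix)
        infer_core_span(call, part, published_matrix, ["TB9Sb"])
        assert call.span_marker_ids == [f"TD{i}" for i in range(1, 41)]

    def test_span_contains_every_retained_core_marker(self, published_matrix):
        call = self._call_from_published_table(published_matrix)
        part = partition_markers(published_matrix)
        infer_core_span(call, part, published_matrix, ["TB9Sb", "PI", "Telo2_1", "Iso3"])
        retained = set(published_matrix.present_in("Iso3"))
        assert set(call.core_ids) & retained <= set(call.span_marker_ids)

    def test_no_core_markers_rejected(self, published_matrix):
        call = CoreCall.from_flags({m: False for m in published_matrix.marker_ids})
        part = partition_markers(published_matrix)
        with pytest.raises(ValueError):
            infer_core_span(call, part, published_matrix, ["TB9Sb"])


class TestInsilicoPCR:
    def test_round_trip_and_strand_symmetry(self):
        rng = np.random.default_rng(7)
        genome = random_dna(rng, 2_000)
        fwd = genome[500:520]
        rev = revcomp(genome[700:720])
        pair = PrimerPair("m", fwd, rev, 220)
        assert insilico_pcr(pair, genome).sizes == [220]
        assert insilico_pcr(pair, revcomp(genome)).sizes == [220]

    def test_divergent_orientation_no_product(self):
        rng = np.random.default_rng(8)
        genome = random_dna(rng, 2_000)
        fwd = genome[500:520]
        rev = genome[700:720]  # same strand, not convergent
        assert insilico_pcr(PrimerPair("m", fwd, rev, 0), genome).present is False

    def test_max_size_cutoff(self):
        rng = np.random.default_rng(9)
        genome = random_dna(rng, 5_000)
        fwd = genome[100:120]
        rev = revcomp(genome[4_000:4_020])
        assert insilico_pcr(PrimerPair("m", fwd, rev, 0), genome, max_size=2_000).present is False
        assert insilico_pcr(PrimerPair("m", fwd, rev, 0), genome, max_size=4_000).present is True


class TestDesignJunctionPrimers:
    def test_unique_flank_marker_converts(self, experiment):
        pairs = experiment.classification.pairs
        assert len(pairs) == len(experiment.dmap.core_marker_ids)
        for pair in pairs:
            res = insilico_pcr(pair, experiment.genomes.b_plus)
            assert res.sizes == [pair.expected_size]
            assert insilico_pcr(pair, experiment.genomes.b_minus).present is False

    def test_primers_live_in_marker_and_straddle_junction(self, experiment):
        by_id = {m.id: m for m in experiment.dmap.map_markers}
        for pair in experiment.classification.pairs:
            band = by_id[pair.marker_id].band.sequence
            assert pair.forward in band
            site = revcomp(pair.reverse)
            assert site in band
            pos = band.index(site)
            assert pos < 112 < pos + len(site)  # straddles the LTR/flank junction
            assert pos > band.index(pair.forward)  # reverse downstream of forward

    def test_marker_shared_with_b_minus_is_unconvertible(self):
        rng = np.random.default_rng(10)
        band = random_dna(rng, 250)
        marker = TDMarker("TDx", "CRM2-ACC-250", TDBand(250, band, ["ACC"], ("+", 0, 250)))
        shared = random_dna(rng, 300) + band + random_dna(rng, 300)
        with pytest.raises(ValueError):
            design_junction_primers(marker, b_plus=shared, b_minus=shared)


def test_genotype_vector_matches_presence(experiment):
    """Junction-junction PCR reproduces the presence matrix for the
    converted markers on every derivative."""
    geno = experiment.classification.genotypes
    frame = experiment.dmap.matrix_all.to_frame()
    core = [p.marker_id for p in experiment.classification.pairs]
    assert geno.equals(frame.loc[core].astype(bool))
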