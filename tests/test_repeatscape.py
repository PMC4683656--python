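"""Synthetic repeat landscape: determinism, layout invariants, pedigree
nestedness, and read-simulator calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bcenmap.repeatscape import (
    CENTC_LEN,
    LTR_TAG_LEN,
    PedigreeNode,
    RECOGNITION,
    build_repeat_library,
    band_sequence,
    coverage_from_starts,
    derive_pedigree,
    simulate_centromere,
    simulate_chip_reads,
)
from bcenmap.sequtils import revcomp


class TestRepeatLibrary:
    def test_centc_monomer_is_156_bp(self, library):
        assert len(library.centc_monomer) == CENTC_LEN == 156

    def test_units_are_dna(self, library):
        for name, seq in library.units.items():
            assert set(seq) <= set("ACGT"), name

    def test_primer_sites_inside_5p_ltr(self, library):
        assert library.selective_annealing in library.ltr_5p
        assert library.primary_annealing in library.ltr_5p
        # the 3' LTR variant lacks them, so each insertion gives one band
        assert library.selective_annealing not in library.ltr_3p

    def test_ltr_tag_region_free_of_recognition_site(self, library):
        assert RECOGNITION not in library.ltr_5p

    def test_same_seed_reproduces_library(self, library):
        assert build_repeat_library(seed=1).units == library.units

    def test_different_seeds_differ(self, library):
        other = build_repeat_library(seed=2)
        assert any(other.units[n] != library.units[n] for n in library.units)

    def test_short_ltr_rejected(self):
        with pytest.raises(ValueError):
            build_repeat_library(seed=1, ltr_len=100)


class TestSimulateCentromere:
    def test_features_tile_sequence(self, small_layout):
        small_layout.check_tiling()

    def test_two_junctions_per_insertion(self, library):
        lay = simulate_centromere(library, 5, seed=3, backbone_bp=8_000, n_b_blocks=2)
        lay0 = simulate_centromere(library, 0, seed=3, backbone_bp=8_000, n_b_blocks=2)
        assert len(lay.planted_junctions) == len(lay0.planted_junctions) + 2 * 5

    def test_no_insertions_means_no_ltr_junctions(self, library):
        lay = simulate_centromere(library, 0, seed=3, backbone_bp=8_000, n_b_blocks=2)
        units = {f.unit for f in lay.features}
        assert "ltr_5p" not in units and lay.insertions == []

    def test_band_sequences_start_with_primer_site(self, library, small_layout):
        primer = revcomp(library.selective_annealing)
        for ins in small_layout.insertions:
            band = band_sequence(small_layout.sequence, ins)
            assert band.startswith(primer)
            assert len(band) == ins.band_size

    def test_deterministic_for_seed(self, library, small_layout):
        again = simulate_centromere(
            library, 8, seed=7, backbone_bp=8_000, n_b_blocks=2,
            band_sizes=[150, 200, 250, 300, 180, 220, 260, 340],
        )
        assert again.sequence == small_layout.sequence

    def test_cenh3_domain_inside_sequence(self, small_layout):
        s, e = small_layout.cenh3_domain
        assert 0 <= s < e <= len(small_layout.sequence)

    def test_impossible_layout_raises(self, library):
        with pytest.raises(ValueError):
            simulate_centromere(library, 40, seed=1, backbone_bp=2_000, n_b_blocks=1)


class TestPedigree:
    @pytest.fixture()
    def root(self, small_layout):
        return small_layout

    def test_zero_fractions_copy_root(self, root):
        spec = [("root", None, 0.0), ("a", "root", 0.0), ("b", "a", 0.0)]
        out = derive_pedigree(root, spec)
        assert all(d.sequence == root.sequence for d in out)

    def test_length_conservation_and_nesting(self, root):
        spec = [
            PedigreeNode("root", None, 0.0),
            PedigreeNode("d1", "root", 0.2),
            PedigreeNode("d2", "d1", 0.3),
        ]
        out = {d.name: d for d in derive_pedigree(root, spec)}
        for name, parent in [("d1", "root"), ("d2", "d1")]:
            d, p = out[name], out[parent]
            removed = sum(e - s for s, e in d.deletions)
            assert len(d.sequence) == len(p.sequence) - removed
            # retained interval nested within the parent's
            assert p.root_interval[0] <= d.root_interval[0]
            assert d.root_interval[1] <= p.root_interval[1]
            assert d.sequence in p.sequence

    def test_core_excision_removes_cenh3_domain(self, root):
        spec = [PedigreeNode("root", None, 0.0), PedigreeNode("telo", "root", 1.0)]
        telo = derive_pedigree(root, spec)[1]
        s, e = root.cenh3_domain
        assert telo.root_interval[0] >= e
        assert root.sequence[s:e] not in telo.sequence

    def test_non_tree_spec_rejected(self, root):
        with pytest.raises(ValueError):
            derive_pedigree(root, [("root", None, 0.0), ("a", "ghost", 0.1)])

    def test_out_of_bounds_deletion_rejected(self, root):
        with pytest.raises(ValueError):
            derive_pedigree(root, [("root", None, 0.0), ("a", "root", 1.5)])


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(0)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))


class TestChipReads:
    GENOME_BP = 20_000

    def test_same_seed_identical_readset(self, genome):
        a = simulate_chip_reads(genome, None, "active_chip", {}, 500, 100, seed=5)
        b = simulate_chip_reads(genome, None, "active_chip", {}, 500, 100, seed=5)
        assert np.array_equal(a.sequences, b.sequences)
        assert np.array_equal(a.source_starts, b.source_starts)

    def test_reads_drawn_from_genome(self, genome):
        rs = simulate_chip_reads(genome, None, "fragmented_control", {}, 50, 100, seed=5)
        for row, start, strand in zip(rs.sequences, rs.source_starts, rs.source_strands):
            read = row.tobytes().decode()
            src = genome[start : start + 100]
            assert read == (src if strand == 0 else revcomp(src))

    def test_uniform_when_fold_map_empty(self, genome):
        L = 100
        n = 40_000  # ~200x coverage
        rs = simulate_chip_reads(genome, None, "active_chip", {}, n, L, seed=5)
        cov = coverage_from_starts(rs.source_starts, L, len(genome))
        inner = cov[L:-L]
        assert abs(inner.mean() - n * L / (len(genome) - L + 1)) < 0.05 * inner.mean()

    @pytest.mark.parametrize("fold", [1.0, 6.0, 36.0])
    def test_fold_calibration_within_15_percent(self, genome, fold):
        """Planted enrichment is recovered as a per-base coverage ratio."""
        L = 150
        iv = (8_000, 11_000)
        weight = self.GENOME_BP + (fold - 1) * (iv[1] - iv[0])
        n = int(200 * weight / L)  # >= 200x expected background coverage
        rs = simulate_chip_reads(genome, None, "active_chip", {iv: fold}, n, L, seed=9)
        cov = coverage_from_starts(rs.source_starts, L, len(genome))
        inside = cov[iv[0] + L : iv[1] - L].mean()
        outside = np.concatenate([cov[L : iv[0] - L], cov[iv[1] + L : -L]]).mean()
        assert 0.85 * fold <= inside / outside <= 1.15 * fold

    def test_inactive_role_forces_domain_to_background(self, genome):
        L, iv = 100, (8_000, 11_000)
        rs = simulate_chip_reads(
            genome, None, "inactive_chip", {iv: 30.0}, 20_000, L, seed=9,
            cenh3_domain=iv,
        )
        cov = coverage_from_starts(rs.source_starts, L, len(genome))
        inside = cov[iv[0] + L : iv[1] - L].mean()
        outside = np.concatenate([cov[L : iv[0] - L], cov[iv[1] + L : -L]]).mean()
        assert inside / outside < 1.3

    def test_invalid_inputs_rejected(self, genome):
        with pytest.raises(ValueError):
            simulate_chip_reads(genome, None, "active_chip", {}, 0, 100, seed=1)
        with pytest.raises(ValueError):
            simulate_chip_reads(genome, None, "not_a_role", {}, 10, 100, seed=1)
        with pytest.raises(ValueError):
            simulate_chip_reads(genome, None, "active_chip", {(0, 10): -1.0}, 10, 100, seed=1)


@given(st.integers(0, 2**31 - 1))
def test_library_determinism_property(seed):
    a = build_repeat_library(seed=seed)
    b = build_repeat_library(seed=seed)
    assert a.units == b.units
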