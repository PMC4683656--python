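"""Unique-read mapping and enrichment: index correctness, retention rules
against a brute-force oracle, fold computation and junction flags."""

import numpy as np
import pytest

from bcenmap.chipmap import (
    N_BYTE,
    Placement,
    build_index,
    coverage_arrays,
    fold_enrichment,
    junction_coverage,
    map_reads,
)
from bcenmap.repeatscape import ReadSet, simulate_chip_reads
from bcenmap.sequtils import encode, random_dna, revcomp


def _readset(seqs, L):
    arr = np.vstack([encode(s) for s in seqs])
    return ReadSet(
        library_name="t", role="active_chip", sequences=arr, read_length=L, seed=0,
        source_starts=np.zeros(len(seqs), dtype=np.int64),
        source_strands=np.zeros(len(seqs), dtype=np.int8),
    )


class TestBuildIndex:
    def test_hand_enumerated_placements(self):
        idx = build_index({"r": "ACGTACGT"}, k=4)
        hits = idx.seeds[b"ACGT"]
        local = sorted(int(h) - idx.offsets[0] for h in hits)
        assert local == [0, 4]

    def test_seeds_overlapping_n_absent(self):
        idx = build_index({"r": "ACGTNACGTACG"}, k=4)
        assert all(b"N" not in key for key in idx.seeds)
        # windows overlapping the N (positions 1-4) are missing entirely
        covered = {int(h) - int(idx.offsets[0]) for hits in idx.seeds.values() for h in hits}
        assert covered == {0, 5, 6, 7, 8}

    def test_lookup_equals_brute_force_scan(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 300)
        k = 12
        idx = build_index({"r": seq}, k=k)
        for i in range(0, len(seq) - k + 1, 7):
            kmer = seq[i : i + k]
            expect = sorted(
                j for j in range(len(seq) - k + 1) if seq[j : j + k] == kmer
            )
            got = sorted(int(h) - idx.offsets[0] for h in idx.seeds[kmer.encode()])
            assert got == expect

    def test_k_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            build_index({"r": "ACGT"}, k=10)


def _oracle_map(read, cat, L, min_margin, min_identity):
    """Brute-force placement: score every position on both strands with the
    same penalized rule, retain iff unique best with margin and identity."""
    best = []
    for strand, rs in (("+", read), ("-", revcomp(read))):
        r = encode(rs)
        for g in range(len(cat) - L + 1):
            w = encode(cat[g : g + L])
            matches = int((w == r).sum())
            nonn = int((w != N_BYTE).sum())
            best.append((5 * matches - 4 * nonn, matches, nonn, g, strand))
    best.sort(reverse=True)
    top = best[0]
    if best[1][0] == top[0]:
        return None
    if top[0] - best[1][0] < min_margin:
        return None
    if top[1] < min_identity * max(top[2], 1):
        return None
    return (top[3], top[4])


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(5)
    rep = random_dna(rng, 80)
    return random_dna(rng, 300) + rep + random_dna(rng, 100) + rep + random_dna(rng, 120)


@pytest.fixture(scope="module")
def index(ref):
    return build_index({"chr": ref}, k=20)


class TestMapReads:
    L, K = 60, 20

    def test_unique_exact_read_retained_with_full_score(self, ref, index):
        read = ref[10 : 10 + self.L]
        mr = map_reads(_readset([read], self.L), index)
        (p,) = mr.placements
        assert (p.start, p.strand, p.score) == (10, "+", self.L)

    def test_repeat_interior_read_discarded(self, ref, index):
        read = ref[310 : 310 + self.L]  # wholly inside the duplicated block
        mr = map_reads(_readset([read], self.L), index)
        assert mr.placements == [] and mr.n_ambiguous == 1

    def test_reverse_strand_read_recovered(self, ref, index):
        read = revcomp(ref[40 : 40 + self.L])
        mr = map_reads(_readset([read], self.L), index)
        (p,) = mr.placements
        assert (p.start, p.strand) == (40, "-")

    def test_matches_brute_force_oracle(self, ref, index):
        rng = np.random.default_rng(11)
        starts = list(rng.integers(0, len(ref) - self.L, size=25))
        reads = []
        for s in starts:
            r = ref[s : s + self.L]
            if rng.random() < 0.5:
                r = revcomp(r)
            if rng.random() < 0.3:  # sprinkle a substitution
                i = int(rng.integers(0, self.L))
                r = r[:i] + {"A": "C", "C": "G", "G": "T", "T": "A"}[r[i]] + r[i + 1 :]
            reads.append(r)
        mr = map_reads(_readset(reads, self.L), index)
        placed = {p.read_id: (p.start, p.strand) for p in mr.placements}
        for rid, read in enumerate(reads):
            expect = _oracle_map(read, ref, self.L, 5, 0.95)
            assert placed.get(rid) == expect, f"read {rid}"

    def test_retained_scores_are_sound(self, ref, index):
        rng = np.random.default_rng(13)
        reads = [ref[int(s) : int(s) + self.L] for s in rng.integers(0, len(ref) - self.L, 20)]
        mr = map_reads(_readset(reads, self.L), index)
        for p in mr.placements:
            window = ref[p.start : p.start + self.L]
            read = reads[p.read_id] if p.strand == "+" else revcomp(reads[p.read_id])
            assert sum(a == b for a, b in zip(window, read)) == p.score

    def test_junction_read_maps_to_map_ref_repeat_read_does_not(self):
        """A read across a planted junction is unique on the minimal map;
        a read wholly inside a multi-copy repeat is discarded."""
        rng = np.random.default_rng(17)
        rep = random_dna(rng, 200)
        uniq = random_dna(rng, 200)
        marker = rep[-50:] + uniq[:100]  # junction at offset 50
        genome = rep + rep + uniq
        index = build_index({"bg": rep + rep, "map": marker}, k=self.K)
        junction_read = genome[2 * 200 - 30 : 2 * 200 - 30 + self.L]
        repeat_read = rep[20 : 20 + self.L]
        mr = map_reads(_readset([junction_read, repeat_read], self.L), index)
        placed = {p.read_id: p.ref for p in mr.placements}
        assert placed == {0: "map"}


@pytest.fixture(scope="module")
def world():
    """Source genome whose middle 300 bp exist only on the 'map' ref; the
    surrounding 200 bp are absent from both references, like the
    unassembled centromere flanking a marker."""
    rng = np.random.default_rng(23)
    source = random_dna(rng, 12_000)
    marker = source[5_000:5_300]
    bg = source[:4_800] + source[5_500:]
    index = build_index({"bg": bg, "map": marker}, k=40)
    return source, marker, index


class TestFoldEnrichment:
    L = 150


    def _run(self, world, fold, seed=31, coverage=60.0):
        source, marker, index = world
        iv = (5_000 - (self.L - 40), 5_300 + (self.L - 40))
        fold_map = {iv: fold} if fold != 1.0 else {}
        weight = len(source) + (fold - 1.0) * (iv[1] - iv[0])
        n = int(coverage * weight / self.L)
        rs = simulate_chip_reads(source, None, "active_chip", fold_map, n, self.L, seed)
        mr = map_reads(rs, index)
        table = fold_enrichment(
            {"lib": mr.placements}, index, {"m": (0, 300)},
            map_ref="map", background_refs=["bg"], read_length=self.L,
        )
        return table

    def test_flat_library_fold_near_one(self, world):
        t = self._run(world, 1.0)
        assert 0.8 <= float(t.fold.loc["m", "lib"]) <= 1.2

    @pytest.mark.parametrize("fold", [6.0, 36.0])
    def test_planted_fold_recovered_within_15_percent(self, world, fold):
        t = self._run(world, fold)
        assert 0.85 * fold <= float(t.fold.loc["m", "lib"]) <= 1.15 * fold

    def test_doubling_reads_leaves_fold_unchanged(self, world):
        source, marker, index = world
        rs = simulate_chip_reads(source, None, "active_chip", {}, 2_000, self.L, 7)
        mr = map_reads(rs, index)
        args = dict(map_ref="map", background_refs=["bg"], read_length=self.L)
        t1 = fold_enrichment({"lib": mr.placements}, index, {"m": (0, 300)}, **args)
        doubled = mr.placements + [
            Placement(p.read_id + 10**6, p.ref, p.start, p.strand, p.score, p.margin)
            for p in mr.placements
        ]
        t2 = fold_enrichment({"lib": doubled}, index, {"m": (0, 300)}, **args)
        assert float(t1.fold.loc["m", "lib"]) == pytest.approx(float(t2.fold.loc["m", "lib"]))

    def test_zero_genome_coverage_rejected(self, world):
        _, _, index = world
        p = [Placement(0, "map", 0, "+", 100, 100)]
        with pytest.raises(ValueError):
            fold_enrichment(
                {"lib": p}, index, {"m": (0, 300)},
                map_ref="map", background_refs=["bg"], read_length=self.L,
            )


class TestJunctionCoverage:
    def _place(self, starts, L=50):
        return [Placement(i, "map", s, "+", L, L) for i, s in enumerate(starts)]

    def test_flags_match_brute_force_depth(self):
        L = 50
        intervals = {"m": (10, 150)}
        junctions = {"m": 80}
        placements = self._place([0, 40, 60, 90, 100], L)
        flags = junction_coverage(placements, intervals, junctions, read_length=L, map_ref="map")
        depth = np.zeros(300, int)
        for p in placements:
            depth[max(0, p.start) : p.start + L] += 1
        expect = bool((depth[10:150] >= 1).all()) and any(
            p.start <= 70 and p.start + L >= 90 for p in placements
        )
        assert flags["m"] == expect

    def test_ltr_only_coverage_fails(self):
        L = 50
        intervals = {"m": (0, 140)}
        junctions = {"m": 112}
        placements = self._place([0, 30, 60], L)  # covers 0..110 only
        flags = junction_coverage(placements, intervals, junctions, read_length=L, map_ref="map")
        assert flags["m"] is False

    def test_saturated_coverage_passes(self):
        L = 50
        intervals = {"m": (0, 140)}
        junctions = {"m": 112}
        placements = self._place(list(range(0, 95, 5)), L)
        flags = junction_coverage(placements, intervals, junctions, read_length=L, map_ref="map")
        assert flags["m"] is True

    def test_junction_outside_marker_rejected(self):
        with pytest.raises(ValueError):
            junction_coverage([], {"m": (0, 100)}, {"m": 150}, read_length=50, map_ref="map")


def test_coverage_arrays_against_manual_piles(small_layout):
    index = build_index({"c": small_layout.sequence[:2_000]}, k=20)
    placements = [Placement(0, "c", 100, "+", 50, 50), Placement(1, "c", 120, "-", 50, 50)]
    cov = coverage_arrays(placements, index, read_length=50)["c"]
    assert cov[100] == 1 and cov[125] == 2 and cov[180] == 0
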