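#!/usr/bin/env python
"""Stage 1 -- simulate the study system.

Builds the repeat library and genomes: a B chromosome whose ~60-kb
centromere carries 40 CRM2-like insertions (each with a planted
restriction site so transposon display recovers one band of a prescribed
size), two arms carrying 21 further insertions, a B-less background
genome with its own satellite array and two shared CRM2 copies, and the
centromere-only miniB.  Writes FASTA/BED under results/genomes/.

Usage: python analysis/01_simulate_genomes.py [--seed 1]
"""

import argparse
from pathlib import Path

from bcenmap.pipeline import SimConfig, build_genomes
from bcenmap.sequtils import write_bed, write_fasta


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/genomes"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig()
    g = build_genomes(args.seed, cfg)
    write_fasta(
        {
            "B_chromosome": g.bchrom,
            "B73_chr1": g.background,
            "miniB": g.minib,
        },
        out / "genomes.fasta",
    )
    write_bed(
        [("B_chromosome", f.start + g.cen_offset, f.end + g.cen_offset, f.unit, f.depth)
         for f in g.cen_layout.features],
        out / "centromere_features.bed",
    )
    write_bed(
        [("B_chromosome", i.band_start + g.cen_offset, i.band_end + g.cen_offset,
          f"cen_band_{i.index}", i.band_size, i.orientation)
         for i in g.cen_layout.insertions]
        + [("B_chromosome", i.band_start, i.band_end, f"arm_band_{i.index}",
            i.band_size, i.orientation) for i in g.arm_insertions],
        out / "planted_bands.bed",
    )

    print(f"seed {args.seed}")
    print(f"  B chromosome: {len(g.bchrom):,} bp "
          f"(centromere {len(g.cen_layout.sequence):,} bp at offset {g.cen_offset:,})")
    print(f"  background:   {len(g.background):,} bp; miniB: {len(g.minib):,} bp")
    print(f"  planted insertions: {len(g.cen_layout.insertions)} centromeric, "
          f"{len(g.arm_insertions)} on the arms")
    print(f"  junctions recorded in the centromere: {len(g.cen_layout.planted_junctions)}")
    print(f"wrote {out}/genomes.fasta, centromere_features.bed, planted_bands.bed")


if __name__ == "__main__":
    main()
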