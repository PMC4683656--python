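#!/usr/bin/env python
"""Stage 5 -- core-marker classification and junction-junction PCR.

Applies the strict multi-library rule (enriched in every active
replicate, at most twofold in the inactive replicates, zero unique
control coverage, junction-spanning coverage), infers the core-domain
span via the smallest fully functional derivative, converts the core
markers to junction-junction PCR pairs and genotypes every derivative.

Usage: python analysis/05_core_classification.py [--seed 1]
"""

import argparse
from pathlib import Path

from bcenmap.pipeline import (
    build_genomes,
    run_chip_stage,
    run_classification_stage,
    run_deletion_map_stage,
    run_td_stage,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/classification"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    g = build_genomes(args.seed)
    disp = run_td_stage(g)
    dmap = run_deletion_map_stage(g, disp.centromeric_markers)
    chip = run_chip_stage(g, dmap, args.seed)
    cls = run_classification_stage(g, dmap, chip)

    with open(out / "core_calls.tsv", "w") as fh:
        fh.write("marker\tis_core\tactive_enrichment\tinactive_ceiling\tcontrol_zero\tjunction_covered\n")
        for mid, is_core in cls.call.calls.items():
            r = cls.call.reasons[mid]
            fh.write(f"{mid}\t{int(is_core)}\t" + "\t".join(
                str(int(r[k])) for k in
                ["active_enrichment", "inactive_ceiling", "control_zero", "junction_covered"]
            ) + "\n")
    cls.genotypes.astype(int).to_csv(out / "pcr_genotypes.tsv", sep="\t")
    with open(out / "primer_pairs.tsv", "w") as fh:
        fh.write("marker\tforward\treverse\texpected_size\n")
        for p in cls.pairs:
            fh.write(f"{p.marker_id}\t{p.forward}\t{p.reverse}\t{p.expected_size}\n")

    print(f"core markers called ({len(cls.call.core_ids)}): {', '.join(cls.call.core_ids)}")
    print(f"planted CENH3 occupancy:    {', '.join(dmap.core_marker_ids)}")
    if cls.call.core_span:
        print(f"core-domain span (smallest functional derivative rule): "
              f"{cls.call.core_span[0]}-{cls.call.core_span[1]} "
              f"({len(cls.call.span_marker_ids)} markers)")
    print("\njunction-junction PCR genotypes (1 = amplifies):")
    print(cls.genotypes.astype(int).to_string())
    print(f"wrote {out}/core_calls.tsv, pcr_genotypes.tsv, primer_pairs.tsv")


if __name__ == "__main__":
    main()
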