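#!/usr/bin/env python
"""Generate the mirror-of-study synthetic dataset and write its raw tables.

Writes under results/data/: ECAR/OCR plate TSVs with schedule and cell-count
sidecars, the expression study (series-matrix-like TSV), the gene-set
collection (GMT), the qPCR/ROS/lactate/proliferation/viability tables, and
the ground-truth JSON.
"""

import argparse
from pathlib import Path

from metaboswitch.flux import write_plate_tsv
from metaboswitch.screen import write_gmt, write_study_tsv
from metaboswitch.synthetic import generate_mirror_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    data = generate_mirror_dataset(args.seed)
    for plate, tag in ((data.ecar_plate, "ecar"), (data.ocr_plate, "ocr")):
        write_plate_tsv(plate.traces, out / f"{tag}_plate.tsv",
                        out / f"{tag}_schedule.tsv", out / f"{tag}_cells.tsv")
        with open(out / f"{tag}_conditions.tsv", "w") as fh:
            fh.write("well\tcondition\n")
            for w, c in plate.condition_of.items():
                fh.write(f"{w}\t{c}\n")
    write_study_tsv(data.study, out / "expression_study.tsv")
    write_gmt(data.gene_sets, out / "gene_sets.gmt")
    for name, df in (("qpcr", data.qpcr), ("ros", data.ros),
                     ("lactate", data.lactate), ("counts", data.counts),
                     ("viability", data.viability)):
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    data.truth.save(out / "ground_truth.json")
    print(f"wrote mirror dataset (seed {args.seed}) to {out}/:")
    print(f"  {len(data.ecar_plate.traces)} ECAR wells, "
          f"{len(data.ocr_plate.traces)} OCR wells")
    print(f"  expression: {data.study.matrix.shape[0]} genes x "
          f"{data.study.matrix.shape[1]} samples")
    print(f"  gene sets: {len(data.gene_sets)} ({sum(len(s.members) for s in data.gene_sets)} memberships)")


if __name__ == "__main__":
    main()
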