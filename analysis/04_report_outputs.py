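"""Assemble the deterministic report: clustered heat-map tables + manifest.

Builds hierarchically clustered orderings for (a) the selected
discriminatory OTUs x samples, (b) the selected brain features x samples,
and (c) the top-pair S_Combined matrix, then writes a run manifest with
input digests so a rerun can be verified byte-for-byte.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from gutbrain import align_cohort, cluster_heatmap, log2_transform, write_manifest, zscale
from gutbrain.preprocess import read_brain_table, read_labels, read_otu_table


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--distance", choices=("euclidean", "correlation"), default="euclidean")
    ap.add_argument("--linkage", choices=("average", "complete"), default="average")
    args = ap.parse_args(argv)

    cohort_dir = args.outdir / "cohort"
    otu = read_otu_table(cohort_dir / "otu.tsv")
    brain = read_brain_table(cohort_dir / "brain.csv")
    labels = read_labels(cohort_dir / "labels.csv")
    otu, brain, labels, _ = align_cohort(otu, brain, labels)

    cv = json.loads((args.outdir / "cv_report.json").read_text())
    outputs = []
    for name, table in (("otu", log2_transform(otu)), ("brain", zscale(brain))):
        sel = cv[name]["selected_features"]
        cm = cluster_heatmap(table.values[sel].T, args.distance, args.linkage)
        path = args.outdir / f"heatmap_{name}.csv"
        cm.to_csv(path)
        outputs.append(path)
        print(f"heatmap_{name}: rows {list(cm.row_order)[:3]}... cols {len(cm.col_order)}")

    top = pd.read_csv(args.outdir / "top_pairs.csv")
    mat = top.pivot_table(index="otu_id", columns="brain_feature_id",
                          values="s_combined", fill_value=0.0)
    if mat.shape[0] >= 2 and mat.shape[1] >= 2:
        cm = cluster_heatmap(mat, args.distance, args.linkage)
        path = args.outdir / "pairs_heatmap.csv"
        cm.to_csv(path)
        outputs.append(path)

    outputs.append(args.outdir / "circos_links.tsv")
    config = {
        "seed": args.seed,
        "ntree": cv["ntree"],
        "top_k": cv["top_k"],
        "distance": args.distance,
        "linkage": args.linkage,
    }
    inputs = [cohort_dir / "otu.tsv", cohort_dir / "brain.csv", cohort_dir / "labels.csv"]
    write_manifest(config, inputs, outputs, args.outdir / "manifest.json")
    print(f"manifest: {args.outdir}/manifest.json ({len(outputs)} outputs)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
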