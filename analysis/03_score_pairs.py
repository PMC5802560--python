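"""Rank-product scoring of every (OTU, brain feature) pair.

Fits the two diet classifiers and one regression forest per brain feature
(all OTUs as predictors), combines the three rank scores into S_Combined,
keeps the top 27 pairs, grows the three downstream diet models (OTU-only,
brain-only, combined) by forward selection until 100% LOOCV accuracy, and
applies the 0.84 score cutoff.

Outputs: pairs.csv (all pairs), top_pairs.csv, circos_links.tsv (top
pairs), forward_selection.json, thresholded_pairs.csv, plus how many
planted links landed in the top 27 when ground truth is available.
"""

import argparse
import json
import sys
from pathlib import Path

from gutbrain import (
    ForestConfig,
    align_cohort,
    apply_threshold,
    forward_select,
    log2_transform,
    score_cohort,
    select_top_pairs,
    zscale,
)
from gutbrain.pair_score import write_circos_links
from gutbrain.preprocess import read_brain_table, read_labels, read_otu_table


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--ntree-class", type=int, default=500,
                    help="trees per classification forest (study scale: 16000)")
    ap.add_argument("--ntree-reg", type=int, default=300,
                    help="trees per regression forest (study scale: 4000)")
    ap.add_argument("--top-pairs", type=int, default=27)
    ap.add_argument("--threshold", type=float, default=0.84)
    args = ap.parse_args(argv)

    cohort_dir = args.outdir / "cohort"
    otu = read_otu_table(cohort_dir / "otu.tsv")
    brain = read_brain_table(cohort_dir / "brain.csv")
    labels = read_labels(cohort_dir / "labels.csv")
    otu, brain, labels, _ = align_cohort(otu, brain, labels)
    otu_l2, brain_z = log2_transform(otu), zscale(brain)

    res = score_cohort(
        otu_l2, brain_z, labels,
        ForestConfig(ntree=args.ntree_class, seed=args.seed),
        ForestConfig(ntree=args.ntree_reg, seed=args.seed),
    )
    res.pairs.to_csv(args.outdir / "pairs.csv", index=False)
    top = select_top_pairs(res.pairs, args.top_pairs)
    top.to_csv(args.outdir / "top_pairs.csv", index=False)
    write_circos_links(top, args.outdir / "circos_links.tsv")
    print(f"scored {len(res.pairs)} pairs; top pair "
          f"{top.iloc[0]['otu_id']} -> {top.iloc[0]['brain_feature_id']} "
          f"(S_Combined = {top.iloc[0]['s_combined']:.3f})")

    truth_path = cohort_dir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        planted = {(o, b) for o, b, _ in truth["linked_pairs"]}
        found = {(r.otu_id, r.brain_feature_id) for r in top.itertuples()}
        print(f"planted links recovered in top {args.top_pairs}: "
              f"{len(planted & found)}/{len(planted)}")

    fwd_report = {}
    cfg = ForestConfig(ntree=args.ntree_class, seed=args.seed)
    for mode in ("otu", "brain", "both"):
        fs = forward_select(top, otu_l2.values, brain_z.values, labels.labels, cfg,
                            target_accuracy=1.0, mode=mode)
        fwd_report[mode] = {
            "n_pairs_used": len(fs.selected),
            "reached_100pct": fs.reached,
            "loocv_accuracy": fs.report.accuracy,
            "accuracy_path": list(fs.accuracies),
        }
        print(f"forward selection [{mode}]: {len(fs.selected)} pair(s), "
              f"LOOCV accuracy {fs.report.accuracy:.0%}"
              + ("" if fs.reached else " (target not reached)"))
    (args.outdir / "forward_selection.json").write_text(json.dumps(fwd_report, indent=1))

    kept = apply_threshold(res.pairs, args.threshold)
    kept.to_csv(args.outdir / "thresholded_pairs.csv", index=False)
    print(f"pairs with S_Combined >= {args.threshold}: {len(kept)}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
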