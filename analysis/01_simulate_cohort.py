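"""Generate the synthetic study cohort and write it to disk.

Emulates the emulated study design: 20 samples (4 diets x 5 animals), 100
OTUs with 9 diet-discriminative ones, 40 brain features (10 ROIs x
{fa, rd, ad, tr}) of which 9 are linked to planted OTUs. Writes the OTU
TSV, the long-form brain CSV, the diet labels and the planted ground
truth under <outdir>/cohort/.
"""

import argparse
import sys
from pathlib import Path

from gutbrain import CohortDesign, generate_cohort, write_cohort


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--paired", action="store_true",
                    help="also emit pre-diet baseline fecal samples")
    args = ap.parse_args(argv)

    design = CohortDesign(seed=args.seed, paired_sampling=args.paired)
    cohort = generate_cohort(design)
    paths = write_cohort(cohort, args.outdir / "cohort")

    print(f"cohort: {len(cohort.otu.sample_ids)} samples, "
          f"{len(cohort.otu.otu_ids)} OTUs, {len(cohort.brain.feature_ids)} brain features")
    print(f"planted: {len(cohort.truth.signal_otu_ids)} signal OTUs, "
          f"{len(cohort.truth.linked_pairs)} OTU->brain links")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
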