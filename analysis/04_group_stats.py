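#!/usr/bin/env python
"""Run the gated group-statistics battery on the connectivity summaries.

Per band: Mann-Whitney on whole-brain PLI (patients vs controls); where
significant, per-ROI permutation tests on node strengths and Mann-Whitney
tests per resting-state network; where a network differs, Spearman
correlations of its PLI with EDSS, cognition and volumes per group, and
effect-modification regressions with the volumes as modifiers.  The table
is written to the study directory and copied to results/tests.tsv.
"""

import argparse
import shutil
from pathlib import Path

from megconn.pipeline import StudyConfig, stage_stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=ROOT / "scratch/study")
    parser.add_argument("--n-perm", type=int, default=None)
    args = parser.parse_args()

    config = StudyConfig.from_yaml(args.out / "config_resolved.yaml")
    if args.n_perm is not None:
        config.stats.n_perm = args.n_perm
    tests = stage_stats(config, args.out)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    shutil.copy(args.out / "tests.tsv", results / "tests.tsv")

    mw = tests.query("test == 'mann_whitney'")
    print("group comparisons (Mann-Whitney):")
    print(mw[["band", "scope", "statistic", "p", "direction"]]
          .to_string(index=False))
    sig_roi = tests.query("test == 'permutation_t' and p < 0.05")
    print(f"\nROIs with significant permutation tests: "
          f"{sig_roi.groupby('band').size().to_dict()}")
    sp = tests.query("test == 'spearman' and p < 0.05")
    if len(sp):
        print("\nsignificant covariate correlations:")
        print(sp[["band", "scope", "group", "covariate", "statistic", "p"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
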