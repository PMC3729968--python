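#!/usr/bin/env python
"""Reconstruct ROI time series from the simulated sensor recordings.

For every subject: broadband (0.5-48 Hz) data covariance, SAM-style scalar
beamformer weights with unit gain at each of the 390 atlas voxels, linear
projection of the sensor data through the weights, and selection of the
maximum-power voxel per ROI and frequency band.  Writes roi_series.h5 into
the study directory produced by 01_simulate_cohort.py.
"""

import argparse
from pathlib import Path

from megconn.pipeline import StudyConfig, stage_beamform

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=ROOT / "scratch/study")
    args = parser.parse_args()

    config = StudyConfig.from_yaml(args.out / "config_resolved.yaml")
    print(f"beamforming {args.out} "
          f"(reg_fraction={config.beamformer.reg_fraction})")
    stage_beamform(config, args.out)
    tail = [ln for ln in (args.out / "run_log.txt").read_text().splitlines()
            if ln.startswith("beamform:")]
    print(f"done: {len(tail)} subjects; last log line:\n  {tail[-1]}")


if __name__ == "__main__":
    main()
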