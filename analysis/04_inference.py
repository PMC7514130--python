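#!/usr/bin/env python
"""Group inference: channel-wise t-tests with FDR and LOOCV classification.

For each task phase, patients and controls are compared channel by
channel (pooled-variance t, Benjamini-Hochberg across the 21 channels)
and a leave-one-out cross-validated linear model predicts the group
label from all channels' entropies; ROC/AUC summarize the out-of-sample
predictions.  Tables land under results/.
"""

import argparse
from pathlib import Path

from nirsentropy.io import read_tidy_table
from nirsentropy.pipeline import PipelineConfig, infer_stage, write_manifest


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    for name in ("null", "effect"):
        out = args.out_dir / f"inference_{name}"
        infer_stage(args.scratch / name / "hb", cfg, out)
        write_manifest(cfg, out)
        summary = read_tidy_table(out / "summary.tsv")
        print(f"--- {name} cohort ---")
        print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
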