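#!/usr/bin/env python
"""Monte-Carlo operating characteristics of the whole pipeline.

Repeats the simulate -> preprocess -> entropy -> inference chain over
many cohorts to measure (a) calibration under the null: held-out AUC
centred on 0.5, channel-wise type-I error near the nominal 5%, and
FDR false positives below the control level; and (b) power with the
complexity effect calibrated to Cohen's d ~ 1.5 on 3 of 21 channels.
A compact summary table goes to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nirsentropy.calibration import COMPLEXITY_EFFECT_D15, monte_carlo
from nirsentropy.io import write_tidy_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-null", type=int, default=30)
    ap.add_argument("--n-effect", type=int, default=30)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    base = (args.seed * 10_000) % 1_000_000
    null = monte_carlo(args.n_null, effect=0.0, base_seed=base)
    eff = monte_carlo(args.n_effect, effect=COMPLEXITY_EFFECT_D15,
                      base_seed=base + args.n_null)
    rows = [
        {"condition": "null", "n_cohorts": args.n_null,
         "mean_auc": null["auc"].mean(), "median_auc": null["auc"].median(),
         "uncorrected_rejection_rate": null["uncorrected_rate_null_channels"].mean(),
         "fdr_false_positive_rate": null["fdr_false_positive_rate"].mean(),
         "mean_d_affected": float("nan"),
         "median_true_detected": float("nan")},
        {"condition": "effect_d1.5", "n_cohorts": args.n_effect,
         "mean_auc": eff["auc"].mean(), "median_auc": eff["auc"].median(),
         "uncorrected_rejection_rate": eff["uncorrected_rate_null_channels"].mean(),
         "fdr_false_positive_rate": eff["fdr_false_positive_rate"].mean(),
         "mean_d_affected": eff["mean_d_affected"].mean(),
         "median_true_detected": eff["n_true_detected_fdr"].median()},
    ]
    table = pd.DataFrame(rows)
    write_tidy_table(table, args.out_dir / "operating_characteristics.tsv")
    print(table.to_string(index=False))
    print(
        f"\nNull cohorts: held-out AUC centred near 0.5 and FDR false positives "
        f"<= 5% indicate a calibrated pipeline; effect cohorts "
        f"(complexity_effect={COMPLEXITY_EFFECT_D15}) show the classifier and "
        f"channel tests recovering the injected difference."
    )


if __name__ == "__main__":
    main()
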