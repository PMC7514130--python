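"""Operating characteristics of the pipeline on simulated cohorts.

Runs many synthetic cohorts end to end (generation, preprocessing,
entropy, channel tests, LOOCV classification) to measure:

* null calibration — with no group difference, the held-out AUC should
  average 0.5, uncorrected channel rejections should occur at the nominal
  rate, and FDR-corrected false positives should stay below the control
  level;
* power — with the complexity effect calibrated so affected channels show
  a pooled Cohen's d around 1.5, the classifier should discriminate
  (median AUC well above chance) and the FDR-corrected channel tests
  should recover affected channels.

Channels of one subject share that subject's latent blend weight, so
channel-wise test outcomes are positively correlated within a cohort;
aggregate rates are therefore summarized with per-cohort (cluster-level)
dispersion, not a pooled binomial.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .entropy import SampEnParams, compute_complexity_table
from .inference import channelwise_ttest, loocv_linear_classifier
from .preprocess import PreprocessParams, preprocess_cohort
from .synthetic import SyntheticCohortConfig, generate_cohort

#: complexity_effect value empirically calibrated (see
#: ``calibrate_complexity_effect``) so that the affected channels show a
#: pooled Cohen's d of about 1.5 on post-pipeline Sample Entropy.
COMPLEXITY_EFFECT_D15 = 0.42


def _pooled_cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    sp = np.sqrt(
        ((len(a) - 1) * a.std(ddof=1) ** 2 + (len(b) - 1) * b.std(ddof=1) ** 2)
        / (len(a) + len(b) - 2)
    )
    return float((a.mean() - b.mean()) / sp)


def run_cohort(
    seed: int,
    effect: float = 0.0,
    phase: str = "CDT",
    metric: str = "sampen",
    tau: int = 1,
    base_config: SyntheticCohortConfig | None = None,
    preprocess_params: PreprocessParams = PreprocessParams(),
    sampen_params: SampEnParams = SampEnParams(),
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    solver: str = "ridge",
    ridge_lambda: float = 2.0,
) -> dict:
    """Simulate, preprocess and analyze one cohort; return summary scalars."""
    cfg = base_config or SyntheticCohortConfig()
    cfg = dataclasses.replace(cfg, seed=seed, complexity_effect=effect)
    recordings, truth = generate_cohort(cfg)
    cohort = preprocess_cohort(recordings, preprocess_params)
    table = compute_complexity_table(
        cohort, phase, metric=metric, params=sampen_params, tau=tau
    )
    stats = channelwise_ttest(table, alpha=alpha, fdr_q=fdr_q)
    groups = table.groups.loc[table.values.index].to_numpy()
    clf = loocv_linear_classifier(
        table.values.to_numpy(), groups, solver=solver, ridge_lambda=ridge_lambda
    )
    affected = set(truth.affected_channels)
    fdr_channels = set(stats.loc[stats["sig_fdr"], "channel"])
    d_affected = [
        _pooled_cohens_d(
            table.values.loc[groups == 1, ch].dropna().to_numpy(),
            table.values.loc[groups == 0, ch].dropna().to_numpy(),
        )
        for ch in sorted(affected)
    ]
    n_ch = table.values.shape[1]
    n_null_ch = n_ch - (len(affected) if effect != 0 else 0)
    null_ch = (
        set(range(n_ch)) - affected if effect != 0 else set(range(n_ch))
    )
    return {
        "seed": seed,
        "effect": effect,
        "auc": clf.auc,
        "n_sig_uncorrected": int(stats["sig_uncorrected"].sum()),
        "n_sig_fdr": int(stats["sig_fdr"].sum()),
        "uncorrected_rate_null_channels": float(
            stats.loc[stats["channel"].isin(null_ch), "sig_uncorrected"].sum()
        )
        / n_null_ch,
        "fdr_false_positive_rate": len(fdr_channels & null_ch) / n_null_ch,
        "n_true_detected_fdr": len(fdr_channels & affected),
        "mean_d_affected": float(np.mean(d_affected)),
        "n_missing": table.n_missing,
    }


def monte_carlo(
    n_cohorts: int,
    effect: float,
    base_seed: int,
    **kwargs,
) -> pd.DataFrame:
    """Run ``n_cohorts`` independent cohorts with consecutive seeds."""
    rows = [
        run_cohort(seed=base_seed + i, effect=effect, **kwargs)
        for i in range(n_cohorts)
    ]
    return pd.DataFrame(rows)


def calibrate_complexity_effect(
    target_d: float = 1.5,
    candidate_effects=(0.2, 0.3, 0.4, 0.5),
    n_cohorts: int = 4,
    base_seed: int = 0,
    **kwargs,
) -> float:
    """Interpolate the complexity_effect giving a target post-pipeline d.

    Simulates a few cohorts per candidate effect, measures the mean
    pooled Cohen's d on affected channels, and linearly interpolates to
    the target.  Used once to fix ``COMPLEXITY_EFFECT_D15``.
    """
    effects = np.asarray(candidate_effects, float)
    ds = np.array(
        [
            monte_carlo(n_cohorts, e, base_seed, **kwargs)["mean_d_affected"].mean()
            for e in effects
        ]
    )
    if not (ds.min() <= target_d <= ds.max()):
        raise ValueError(
            f"target d={target_d} outside measured range {ds.min():.2f}-{ds.max():.2f}"
        )
    return float(np.interp(target_d, ds, effects))
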