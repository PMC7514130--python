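"""End-to-end pipeline stages and configuration.

Each stage function reads/writes the package's own formats so a full
analysis is reproducible from one config and one seed:

    simulate -> preprocess -> complexity -> infer

``full_run`` chains them and writes a run manifest (config, seed, stage
order, library versions) alongside the result tables.  Outputs are
deterministic given the seed: the same config produces byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .entropy import SampEnParams, compute_complexity_table
from .inference import DEFAULT_METRIC_MAP, run_full_inference
from .io import (
    read_hemoglobin_text,
    read_recording_text,
    write_ground_truth,
    write_hemoglobin_text,
    write_recording_text,
    write_tidy_table,
)
from .preprocess import PreprocessParams, preprocess_cohort
from .synthetic import SyntheticCohortConfig, generate_cohort


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    cohort: SyntheticCohortConfig = SyntheticCohortConfig()
    preprocess: PreprocessParams = PreprocessParams()
    sampen: SampEnParams = SampEnParams()
    metric_map: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_METRIC_MAP)
    )
    alpha: float = 0.05
    fdr_q: float = 0.05
    solver: str = "ridge"
    ridge_lambda: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.cohort.seed != self.seed:
            object.__setattr__(
                self, "cohort", dataclasses.replace(self.cohort, seed=self.seed)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["phase_plan"] = [list(p) for p in d["cohort"]["phase_plan"]]
        d["metric_map"] = {k: list(v) for k, v in self.metric_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = dict(d.pop("cohort"))
        cohort["phase_plan"] = tuple((str(l), float(s)) for l, s in cohort["phase_plan"])
        for key in ("affected_channels",):
            cohort[key] = tuple(cohort[key])
        cohort["physio_amplitudes"] = tuple(cohort["physio_amplitudes"])
        d["cohort"] = SyntheticCohortConfig(**cohort)
        d["preprocess"] = PreprocessParams(**d.pop("preprocess"))
        d["sampen"] = SampEnParams(**d.pop("sampen"))
        d["metric_map"] = {k: (str(m), int(t)) for k, (m, t) in d.pop("metric_map").items()}
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def simulate(config: PipelineConfig, out_dir) -> list[Path]:
    """Generate the synthetic cohort and write one text recording per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings, truth = generate_cohort(config.cohort)
    paths = [
        write_recording_text(rec, out_dir / f"{rec.subject_id}_raw.tsv")
        for rec in recordings
    ]
    write_ground_truth(truth, out_dir / "ground_truth.json")
    return paths


def preprocess_stage(in_dir, config: PipelineConfig, out_dir) -> list[Path]:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = [read_recording_text(p) for p in sorted(in_dir.glob("*_raw.tsv"))]
    if not raw:
        raise FileNotFoundError(f"no *_raw.tsv recordings in {in_dir}")
    cohort = preprocess_cohort(raw, config.preprocess)
    return [
        write_hemoglobin_text(hb, out_dir / f"{hb.subject_id}_hb.tsv")
        for hb in cohort
    ]


def complexity_stage(in_dir, config: PipelineConfig, out_dir) -> list[Path]:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = [read_hemoglobin_text(p) for p in sorted(in_dir.glob("*_hb.tsv"))]
    if not cohort:
        raise FileNotFoundError(f"no *_hb.tsv recordings in {in_dir}")
    if not all(hb.cbsi_applied for hb in cohort):
        raise ValueError(
            "stage-order violation: complexity requires CBSI-corrected input"
        )
    paths = []
    for phase, (metric, tau) in config.metric_map.items():
        table = compute_complexity_table(
            cohort, phase, metric=metric, params=config.sampen, tau=tau
        )
        paths.append(
            write_tidy_table(table.to_tidy(), out_dir / f"complexity_{phase}.tsv")
        )
    return paths


def infer_stage(in_dir, config: PipelineConfig, out_dir) -> dict[str, Path]:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = [read_hemoglobin_text(p) for p in sorted(in_dir.glob("*_hb.tsv"))]
    result = run_full_inference(
        cohort,
        metric_map=config.metric_map,
        params=config.sampen,
        alpha=config.alpha,
        fdr_q=config.fdr_q,
        solver=config.solver,
        ridge_lambda=config.ridge_lambda,
    )
    paths = {}
    for phase, pi in result.phases.items():
        paths[f"stats_{phase}"] = write_tidy_table(
            pi.channel_stats, out_dir / f"channel_stats_{phase}.tsv"
        )
        pred = pd.DataFrame(
            {
                "subject_id": pi.classifier.subject_ids,
                "label": pi.classifier.labels,
                "prediction": pi.classifier.predictions,
            }
        )
        paths[f"predictions_{phase}"] = write_tidy_table(
            pred, out_dir / f"predictions_{phase}.tsv"
        )
        roc = pd.DataFrame(
            {
                "threshold": pi.classifier.roc.thresholds,
                "fpr": pi.classifier.roc.fpr,
                "tpr": pi.classifier.roc.tpr,
            }
        )
        paths[f"roc_{phase}"] = write_tidy_table(roc, out_dir / f"roc_{phase}.tsv")
    paths["summary"] = write_tidy_table(result.summary, out_dir / "summary.tsv")
    return paths


STAGE_ORDER = ("simulate", "preprocess", "complexity", "infer")


def write_manifest(config: PipelineConfig, out_dir) -> Path:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_order": list(STAGE_ORDER),
        "versions": {
            "nirsentropy": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def full_run(config: PipelineConfig, out_dir) -> dict:
    """Run all stages into ``out_dir`` subdirectories; returns output paths."""
    out_dir = Path(out_dir)
    raw_dir = out_dir / "raw"
    hb_dir = out_dir / "hemoglobin"
    res_dir = out_dir / "results"
    simulate(config, raw_dir)
    preprocess_stage(raw_dir, config, hb_dir)
    complexity_paths = complexity_stage(hb_dir, config, res_dir)
    infer_paths = infer_stage(hb_dir, config, res_dir)
    manifest = write_manifest(config, out_dir)
    return {"complexity": complexity_paths, "inference": infer_paths,
            "manifest": manifest}
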