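"""End-to-end run: cohort -> responder labels -> prediction grid -> report.

The pipeline is a pure function of (inputs, configuration, seed): outputs
are a labels CSV, the full grid CSV (with the frozen hyperparameters in a
header comment), a best-models JSON, a plain-text summary, and a log with
per-stage timing. Percentages are printed rounded to integers in the
summary but stored at full precision in the CSVs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import load_cohort, load_study_cohort, summarize_cohort
from .errors import RehabPredictError
from .labeling import SRDThresholds, label_cohort, responder_counts
from .prediction import (
    DEFAULT_FEATURE_SETS,
    MODEL_FAMILIES,
    best_models,
    run_grid,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``cohort_path`` may be None to use the bundled study cohort.
    ``metrics_path`` optionally points to a per-dataset table of the ten
    normalized digital health metrics (enables feature set 5).
    """

    out_dir: str = "results"
    cohort_path: str | None = None
    metrics_path: str | None = None
    srd: SRDThresholds = field(default_factory=SRDThresholds)
    feature_sets: tuple = DEFAULT_FEATURE_SETS
    families: tuple = MODEL_FAMILIES
    outcomes: tuple = ("arat", "bbt", "nhpt")
    nonresponder_id: str = "02-right"
    seed: int = 17


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write the output directory; returns its path.

    Any stage error aborts before partial outputs are written.
    """
    t0 = time.perf_counter()
    log: list[str] = []

    def stage(name: str) -> None:
        log.append(f"[{time.perf_counter() - t0:8.3f}s] {name}")

    stage("load cohort")
    if config.cohort_path is None:
        cohort = load_study_cohort()
    else:
        if not Path(config.cohort_path).exists():
            raise RehabPredictError(
                f"stage load-cohort: missing cohort file {config.cohort_path}")
        cohort = load_cohort(config.cohort_path)
    metric_table = None
    if config.metrics_path is not None:
        if not Path(config.metrics_path).exists():
            raise RehabPredictError(
                f"stage load-metrics: missing metric table {config.metrics_path}")
        metric_table = pd.read_csv(config.metrics_path, index_col="dataset_id")

    stage("responder labeling")
    labels = label_cohort(cohort, config.srd)
    counts = responder_counts(labels)

    stage("prediction grid")
    grid = run_grid(cohort, labels,
                    feature_sets=config.feature_sets,
                    families=config.families,
                    outcomes=config.outcomes,
                    metric_table=metric_table,
                    nonresponder_id=config.nonresponder_id,
                    seed=config.seed)
    best = best_models(grid)
    summary = summarize_cohort(cohort)
    stage("write outputs")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# rehabpredict {__version__}; seed={config.seed}; "
              f"hyperparameters={grid.hyperparameters}\n")
    labels.to_csv(out / "labels.csv")
    with open(out / "grid.csv", "w", encoding="utf-8") as fh:
        fh.write(header)
        grid.table.to_csv(fh, index=False)
    best_json = best.to_dict(orient="records")
    with open(out / "best_models.json", "w", encoding="utf-8") as fh:
        json.dump({"software": f"rehabpredict {__version__}",
                   "seed": config.seed,
                   "hyperparameters": grid.hyperparameters,
                   "skipped": grid.skipped,
                   "best_models": best_json}, fh, indent=2, default=str)
    cfg = asdict(config)
    cfg["srd"] = {"arat": config.srd.arat, "bbt": config.srd.bbt,
                  "nhpt": config.srd.nhpt}
    cfg["feature_sets"] = [sorted(s) for s in config.feature_sets]
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh)

    lines = [
        f"rehabpredict {__version__} run (seed {config.seed})",
        f"cohort: {summary['n_participants']} participants, "
        f"{summary['n_datasets']} datasets",
        f"age {summary['age']['mean']:.1f} +/- {summary['age']['sd']:.1f} y, "
        f"EDSS {summary['edss']['mean']:.1f} +/- {summary['edss']['sd']:.1f}",
        "considerable improvements: "
        + ", ".join(f"{s.upper()} {counts[s]}" for s in config.outcomes),
        "",
        "best models per outcome (balanced accuracy %, non-responder correct):",
    ]
    for _, row in best.iterrows():
        lines.append(
            f"  {row['outcome'].upper():4s} {row['model']:6s} "
            f"sets {{{row['feature_sets']}}}: "
            f"BA {round(100 * row['balanced_accuracy'])}%, "
            f"sens {round(100 * row['sensitivity'])}%, "
            f"spec {round(100 * row['specificity'])}%, "
            f"prec {round(100 * row['precision'])}%, "
            f"non-responder {'yes' if row['nonresponder_correct'] else 'no'}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    stage("done")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return out
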