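"""End-to-end analysis: QC, smoothing, calibration, tracking, metrics, stats.

``run_pipeline`` ties the stages into the full study workflow: quality
control on the cohort, Woltring-style smoothing of marker trajectories,
static-trial calibration of every tracking model, dynamic-trial tracking,
cycle events, per-cycle tilt metrics, then model-vs-Definition agreement
tables and sex-stratified summaries.  Reports are deterministic given the
inputs and the seed.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .csvio import read_csv_trial
from .errors import ConfigError
from .events import DEFAULT_CONTACT_THRESHOLD_MM, detect_dvj_events
from .metrics import compute_metrics
from .models import (MODEL_SPECS, TRACKING_MODELS, TrunkModel, calibrate,
                     track_trial)
from .simulate import ArtifactConfig, Cohort, generate_cohort
from .smoothing import SmoothingConfig, smooth_trial
from .stats import (compare_models, qc_filter, sex_difference_summary)

ALL_MODELS = (TrunkModel.DEFINITION, *TRACKING_MODELS)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``input_dir`` (CSV trials in the package dialect) or the
    simulation parameters (``n_participants`` etc.) supply the cohort.
    """

    input_dir: str | None = None
    n_participants: int = 18
    n_flicker: int = 0
    models: tuple[str, ...] = tuple(m.value for m in ALL_MODELS)
    predicted_mse: float | None = 10.0       # mm^2; None disables smoothing
    event_source: str = "truth"              # "truth" | "detect"
    contact_threshold_mm: float = DEFAULT_CONTACT_THRESHOLD_MM
    qc_max_dropout: float = 0.10
    icc_form: str = "absolute"
    output_dir: str | None = None
    seed: int = 0
    artifact: dict = field(default_factory=dict)

    def __post_init__(self):
        valid = {m.value for m in ALL_MODELS}
        bad = set(self.models) - valid
        if bad:
            raise ConfigError(f"unknown model ids {sorted(bad)}")
        if TrunkModel.DEFINITION.value not in self.models:
            self.models = (TrunkModel.DEFINITION.value, *self.models)
        if self.event_source not in ("truth", "detect"):
            raise ConfigError("event_source must be 'truth' or 'detect'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All report tables of one run plus reproducibility metadata."""

    metric_table: pd.DataFrame      # per participant-model-task-metric value
    summary_table: pd.DataFrame     # group means +/- SD (ALL / Female / Male)
    comparison_table: pd.DataFrame  # mean abs diff + Wilcoxon p
    agreement_table: pd.DataFrame   # ICC + 95% CI + band
    sexdiff_table: pd.DataFrame     # female/male means and differences
    metadata: dict

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "metric_table": self.metric_table,
            "summary_table": self.summary_table,
            "comparison_table": self.comparison_table,
            "agreement_table": self.agreement_table,
            "sexdiff_table": self.sexdiff_table,
        }
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# cohort analysis

def analyze_cohort(cohort: Cohort, models=ALL_MODELS,
                   predicted_mse: float | None = 10.0,
                   event_source: str = "truth",
                   contact_threshold_mm: float = DEFAULT_CONTACT_THRESHOLD_MM,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Track every participant with every model and collect cycle metrics.

    Returns the long-format metric table (one row per participant, model,
    task and metric) plus a list of per-trial warnings.
    """
    models = [TrunkModel(m) for m in models]
    rows, notes = [], []
    smoothing = (SmoothingConfig(predicted_mse)
                 if predicted_mse is not None else None)
    for part in cohort.participants:
        if "static" not in part.trials:
            raise ConfigError(f"{part.subject}: no static trial")
        calibrations = {m: calibrate(part.trials["static"], MODEL_SPECS[m])
                        for m in models}
        for task in ("gait", "dvj"):
            trial = part.trials.get(task)
            if trial is None:
                continue
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                work = (smooth_trial(trial, smoothing)
                        if smoothing is not None
                        else trial.interpolate_gaps())
                truth = part.truths.get(task) if part.truths else None
                if task == "dvj" and (event_source == "detect"
                                      or truth is None):
                    heel = work.marker("HEEL")[:, 2]
                    annotation = detect_dvj_events(
                        heel, work.rate, contact_threshold_mm)
                elif truth is not None:
                    # gait cycles always come from annotations
                    annotation = truth.annotation
                else:
                    raise ConfigError(
                        f"{part.subject}/{task}: no annotated events "
                        "available")
                for model in models:
                    series = track_trial(work, calibrations[model])
                    m = compute_metrics(series, annotation)
                    for metric, value in m.as_dict().items():
                        rows.append({
                            "subject": part.subject, "sex": part.sex,
                            "model": model.value, "task": task,
                            "metric": metric, "value": value,
                        })
            notes.extend(f"{part.subject}/{task}: {w.message}" for w in caught)
    table = pd.DataFrame(rows)
    return table, notes


def summarize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Group means +/- SD of each metric for ALL, female and male subsets."""
    rows = []
    for model in [m.value for m in ALL_MODELS]:
        sub = table[table["model"] == model]
        if sub.empty:
            continue
        for task in ("gait", "dvj"):
            for metric in ("mean", "max", "min", "rom"):
                cell = sub[(sub["task"] == task) & (sub["metric"] == metric)]
                if cell.empty:
                    continue
                row = {"model": model, "task": task, "metric": metric}
                for label, grp in (("all", cell),
                                   ("female", cell[cell["sex"] == "F"]),
                                   ("male", cell[cell["sex"] == "M"])):
                    vals = grp["value"].to_numpy(dtype=float)
                    row[f"{label}_mean"] = vals.mean() if vals.size else np.nan
                    row[f"{label}_sd"] = (vals.std(ddof=1)
                                          if vals.size > 1 else np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def load_cohort_csv(input_dir) -> Cohort:
    """Assemble a cohort from ``*.csv`` trials in the package dialect."""
    from .simulate import Participant
    trials_by_subject: dict[str, dict] = {}
    for path in sorted(Path(input_dir).glob("*.csv")):
        trial = read_csv_trial(path)
        trials_by_subject.setdefault(trial.subject, {})[trial.kind] = trial
    if not trials_by_subject:
        raise ConfigError(f"no CSV trials found in {input_dir}")
    participants = []
    for subject, trials in sorted(trials_by_subject.items()):
        sex = next((t.sex for t in trials.values() if t.sex), None)
        participants.append(Participant(
            subject=subject, sex=sex or "F", height_cm=float("nan"),
            template=None, trials=trials, truths={}))
    return Cohort(participants=participants, seed=-1)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None,
                 ) -> ReportBundle:
    """Full analysis: cohort -> QC -> tracking -> metrics -> agreement tables."""
    if cohort is None:
        if config.input_dir:
            cohort = load_cohort_csv(config.input_dir)
        else:
            cohort = generate_cohort(
                n=config.n_participants, n_flicker=config.n_flicker,
                artifact=ArtifactConfig(**config.artifact),
                seed=config.seed)
    retained, excluded = qc_filter(cohort, config.qc_max_dropout)
    kept = Cohort(participants=[p for p in cohort.participants
                                if p.subject in retained],
                  seed=cohort.seed)
    event_source = config.event_source
    if config.input_dir and event_source == "truth":
        event_source = "detect"  # file cohorts carry no ground truth
    table, notes = analyze_cohort(
        kept, models=config.models, predicted_mse=config.predicted_mse,
        event_source=event_source,
        contact_threshold_mm=config.contact_threshold_mm)
    comparison = compare_models(table, icc_form=config.icc_form)
    agreement = comparison[["model", "task", "metric", "n",
                            "icc", "icc_ci_low", "icc_ci_high", "band"]]
    comparison_short = comparison[["model", "task", "metric", "n",
                                   "mean_abs_diff", "wilcoxon_p"]]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sexdiff = sex_difference_summary(table)
    notes.extend(str(w.message) for w in caught)
    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "participants_retained": sorted(retained),
        "participants_excluded": [list(e) for e in excluded],
        "warnings": notes,
    }
    bundle = ReportBundle(metric_table=table,
                          summary_table=summarize_metrics(table),
                          comparison_table=comparison_short,
                          agreement_table=agreement,
                          sexdiff_table=sexdiff, metadata=metadata)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
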