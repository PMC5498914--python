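"""End-to-end experiment orchestration.

Three named experiment designs:

* ``original``  — all 13 features on the imbalanced cohort.
* ``smote_all`` — rebalance to 300/300 with SMOTE, then all features.
* ``smote_rfe`` — rebalance, select a feature subset with RFE, then
  evaluate on the selected subset.

Each runs preprocess -> feature extraction -> (resampling) ->
(selection) -> the requested classifiers -> repeated-CV evaluation, and
writes the feature table, per-model report JSONs, ROC CSVs and a run
manifest. Reruns with an identical config produce byte-identical report
files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .dataset import LabelledDataset
from .evaluation import CvConfig, EvaluationReport, cross_validate, roc_export
from .features import FeatureConfig, extract_features
from .imbalance import SmoteConfig, smote_resample
from .preprocess import PreprocessConfig, preprocess
from .records import FHRRecord, ValidationError
from .selection import rfe_select
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("ctglearn")

EXPERIMENTS = ("original", "smote_all", "smote_rfe")

__all__ = ["PipelineConfig", "ExperimentResult", "run_experiment", "build_feature_table"]


@dataclass
class PipelineConfig:
    experiment: str = "original"
    models: tuple = ("flda", "rf", "dl")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    record_dir: str | None = None          # load CSV records instead of synthesising
    dataset: LabelledDataset | None = None  # prebuilt feature table (skips generation)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    rfe_sizes: tuple | None = None
    cv: CvConfig = field(default_factory=CvConfig)
    smote_within_folds: bool = False
    seed: int = 0
    out_dir: str = "ctg_run"

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValidationError(f"experiment must be one of {EXPERIMENTS}")
        for m in self.models:
            if m not in ("flda", "rf", "dl"):
                raise ValidationError(f"unknown model {m!r}")


@dataclass
class ExperimentResult:
    config: PipelineConfig
    dataset: LabelledDataset
    evaluated: LabelledDataset      # after any resampling/selection
    reports: dict                   # model name -> EvaluationReport
    selected_features: tuple | None
    rfe_profile: list | None
    out_dir: Path


def build_feature_table(
    records,
    pre_cfg: PreprocessConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
) -> LabelledDataset:
    """Preprocess each record and extract its 13 features. Records that
    fail preprocessing are skipped with a warning rather than aborting
    the cohort."""
    rows, labels, ids = [], [], []
    for rec in records:
        try:
            clean = preprocess(rec, pre_cfg)
            vec = extract_features(clean, feat_cfg)
        except ValidationError as exc:
            log.warning("record %s skipped: %s", rec.record_id, exc)
            continue
        rows.append(vec.to_array())
        labels.append(1 if rec.label == "case" else 0)
        ids.append(rec.record_id)
    if not rows:
        raise ValidationError("no record survived preprocessing")
    return LabelledDataset(np.vstack(rows), np.array(labels), record_ids=tuple(ids))


def _load_record_dir(path: str) -> list[FHRRecord]:
    """Load `*.csv` signal files with labels from a sibling labels.csv
    (columns record_id,label)."""
    import pandas as pd

    from .records import read_record

    root = Path(path)
    labels_file = root / "labels.csv"
    label_map = {}
    if labels_file.exists():
        df = pd.read_csv(labels_file)
        label_map = dict(zip(df["record_id"].astype(str), df["label"].astype(str)))
    records = []
    for f in sorted(root.glob("*.csv")):
        if f.name in ("labels.csv", "outcomes.csv", "features.csv"):
            continue
        records.append(read_record(f, label=label_map.get(f.stem, "unknown")))
    if not records:
        raise ValidationError(f"no signal CSVs found under {root}")
    return records


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_experiment(cfg: PipelineConfig) -> ExperimentResult:
    """Run one named experiment end to end and write its artefacts."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if cfg.dataset is not None:
        dataset = cfg.dataset
    else:
        if cfg.record_dir is not None:
            records = _load_record_dir(cfg.record_dir)
            log.info("loaded %d records from %s", len(records), cfg.record_dir)
        else:
            records, _, outcomes = generate_cohort(cfg.cohort)
            outcomes.to_csv(out / "outcomes.csv", index=False)
            log.info(
                "synthesised cohort: %d controls / %d cases, %.0f min at %g Hz",
                cfg.cohort.n_controls, cfg.cohort.n_cases,
                cfg.cohort.duration_min, cfg.cohort.fs,
            )
        dataset = build_feature_table(records, cfg.preprocess, cfg.features)
    dataset.to_csv(out / "features.csv")
    log.info("feature table: %d records x %d features (%.1fs)",
             dataset.labels.size, dataset.features.shape[1], time.time() - t0)

    evaluated = dataset
    selected = None
    profile = None
    resampler = None
    if cfg.experiment in ("smote_all", "smote_rfe"):
        if cfg.smote_within_folds:
            def resampler(train, fold_seed, _cfg=cfg.smote):
                n_min, n_maj = train.n_cases, train.n_controls
                target = max(n_min, min(_cfg.target_minority, n_maj))
                fold_cfg = SmoteConfig(
                    k_neighbours=min(_cfg.k_neighbours, max(1, n_min - 1)),
                    target_minority=target,
                    target_majority=min(_cfg.target_majority, n_maj),
                    seed=fold_seed,
                )
                return smote_resample(train, fold_cfg)
        else:
            evaluated = smote_resample(dataset, cfg.smote)
            log.info("SMOTE: %d/%d -> %d/%d (applied before CV; fold metrics "
                     "are optimistically biased)",
                     dataset.n_cases, dataset.n_controls,
                     evaluated.n_cases, evaluated.n_controls)
    if cfg.experiment == "smote_rfe":
        rfe = rfe_select(evaluated, sizes=cfg.rfe_sizes, folds=cfg.cv.k_folds, seed=cfg.seed)
        selected = rfe.selected
        profile = rfe.profile
        evaluated = evaluated.subset_features(selected)
        _write_json({"ranking": rfe.ranking, "profile": rfe.profile,
                     "best_size": rfe.best_size, "selected": rfe.selected},
                    out / "rfe.json")
        log.info("RFE kept %d features: %s", rfe.best_size, ", ".join(selected))

    reports: dict[str, EvaluationReport] = {}
    for model in cfg.models:
        t1 = time.time()
        report = cross_validate(evaluated, model, cfg.cv, resampler=resampler)
        reports[model] = report
        _write_json(report.to_dict(), out / f"report_{model}.json")
        pts = report.roc_points
        with open(out / f"roc_{model}.csv", "w") as fh:
            fh.write("threshold,fpr,tpr\n")
            for thr, fpr, tpr in pts:
                fh.write(f"{'inf' if not np.isfinite(thr) else repr(thr)},{fpr!r},{tpr!r}\n")
        log.info("%s: sens=%.3f spec=%.3f auc=%.3f err=%.3f (%.1fs)",
                 model,
                 -1 if report.sensitivity is None else report.sensitivity,
                 -1 if report.specificity is None else report.specificity,
                 report.auc, report.cv_error, time.time() - t1)

    manifest = {
        "version": __version__,
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "models": list(cfg.models),
        "cohort": None if cfg.record_dir else asdict(cfg.cohort),
        "record_dir": cfg.record_dir,
        "preprocess": asdict(cfg.preprocess),
        "smote": asdict(cfg.smote) if cfg.experiment != "original" else None,
        "smote_within_folds": cfg.smote_within_folds,
        "cv": asdict(cfg.cv),
        "selected_features": selected,
    }
    _write_json(manifest, out / "manifest.json")
    return ExperimentResult(
        config=cfg, dataset=dataset, evaluated=evaluated, reports=reports,
        selected_features=selected, rfe_profile=profile, out_dir=out,
    )
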