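"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
fuse -> classify -> report.

A run directory receives the generated signals, per-subject feature
tables, selection reports, evaluation reports (JSON + TSV), a log and a
manifest with the config hash and seed.  Rerunning with the same config
reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation, selection as sel_mod
from .evaluation import CLASSIFIER_NAMES, SplitSpec
from .exceptions import ConfigurationError, DomainError
from .features.connectivity import plv_network
from .features.spectral import extract_spectral_features
from .features.time import extract_time_features
from .preprocess import (
    EEGRecording,
    preprocess_recording,
    select_condition_windows,
)
from .simulate import (
    SubjectRecord,
    SynthConfig,
    config_to_dict,
    generate_cohort,
    null_config,
    write_manifest,
    write_session_csv,
)

logger = logging.getLogger(__name__)

DOMAINS = ("time", "freq", "plv")


@dataclass
class PipelineConfig:
    """Everything a full run needs; field names double as config-file keys."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    low: float = 1.0
    high: float = 35.0
    ica: bool = False
    epoch_ms: float = 1000.0
    reject_ptp: float = 100.0
    nw: float = 4.0
    alpha: float = 0.05
    correction: str = "none"
    split: SplitSpec = field(default_factory=SplitSpec)
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    paper_mode: bool = False  # whole-cohort selection instead of per-split
    write_signals: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = config_to_dict(self.synth)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SYNTH_KEYS = {
    "n_subjects": int,
    "fs": float,
    "noise_scale": float,
    "blink_rate_per_min": float,
    "blink_amplitude": float,
    "line_noise_amplitude": float,
    "seed": int,
}
_PIPE_KEYS = {
    "low": float,
    "high": float,
    "ica": None,
    "epoch_ms": float,
    "reject_ptp": float,
    "nw": float,
    "alpha": float,
    "correction": str,
    "paper_mode": None,
    "write_signals": None,
    "log_level": str,
}
_SPLIT_KEYS = {
    "train_fraction": float,
    "cv_folds": int,
    "mode": str,
}


def _parse_bool(v: str) -> bool:
    if v.lower() in ("1", "true", "yes", "on"):
        return True
    if v.lower() in ("0", "false", "no", "off"):
        return False
    raise ConfigurationError(f"not a boolean: {v!r}")


def load_config(path: str | Path, overrides: Mapping | None = None) -> PipelineConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment).

    Recognized keys: the scalar SynthConfig fields, the pipeline
    parameters, the split fields, ``classifiers`` (comma-separated) and
    ``null`` (boolean: build a no-effect cohort).
    """
    text = Path(path).read_text()
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected key = value")
        key, value = (part.strip() for part in line.split("=", 1))
        kv[key] = value
    if overrides:
        kv.update({k: str(v) for k, v in overrides.items()})
    return config_from_mapping(kv)


def config_from_mapping(kv: Mapping[str, str]) -> PipelineConfig:
    synth_kwargs: dict = {}
    pipe_kwargs: dict = {}
    split_kwargs: dict = {}
    use_null = False
    for key, value in kv.items():
        if key == "null":
            use_null = _parse_bool(value)
        elif key == "classifiers":
            pipe_kwargs["classifiers"] = tuple(
                c.strip() for c in value.split(",") if c.strip()
            )
        elif key in _SYNTH_KEYS:
            synth_kwargs[key] = _SYNTH_KEYS[key](value)
        elif key in _SPLIT_KEYS:
            split_kwargs[key] = _SPLIT_KEYS[key](value)
        elif key in _PIPE_KEYS:
            caster = _PIPE_KEYS[key]
            pipe_kwargs[key] = _parse_bool(value) if caster is None else caster(value)
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    synth = null_config(**synth_kwargs) if use_null else SynthConfig(**synth_kwargs)
    split_kwargs.setdefault("seed", synth.seed)
    return PipelineConfig(synth=synth, split=SplitSpec(**split_kwargs), **pipe_kwargs)


# ---------------------------------------------------------------------------
# per-subject stages
# ---------------------------------------------------------------------------


def extract_subject_features(
    record: SubjectRecord, config: PipelineConfig
) -> tuple[dict[str, pd.DataFrame], np.ndarray]:
    """Preprocess one subject and extract the three domain tables.

    Returns ``{"time": ..., "freq": ..., "plv": ...}`` (row-aligned, one
    row per surviving epoch) and the per-epoch label vector.
    """
    rec = EEGRecording(record.data, record.fs, record.channel_names)
    windows = select_condition_windows(record.condition_windows)
    cleaned, epochs = preprocess_recording(
        rec,
        windows,
        low=config.low,
        high=config.high,
        ica=config.ica,
        epoch_ms=config.epoch_ms,
        reject_ptp_uv=config.reject_ptp,
        random_state=config.synth.seed + record.seed,
    )
    tables = {
        "time": extract_time_features(epochs),
        "freq": extract_spectral_features(epochs, nw=config.nw),
        "plv": plv_network(cleaned, epochs),
    }
    return tables, np.asarray(epochs.labels)


def extract_cohort_features(
    records: Sequence[SubjectRecord], config: PipelineConfig
) -> tuple[list[dict[str, pd.DataFrame]], list[np.ndarray]]:
    tables_by_subject: list[dict[str, pd.DataFrame]] = []
    labels_by_subject: list[np.ndarray] = []
    for rec in records:
        logger.info("extracting features: subject %s", rec.subject_id)
        tables, labels = extract_subject_features(rec, config)
        tables_by_subject.append(tables)
        labels_by_subject.append(labels)
    return tables_by_subject, labels_by_subject


# ---------------------------------------------------------------------------
# cohort-level evaluation
# ---------------------------------------------------------------------------


def _pool(tables: Sequence[pd.DataFrame], labels: Sequence[np.ndarray]):
    pooled = pd.concat(tables, ignore_index=True)
    return pooled, np.concatenate(labels)


def evaluate_scenario(
    tables: Sequence[pd.DataFrame],
    labels: Sequence[np.ndarray],
    config: PipelineConfig,
    selection: Mapping | None,
) -> pd.DataFrame:
    """Benchmark one feature set (already fused or single-domain) under the
    configured split mode.  ``selection`` of None disables in-harness
    screening (whole-cohort mode pre-selects columns instead)."""
    split = config.split
    if split.mode == "pooled_epochs":
        X, y = _pool(tables, labels)
        return evaluation.run_benchmark(
            X, y, split, config.classifiers, selection
        )
    if split.mode == "per_subject_epochs":
        reports = [
            evaluation.run_benchmark(X, y, split, config.classifiers, selection)
            for X, y in zip(tables, labels)
        ]
        return evaluation.summarize_reports(reports)
    # leave_subject_out
    per_subject_rows = []
    for held in range(len(tables)):
        X_tr, y_tr = _pool(
            [t for i, t in enumerate(tables) if i != held],
            [l for i, l in enumerate(labels) if i != held],
        )
        rows = {}
        for name in config.classifiers:
            m = evaluation._fit_score(
                name, split.seed, X_tr, y_tr, tables[held], labels[held], selection
            )
            rows[name] = m
        per_subject_rows.append(rows)
    out = {}
    for m in evaluation.METRIC_NAMES:
        vals = pd.DataFrame(
            {name: [r[name][m] for r in per_subject_rows] for name in config.classifiers}
        )
        out[f"holdout_{m}_mean"] = vals.mean()
        out[f"holdout_{m}_sd"] = vals.std(ddof=0)
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and populate ``out_dir``.

    Stage order: simulate, preprocess, extract (time / spectral /
    connectivity), t-test selection, fusion, classification under three
    scenarios (each domain subset plus the fused vector).  Returns a dict
    with the evaluation summaries and selection results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("eegstress")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run_pipeline_inner(config, out_dir)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: PipelineConfig, out_dir: Path) -> dict:
    logger.info("stage simulate: %d subjects, seed %d",
                config.synth.n_subjects, config.synth.seed)
    records = generate_cohort(config.synth)
    if config.write_signals:
        sig_dir = out_dir / "signals"
        for rec in records:
            write_session_csv(rec, sig_dir / f"{rec.subject_id}.csv")
        write_manifest(records, sig_dir / "manifest.tsv")

    logger.info("stage preprocess+extract")
    tables_by_subject, labels_by_subject = extract_cohort_features(records, config)

    feat_dir = out_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    for rec, tables, labels in zip(records, tables_by_subject, labels_by_subject):
        for domain in DOMAINS:
            df = tables[domain].copy()
            df.insert(0, "label", labels)
            df.to_csv(
                feat_dir / f"{rec.subject_id}_{domain}.tsv",
                sep="\t", index=False, float_format="%.8g",
            )

    logger.info("stage select (whole-cohort report)")
    sel_dir = out_dir / "selection"
    pooled_by_domain = {
        d: _pool([t[d] for t in tables_by_subject], labels_by_subject)
        for d in DOMAINS
    }
    cohort_selections = {}
    for d in DOMAINS:
        X, y = pooled_by_domain[d]
        res = sel_mod.select_significant(
            X, y, alpha=config.alpha, correction=config.correction
        )
        res.write_tsv(sel_dir / f"selection_{d}.tsv")
        cohort_selections[d] = res
        logger.info("domain %s: %d/%d features significant",
                    d, res.n_selected, X.shape[1])

    logger.info("stage classify")
    harness_selection = (
        None
        if config.paper_mode
        else {"alpha": config.alpha, "correction": config.correction}
    )
    scenario_tables: dict[str, tuple[list[pd.DataFrame], list[np.ndarray]]] = {}
    for d in DOMAINS:
        per_subj = [t[d] for t in tables_by_subject]
        if config.paper_mode:
            feats = cohort_selections[d].selected_features
            if feats:
                per_subj = [t.loc[:, feats] for t in per_subj]
        scenario_tables[d] = (per_subj, labels_by_subject)
    fused_per_subj = [
        pd.concat([t[d] for d in DOMAINS], axis=1) for t in tables_by_subject
    ]
    if config.paper_mode:
        feats = [
            f for d in DOMAINS for f in cohort_selections[d].selected_features
        ]
        if feats:
            fused_per_subj = [t.loc[:, feats] for t in fused_per_subj]
    scenario_tables["fused"] = (fused_per_subj, labels_by_subject)

    summaries: dict[str, pd.DataFrame] = {}
    for name, (tabs, labs) in scenario_tables.items():
        logger.info("scenario %s (%d columns)", name, tabs[0].shape[1])
        summaries[name] = evaluate_scenario(tabs, labs, config, harness_selection)

    eval_dir = out_dir / "evaluation"
    eval_dir.mkdir(exist_ok=True)
    results_json: dict = {
        "config_hash": config.content_hash(),
        "seed": config.synth.seed,
        "split_mode": config.split.mode,
        "selection_counts": {
            d: cohort_selections[d].n_selected for d in DOMAINS
        },
        "scenarios": {
            name: json.loads(df.to_json(orient="index"))
            for name, df in summaries.items()
        },
    }
    (eval_dir / "evaluation.json").write_text(
        json.dumps(results_json, indent=2, sort_keys=True) + "\n"
    )
    for name, df in summaries.items():
        evaluation.report_to_tsv(df, eval_dir / f"evaluation_{name}.tsv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "n_subjects": len(records),
        "labels": {r.subject_id: r.label for r in records},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    logger.info("pipeline complete: %s", out_dir)
    return {
        "summaries": summaries,
        "selections": cohort_selections,
        "records": records,
        "results": results_json,
    }


def load_feature_table(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a feature TSV written by the pipeline (label column first)."""
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise DomainError(f"{path}: no 'label' column")
    labels = df.pop("label").to_numpy()
    return df, labels
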