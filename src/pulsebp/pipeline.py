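"""End-to-end orchestration: simulate -> extract -> features -> fit ->
predict -> evaluate, as one seed-reproducible, logged run.

A run directory contains every artifact of the workflow: the effective
configuration, the record-level feature table, the cuff-reference table,
the fitted SBP/DBP calibration models, held-out predictions, the
evaluation report (JSON + CSV), plots, and a log.  The same seed and
configuration produce a byte-identical ``report.json``.

Simulation and feature extraction (the expensive stages) cache their
outputs beside a manifest holding a checksum of the configuration slice
they depend on; a re-run with ``resume=True`` reuses them only when the
checksum matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import fiducials as fid
from .errors import ConfigError, FiducialFailureError, RecordRejectedError
from .evaluation import PairedMeasurements, evaluate_pairs
from .io import Recording, write_report
from .model import BPRegression, BPRegressionResults
from .plots import save_report_plots
from .synth import CohortParams, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "extract_record_features"]

log = logging.getLogger("pulsebp")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    seed: int = 0
    n_subjects: int = 60
    duration_s: float = 180.0
    fs: float = 1000.0
    ecg_noise_sd: float = 0.0
    ppg_noise_sd: float = 0.0
    period_jitter_sd: float = 0.0
    ptt_jitter_sd_ms: float = 0.0
    cuff_sd_mmhg: float = 3.0
    quality_threshold: float = 0.9
    smooth_cutoff_hz: float = 15.0
    min_beats: int = 10
    train_fraction: float = 0.5
    min_train_subjects: int = 30
    selection: str = "forward-cv"
    n_folds: int = 5
    max_features: int | None = None
    make_plots: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.fs < 100:
            raise ConfigError("fs must be at least 100 Hz")
        if not 0.0 <= self.quality_threshold <= 1.0:
            raise ConfigError("quality_threshold must lie in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie strictly in (0, 1)")
        if self.min_beats < 1:
            raise ConfigError("min_beats must be at least 1")
        if self.cuff_sd_mmhg < 0 or self.ppg_noise_sd < 0 or self.ecg_noise_sd < 0:
            raise ConfigError("noise standard deviations must be nonnegative")

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            n=self.n_subjects,
            seed=self.seed,
            duration_s=self.duration_s,
            fs=self.fs,
            ecg_noise_sd=self.ecg_noise_sd,
            ppg_noise_sd=self.ppg_noise_sd,
            period_jitter_sd=self.period_jitter_sd,
            ptt_jitter_sd_ms=self.ptt_jitter_sd_ms,
            cuff_sd_mmhg=self.cuff_sd_mmhg,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def extract_record_features(
    recording: Recording,
    quality_threshold: float = 0.9,
    smooth_cutoff_hz: float = 15.0,
    min_beats: int = 10,
) -> tuple[pd.Series, pd.DataFrame]:
    """Record -> aggregated feature vector + per-beat fiducial table."""
    r_peaks = fid.detect_r_peaks(recording)
    beats = fid.segment_beats(recording, r_peaks)
    beats = fid.quality_gate(beats, threshold=quality_threshold)
    rows = []
    vectors = []
    for b in beats:
        if not b.accepted:
            rows.append({"beat": b.index, "accepted": False,
                         "quality": b.quality})
            continue
        try:
            f = fid.detect_fiducials(b, smooth_cutoff_hz=smooth_cutoff_hz)
        except FiducialFailureError:
            b.accepted = False
            rows.append({"beat": b.index, "accepted": False,
                         "quality": b.quality})
            continue
        row = {"beat": b.index, "accepted": True, "quality": b.quality}
        for k in fid.FIDUCIAL_ORDER:
            row[f"t_{k}"] = f.times[k]
            row[f"a_{k}"] = f.amplitudes[k]
        rows.append(row)
        vectors.append(feat.compute_beat_features(f, b))
    agg = feat.aggregate_record(vectors, min_beats=min_beats)
    agg["subject_id"] = recording.subject_id
    return agg, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage caching
# ---------------------------------------------------------------------------

def _checksum(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


def _cache_valid(manifest_path: Path, checksum: str, outputs: list[Path]) -> bool:
    if not manifest_path.exists() or not all(p.exists() for p in outputs):
        return False
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    return manifest.get("checksum") == checksum


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    resume: bool = False,
) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, out_dir, resume)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path, resume: bool) -> Path:
    config.to_yaml(out_dir / "config.yaml")
    t0 = time.time()

    sim_keys = {
        k: v for k, v in config.to_dict().items()
        if k in ("seed", "n_subjects", "duration_s", "fs", "ecg_noise_sd",
                 "ppg_noise_sd", "period_jitter_sd", "ptt_jitter_sd_ms",
                 "cuff_sd_mmhg", "quality_threshold", "smooth_cutoff_hz",
                 "min_beats")
    }
    checksum = _checksum(sim_keys)
    features_path = out_dir / "features.csv"
    cuff_path = out_dir / "cuff.csv"
    truth_path = out_dir / "truth_subjects.csv"
    manifest_path = out_dir / "stage_manifest.json"
    cached = resume and _cache_valid(
        manifest_path, checksum, [features_path, cuff_path, truth_path]
    )
    if cached:
        log.info("stage simulate+extract: reusing cached outputs")
        features_df = pd.read_csv(features_path)
        cuff = pd.read_csv(cuff_path)
    else:
        log.info("stage simulate: generating cohort n=%d", config.n_subjects)
        cohort = generate_cohort(config.cohort_params())
        cohort.truth.subjects.to_csv(truth_path, index=False)
        cohort.cuff.to_csv(cuff_path, index=False)
        cuff = cohort.cuff

        log.info("stage extract: fiducials and features")
        rows = []
        for rec in cohort.recordings:
            try:
                agg, _ = extract_record_features(
                    rec,
                    quality_threshold=config.quality_threshold,
                    smooth_cutoff_hz=config.smooth_cutoff_hz,
                    min_beats=config.min_beats,
                )
                rows.append(agg)
            except RecordRejectedError as exc:
                log.warning("stage extract: record %s rejected (%s)",
                            rec.subject_id, exc)
            except Exception:
                log.error("stage extract failed on record %s", rec.subject_id)
                raise
        if not rows:
            raise RecordRejectedError("every record was rejected")
        features_df = pd.DataFrame(rows)
        features_df.to_csv(features_path, index=False)
        manifest_path.write_text(json.dumps(
            {"checksum": checksum, "stage": "simulate+extract"}, sort_keys=True
        ))

    merged = features_df.merge(cuff, on="subject_id", how="inner")
    n = len(merged)
    log.info("stage fit: %d subjects with features and cuff references", n)
    split_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7919])
    )
    order = split_rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    if test_idx.size == 0:
        raise ConfigError("train_fraction leaves no held-out subjects")
    train, test = merged.iloc[train_idx], merged.iloc[test_idx]

    feature_cols = [c for c in feat.FEATURE_NAMES if c in merged.columns]
    results: dict[str, BPRegressionResults] = {}
    for target in ("sbp", "dbp"):
        model = BPRegression.from_dataframe(
            train[["subject_id"] + feature_cols], train, target=target,
            feature_cols=feature_cols,
        )
        res = model.fit(
            selection=config.selection, seed=config.seed,
            n_folds=config.n_folds, max_features=config.max_features,
            min_subjects=config.min_train_subjects,
        )
        res.to_json(out_dir / f"model_{target}.json")
        results[target] = res
        log.info("stage fit: %s selected %s", target, res.selected_features)

    log.info("stage predict: %d held-out subjects", len(test))
    preds = pd.DataFrame({
        "subject_id": test["subject_id"].to_numpy(),
        "pred_sbp": results["sbp"].predict(test[feature_cols]),
        "pred_dbp": results["dbp"].predict(test[feature_cols]),
        "ref_sbp": test["sbp_mean"].to_numpy(),
        "ref_dbp": test["dbp_mean"].to_numpy(),
    })
    preds.to_csv(out_dir / "predictions.csv", index=False)

    log.info("stage evaluate")
    pairs = PairedMeasurements(
        ref_sbp=preds["ref_sbp"].to_numpy(),
        ref_dbp=preds["ref_dbp"].to_numpy(),
        pred_sbp=preds["pred_sbp"].to_numpy(),
        pred_dbp=preds["pred_dbp"].to_numpy(),
        subject_ids=list(preds["subject_id"]),
    )
    report = evaluate_pairs(pairs)
    write_report(report, out_dir / "report.json", out_dir / "report.csv")
    if config.make_plots:
        save_report_plots(report, out_dir / "plots")
    log.info("run complete in %.1f s", time.time() - t0)
    return out_dir
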