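"""End-to-end orchestration of the estimation pipeline.

Stage order: synthesize (or load) the cohort -> preprocess each recording
into gated EA pulses -> extract PWA feature tables -> build calibration-paired
and calibration-free sample tables and the subject-stratified split -> train
the requested estimators per target -> evaluate absolute accuracy and, for
the calibration-mode Lasso, trending ability against the reference.

Each public helper is usable on its own; :func:`run_pipeline` wires them and
optionally persists artifacts (feature table, split, metrics, trend figures)
stamped with the configuration hash and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import models as mdl
from . import pairs as pr
from . import preprocess as pp
from . import pwa
from . import synth as sy
from .config import RunConfig
from .types import ErrorReport, SplitSpec, TrendReport

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class PipelineResult:
    config: RunConfig
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs_cal: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs_free: pd.DataFrame = field(default_factory=pd.DataFrame)
    split: SplitSpec | None = None
    error_reports: dict[str, ErrorReport] = field(default_factory=dict)
    trend_reports: dict[str, TrendReport] = field(default_factory=dict)
    models: dict[str, mdl.TrainedModel] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def cohort_config(cfg: RunConfig) -> sy.CohortConfig:
    s = cfg.synth
    return sy.CohortConfig(
        seed=cfg.stage_seed("synth"),
        n_subjects=s.n_subjects,
        fs=s.fs,
        duration_range=(s.duration_min, s.duration_max),
        noise_sd=s.noise_sd,
        corrupt_frac=s.corrupt_frac,
    )


def extract_features(cohort: sy.SynthCohort, cfg: RunConfig) -> pd.DataFrame:
    """Preprocess every recording and stack the per-window feature tables."""
    p = cfg.preprocess
    tables = []
    for rec in cohort.recordings:
        res = pp.process_recording(
            rec.ppg, rec.abp, win=p.win, overlap=p.overlap, sqi_min=p.sqi_min,
            var_max=p.var_max, lp_cut=p.lp_cut, hp_cut=p.hp_cut, order=p.order,
            align=p.align, max_lag=p.max_lag, L=p.pulse_length,
        )
        demo = {k: v for k, v in rec.demographics.items() if k != "subject_id"}
        tables.append(
            pwa.feature_table(
                res, demo, aix_hr_slope=cfg.pwa.aix_hr_slope,
                inflection_point=cfg.pwa.inflection_point,
            )
        )
    if not tables:
        raise StageError("preprocess: no recordings")
    return pd.concat(tables, ignore_index=True)


def build_sample_tables(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cal = [pr.build_pairs(g) for _, g in features.groupby("subject_id", sort=True)]
    cal = [c for c in cal if not c.empty]
    free = pr.build_calibration_free(features)
    return (pd.concat(cal, ignore_index=True) if cal else pd.DataFrame()), free


def _split_frames(table: pd.DataFrame, split: SplitSpec):
    tr = table[table["subject_id"].isin(split.train_subjects)].reset_index(drop=True)
    te = table[table["subject_id"].isin(split.test_subjects)].reset_index(drop=True)
    return tr, te


def train_and_evaluate(
    result: PipelineResult,
    targets: tuple[str, ...] = ("sbp", "dbp"),
) -> PipelineResult:
    """Fit all configured estimators and compute error reports.

    Report keys are ``{kind}_{target}_{mode}_{split}``; predictions of the
    calibration-mode Lasso on the test set are kept for trending analysis.
    """
    cfg = result.config
    mc = cfg.models
    for mode, table in (("cal", result.pairs_cal), ("free", result.pairs_free)):
        if table.empty:
            continue
        tr, te = _split_frames(table, result.split)
        fcols = pr.pair_feature_columns(table)
        for target in targets:
            y_tr = tr[f"target_{target}"].to_numpy(float)
            y_te = te[f"target_{target}"].to_numpy(float)
            for kind in list(mc.kinds) + (["flat"] if "flat" not in mc.kinds else []):
                key = f"{kind}_{target}_{mode}"
                spec = mdl.ModelSpec(
                    kind, target, seed=cfg.stage_seed(f"model:{key}"),
                    hyperparameters={"budget": mc.svr_budget} if kind == "svr" else {},
                )
                cal_col = f"cal.ref_{target}" if mode == "cal" else None
                try:
                    model = mdl.fit(
                        spec, tr[fcols], y_tr, tr["subject_id"].to_numpy(),
                        k=mc.cv_folds, cal_ref_column=cal_col,
                        max_tune_samples=mc.max_tune_samples,
                        max_train_samples=mc.max_train_samples,
                    )
                except Exception as exc:  # noqa: BLE001
                    raise StageError(f"train ({key}): {exc}") from exc
                result.models[key] = model
                for split_name, frame, yv in (("train", tr, y_tr), ("test", te, y_te)):
                    est = model.predict(frame[fcols] if kind != "flat" else frame)
                    rep = ev.error_stats(est, yv, frame["subject_id"].to_numpy(), split_name)
                    result.error_reports[f"{key}_{split_name}"] = rep
                    logger.info("%s %s: ME %.2f STDE %.2f (n=%d)",
                                key, split_name, rep.me, rep.stde, rep.n)
    return result


def trend_analysis(
    result: PipelineResult,
    model_key: str = "lasso_sbp_cal",
    target: str = "sbp",
) -> dict[str, TrendReport]:
    """Trending ability of a calibration-mode model on the test subjects.

    For each test subject the first valid window is the calibration anchor;
    the model estimates BP at every later window, giving one estimated
    series per subject.  Trend pairs are enumerated over all window pairs of
    the (reference, estimate) series and binned at 3 min.
    """
    cfg = result.config
    model = result.models[model_key]
    feats = result.features
    fcols_table = pwa.feature_columns(include_demographics=False)
    all_pairs = []
    for sid in result.split.test_subjects:
        g = pr._clean(feats[feats["subject_id"] == sid]).sort_values("start")
        if len(g) < 3:
            continue
        cal_row = g.iloc[0]
        est_rows = g.iloc[1:]
        X = {}
        for c in fcols_table:
            X[f"cal.{c}"] = np.full(len(est_rows), float(cal_row[c]))
            X[f"est.{c}"] = est_rows[c].to_numpy(float)
        for t in ("sbp", "dbp", "mbp"):
            X[f"cal.ref_{t}"] = np.full(len(est_rows), float(cal_row[t]))
        for c in pwa.DEMOGRAPHIC_FIELDS:
            if c in g.columns:
                X[c] = est_rows[c].to_numpy(float)
        X = pd.DataFrame(X)
        est_series = np.concatenate([[float(cal_row[target])], model.predict(X)])
        ref_series = np.concatenate([[float(cal_row[target])], est_rows[target].to_numpy(float)])
        times = np.concatenate([[float(cal_row["start"])], est_rows["start"].to_numpy(float)])
        all_pairs += ev.extract_changes(
            times, ref_series, est_series, cfg.evaluate.rel_threshold, subject_id=sid
        )
    reports: dict[str, TrendReport] = {}
    for bin_name, bucket in ev.bin_pairs(all_pairs, cfg.evaluate.bin_edge).items():
        if len(bucket) >= 2:
            reports[f"{target}_{bin_name}"] = ev.polar_stats(
                bucket, cfg.evaluate.angular_limit, timespan_bin=bin_name
            )
    result.trend_reports.update(reports)
    result.summary.setdefault("trend_pairs", {})[target] = len(all_pairs)
    return reports


def run_pipeline(
    cfg: RunConfig,
    outdir=None,
    targets: tuple[str, ...] = ("sbp", "dbp"),
    trend_model: str = "lasso",
) -> PipelineResult:
    """Execute every stage on a synthetic cohort; optionally persist artifacts."""
    result = PipelineResult(config=cfg)
    try:
        cohort = sy.generate_cohort(cohort_config(cfg))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"synth: {exc}") from exc
    try:
        result.features = extract_features(cohort, cfg)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"preprocess/features: {exc}") from exc
    result.pairs_cal, result.pairs_free = build_sample_tables(result.features)
    if result.pairs_cal.empty:
        raise StageError("pairs: no calibration samples produced")
    stats = pr.subject_bp_stats(result.features)
    result.split = pr.stratified_subject_split(
        stats, frac=cfg.train_fraction, seed=cfg.stage_seed("split")
    )
    train_and_evaluate(result, targets)
    for target in targets:
        key = f"{trend_model}_{target}_cal"
        if key in result.models:
            trend_analysis(result, key, target)

    result.summary.update(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        n_subjects=cfg.synth.n_subjects,
        n_windows=int(len(result.features)),
        n_pairs_cal=int(len(result.pairs_cal)),
        n_pairs_free=int(len(result.pairs_free)),
        errors={k: dict(me=r.me, stde=r.stde, n=r.n) for k, r in result.error_reports.items()},
        trends={k: dict(cr=r.cr, pearson_r=r.pearson_r, angular_cr_30=r.angular_cr_30,
                        angular_bias=r.angular_bias, angular_sd=r.angular_sd,
                        n=r.n_pairs) for k, r in result.trend_reports.items()},
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: PipelineResult, outdir: Path) -> None:
    from . import io as pio

    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    pio.write_feature_table(outdir / "features.csv", result.features)
    (outdir / "split.json").write_text(pr.split_to_json(result.split))
    (outdir / "metrics.json").write_text(json.dumps(result.summary, indent=2))
    logger.info("artifacts written to %s (config %s)", outdir, result.summary.get("config_hash"))
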