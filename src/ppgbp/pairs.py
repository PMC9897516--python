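"""Calibration-paired and calibration-free sample tables, and the
subject-level stratified train/test split.

A calibration sample concatenates the features of an earlier (calibration)
window, its reference BP triplet, the features of a later (estimation) window
and the subject demographics; the estimation window's reference BP is the
regression target.  Every ordered pair of valid windows (i < j) of a
recording contributes one sample, so a recording with n valid windows yields
n(n-1)/2 samples with time spans from one window stride upward.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

from .pwa import DEMOGRAPHIC_FIELDS, feature_columns
from .types import SplitSpec

logger = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "dt", "target_sbp", "target_dbp")


def _clean(features: pd.DataFrame) -> pd.DataFrame:
    """Drop windows with any missing feature or target (incomplete PWA)."""
    cols = [c for c in features.columns if c != "subject_id"]
    return features.dropna(subset=cols).reset_index(drop=True)


def build_pairs(features: pd.DataFrame) -> pd.DataFrame:
    """All-combination calibration samples for one recording.

    ``features`` is the per-window feature table of a single recording
    (gated windows only) with columns from :func:`ppgbp.pwa.feature_table`.
    Returns a wide table with calibration-segment columns prefixed ``cal.``,
    estimation-segment columns prefixed ``est.``, the calibration reference
    triplet (``cal.ref_sbp/dbp/mbp``), demographics, ``dt`` and the targets.
    """
    feats = _clean(features)
    n = len(feats)
    if n < 2:
        return pd.DataFrame()
    if feats["subject_id"].nunique() > 1:
        raise ValueError("build_pairs expects windows of a single recording")
    ii, jj = np.triu_indices(n, k=1)
    fcols = feature_columns(include_demographics=False)
    fmat = feats[fcols].to_numpy(float)
    out: dict[str, np.ndarray] = {}
    for k, c in enumerate(fcols):
        out[f"cal.{c}"] = fmat[ii, k]
    out["cal.ref_sbp"] = feats["sbp"].to_numpy(float)[ii]
    out["cal.ref_dbp"] = feats["dbp"].to_numpy(float)[ii]
    out["cal.ref_mbp"] = feats["mbp"].to_numpy(float)[ii]
    for k, c in enumerate(fcols):
        out[f"est.{c}"] = fmat[jj, k]
    for c in DEMOGRAPHIC_FIELDS:
        if c in feats.columns:
            out[c] = feats[c].to_numpy(float)[jj]
    starts = feats["start"].to_numpy(float)
    out["dt"] = starts[jj] - starts[ii]
    out["target_sbp"] = feats["sbp"].to_numpy(float)[jj]
    out["target_dbp"] = feats["dbp"].to_numpy(float)[jj]
    df = pd.DataFrame(out)
    df["subject_id"] = feats["subject_id"].iloc[0]
    assert (df["dt"] > 0).all(), "calibration must precede estimation"
    return df


def build_calibration_free(features: pd.DataFrame) -> pd.DataFrame:
    """One sample per valid window: estimation features + demographics."""
    feats = _clean(features)
    if feats.empty:
        return pd.DataFrame()
    fcols = feature_columns(include_demographics=False)
    out = {f"est.{c}": feats[c].to_numpy(float) for c in fcols}
    for c in DEMOGRAPHIC_FIELDS:
        if c in feats.columns:
            out[c] = feats[c].to_numpy(float)
    out["target_sbp"] = feats["sbp"].to_numpy(float)
    out["target_dbp"] = feats["dbp"].to_numpy(float)
    df = pd.DataFrame(out)
    df["subject_id"] = feats["subject_id"].to_numpy()
    return df


def pair_feature_columns(df: pd.DataFrame) -> list[str]:
    """Model-input columns of a sample table (everything but metadata)."""
    return [c for c in df.columns if c not in META_COLUMNS]


def subject_bp_stats(features: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean/std of reference SBP and DBP over valid windows."""
    g = features.groupby("subject_id")
    return pd.DataFrame(
        dict(
            sbp_mean=g["sbp"].mean(), sbp_std=g["sbp"].std(ddof=0),
            dbp_mean=g["dbp"].mean(), dbp_std=g["dbp"].std(ddof=0),
        )
    ).reset_index()


def stratified_subject_split(
    per_subject_stats: pd.DataFrame,
    frac: float = 0.8,
    seed: int = 0,
    n_bins: int = 4,
    max_attempts: int = 100,
) -> SplitSpec:
    """Subject-level stratified 80/20 split.

    Subjects are binned into quantile strata of their mean SBP and sampled
    proportionally within each stratum.  Candidate draws (derived
    deterministically from ``seed``) are accepted once the train/test means
    of per-subject SBP differ by less than half the pooled SD; otherwise the
    best candidate is kept.  Fewer than five subjects fall back to a plain
    random split with a warning.
    """
    stats = per_subject_stats.sort_values("subject_id").reset_index(drop=True)
    ids = stats["subject_id"].to_numpy()
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two subjects to split")
    rng_root = np.random.default_rng(seed)
    if n < 5:
        warnings.warn("too few subjects to stratify; plain random split")
        perm = rng_root.permutation(n)
        n_tr = max(int(round(frac * n)), 1)
        return SplitSpec(sorted(ids[perm[:n_tr]]), sorted(ids[perm[n_tr:]]), frac, seed)

    order = stats.sort_values(
        ["sbp_mean", "sbp_std", "dbp_mean", "dbp_std", "subject_id"]
    ).index.to_numpy()
    # quantile strata on mean SBP (rank-based, so ties are harmless)
    strata = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        strata[chunk] = b

    pooled_sd = float(stats["sbp_mean"].std(ddof=0))
    # largest-remainder allocation of the train quota across strata, so the
    # overall train size is exactly round(frac * n) and the test set is
    # never empty
    sizes = np.array([int(np.sum(strata == b)) for b in range(n_bins)])
    quotas = frac * sizes
    alloc = np.floor(quotas).astype(int)
    n_train_total = min(max(int(round(frac * n)), 1), n - 1)
    order_rem = np.argsort(-(quotas - alloc), kind="stable")
    k = 0
    while alloc.sum() < n_train_total:
        b = order_rem[k % n_bins]
        if alloc[b] < sizes[b]:
            alloc[b] += 1
        k += 1
    while alloc.sum() > n_train_total:
        b = order_rem[::-1][k % n_bins]
        if alloc[b] > 0:
            alloc[b] -= 1
        k += 1
    best: tuple[float, list, list] | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        train_idx: list[int] = []
        for b in range(n_bins):
            members = np.flatnonzero(strata == b)
            train_idx.extend(rng.choice(members, size=int(alloc[b]), replace=False))
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
        if train_mask.all() or not train_mask.any():
            continue
        diff = abs(
            stats.loc[train_mask, "sbp_mean"].mean()
            - stats.loc[~train_mask, "sbp_mean"].mean()
        )
        score = diff / pooled_sd if pooled_sd > 0 else 0.0
        if best is None or score < best[0]:
            best = (score, sorted(ids[train_mask]), sorted(ids[~train_mask]))
        if score < 0.5:
            break
    assert best is not None
    if best[0] >= 0.5:
        logger.warning("stratified split imbalance %.2f pooled SD", best[0])
    return SplitSpec(best[1], best[2], frac, seed)


def split_to_json(split: SplitSpec) -> str:
    return json.dumps(
        dict(train=list(split.train_subjects), test=list(split.test_subjects),
             train_fraction=split.train_fraction, seed=split.seed),
        indent=2,
    )
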