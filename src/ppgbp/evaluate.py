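"""Absolute-accuracy and trending-ability evaluation.

Absolute accuracy is summarised by the mean error (ME) and the standard
deviation of the error (STDE) of estimate minus reference, cohort-wise and
per subject.  Trending ability compares reference and estimated BP *changes*:
all window pairs whose reference change is at least 20% of the earlier
window's value form trend pairs, split into rapid (<= 3 min) and slow
(> 3 min) time spans.  Direction agreement is the four-quadrant concordance
rate plus the Pearson correlation; amplitude agreement uses the polar-plot
statistics, where each pair maps to a radius ``(d_inv + d_est)/2`` and an
angle measuring the drift from the identity line, with pairs of negative
mean change mirrored through the origin so like-direction changes compare.
"""

from __future__ import annotations

import json
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import ErrorReport, TrendPair, TrendReport

logger = logging.getLogger(__name__)


def error_stats(
    est: np.ndarray,
    ref: np.ndarray,
    subjects: np.ndarray | None = None,
    split: str = "test",
) -> ErrorReport:
    """ME / STDE of ``est - ref`` (mmHg), with per-subject summaries."""
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must be aligned")
    n = est.size
    if n <= 1:
        raise ValueError("need more than one sample for error statistics")
    err = est - ref
    per_subject: dict[str, tuple[float, float]] = {}
    if subjects is not None:
        subjects = np.asarray(subjects)
        for sid in np.unique(subjects):
            e = err[subjects == sid]
            per_subject[str(sid)] = (
                float(e.mean()),
                float(e.std(ddof=1)) if e.size > 1 else 0.0,
            )
    return ErrorReport(float(err.mean()), float(err.std(ddof=1)), n, per_subject, split)


def extract_changes(
    times: np.ndarray,
    series_ref: np.ndarray,
    series_est: np.ndarray,
    rel_threshold: float = 0.20,
    subject_id: str = "",
) -> list[TrendPair]:
    """Trend pairs from one subject's windowed reference/estimate series.

    For every ordered window pair (i < j) the reference change
    ``d_inv = ref_j - ref_i`` is retained iff ``|d_inv| / ref_i >=
    rel_threshold`` (boundary included); ``d_est`` is the estimate change at
    the same windows.  Non-positive baselines are skipped with a warning.
    """
    times = np.asarray(times, float)
    ref = np.asarray(series_ref, float)
    est = np.asarray(series_est, float)
    pairs: list[TrendPair] = []
    n = ref.size
    for i in range(n - 1):
        base = ref[i]
        if base <= 0:
            warnings.warn(f"non-positive baseline reference {base} skipped")
            continue
        for j in range(i + 1, n):
            d_inv = ref[j] - base
            if abs(d_inv) / base >= rel_threshold - 1e-12:
                pairs.append(
                    TrendPair(float(d_inv), float(est[j] - est[i]),
                              float(times[j] - times[i]), subject_id)
                )
    return pairs


def bin_pairs(
    pairs: list[TrendPair], bin_edge: float = 180.0
) -> dict[str, list[TrendPair]]:
    """Split trend pairs into rapid (dt <= bin_edge) and slow bins."""
    return {
        "<=3min": [p for p in pairs if p.dt <= bin_edge],
        ">3min": [p for p in pairs if p.dt > bin_edge],
    }


def four_quadrant(pairs: list[TrendPair]) -> tuple[float, float]:
    """Concordance rate (%) and Pearson r of (d_inv, d_est) pairs.

    A pair is concordant when both changes share the same sign; a zero
    estimated change counts as discordant unless the reference change is
    zero too.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two trend pairs")
    d_inv = np.array([p.d_inv for p in pairs])
    d_est = np.array([p.d_est for p in pairs])
    concordant = np.sign(d_inv) == np.sign(d_est)
    cr = 100.0 * float(np.mean(concordant))
    r = float(sstats.pearsonr(d_inv, d_est).statistic)
    return cr, r


def _angles_deg(pairs: list[TrendPair]) -> tuple[np.ndarray, np.ndarray, int]:
    """Polar angles (deviation from identity line, deg) and radii.

    Pairs with negative mean change are mirrored through the origin; exact
    zero-magnitude pairs are excluded.  Returns (theta, radius, n_excluded).
    """
    theta, radius = [], []
    excluded = 0
    for p in pairs:
        if p.d_inv == 0 and p.d_est == 0:
            excluded += 1
            logger.debug("zero-magnitude trend pair excluded")
            continue
        di, de = p.d_inv, p.d_est
        if (di + de) / 2 < 0:
            di, de = -di, -de
        th = math.degrees(math.atan2(de, di)) - 45.0
        if th <= -180.0:
            th += 360.0
        elif th > 180.0:
            th -= 360.0
        theta.append(th)
        radius.append((di + de) / 2)
    return np.asarray(theta), np.asarray(radius), excluded


def polar_stats(
    pairs: list[TrendPair], limit: float = 30.0, timespan_bin: str = "all"
) -> TrendReport:
    """Polar-plot trending statistics.

    Angular concordance rate at ``+/- limit`` degrees, angular bias (mean
    angle), angular sd, and 95% radial limits of agreement
    ``bias +/- 1.96 sd``.  Also fills the four-quadrant CR and Pearson r so a
    single report carries the full trending summary.
    """
    theta, _, _ = _angles_deg(pairs)
    if theta.size < 2:
        raise ValueError("need at least two nonzero trend pairs")
    cr, r = four_quadrant(pairs)
    bias = float(theta.mean())
    sd = float(theta.std(ddof=1))
    return TrendReport(
        cr=cr,
        pearson_r=r,
        angular_cr_30=100.0 * float(np.mean(np.abs(theta) <= limit)),
        angular_bias=bias,
        angular_sd=sd,
        radial_loa_95=(bias - 1.96 * sd, bias + 1.96 * sd),
        n_pairs=int(theta.size),
        timespan_bin=timespan_bin,
    )


def trend_report_frame(reports: dict[str, TrendReport]) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        rows.append(
            dict(series=name, timespan=rep.timespan_bin, n=rep.n_pairs, cr=rep.cr,
                 pearson_r=rep.pearson_r, angular_cr_30=rep.angular_cr_30,
                 angular_bias=rep.angular_bias, angular_sd=rep.angular_sd,
                 loa_low=rep.radial_loa_95[0], loa_high=rep.radial_loa_95[1])
        )
    return pd.DataFrame(rows)


def render_reports(
    reports: dict[str, tuple[TrendReport, list[TrendPair]]],
    outdir,
    fmt: str = "svg",
) -> dict:
    """Four-quadrant scatter + polar plot per report; returns metadata.

    Empty pair lists are skipped with an ``n=0`` row in the metadata table.
    The polar plot draws the +/-30 deg radial limits, the angular-bias line
    and the 95% limit-of-agreement lines.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict[str, dict] = {}
    for name, (rep, pairs) in reports.items():
        if rep is None or not pairs:
            meta[name] = dict(n=0)
            continue
        d_inv = np.array([p.d_inv for p in pairs])
        d_est = np.array([p.d_est for p in pairs])
        theta, radius, _ = _angles_deg(pairs)
        fig, (ax1, ax2) = plt.subplots(
            1, 2, figsize=(10, 4.5), subplot_kw={}, constrained_layout=True
        )
        lim = 1.05 * max(np.abs(d_inv).max(), np.abs(d_est).max())
        ax1.scatter(d_inv, d_est, s=8, alpha=0.5)
        ax1.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
        ax1.axhline(0, color="k", lw=0.6)
        ax1.axvline(0, color="k", lw=0.6)
        ax1.set_xlabel("reference change (mmHg)")
        ax1.set_ylabel("estimated change (mmHg)")
        ax1.set_title(f"{name}: CR {rep.cr:.1f}%, r = {rep.pearson_r:.2f}")

        ax2.remove()
        ax2 = fig.add_subplot(1, 2, 2, projection="polar")
        ax2.scatter(np.radians(theta), radius, s=8, alpha=0.5)
        rmax = 1.05 * radius.max()
        for ang, style in ((30, "-"), (-30, "-")):
            ax2.plot([math.radians(ang)] * 2, [0, rmax], "k" + style, lw=1.0)
        ax2.plot([math.radians(rep.angular_bias)] * 2, [0, rmax], "r-.", lw=1.0)
        for ang in rep.radial_loa_95:
            ax2.plot([math.radians(ang)] * 2, [0, rmax], "r--", lw=0.8)
        ax2.set_thetamin(-90)
        ax2.set_thetamax(90)
        ax2.set_title(f"angular CR30 {rep.angular_cr_30:.1f}%")
        path = outdir / f"trend_{name}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        meta[name] = dict(
            n=rep.n_pairs, cr=rep.cr, pearson_r=rep.pearson_r,
            angular_cr_30=rep.angular_cr_30, angular_bias=rep.angular_bias,
            angular_sd=rep.angular_sd, loa=list(rep.radial_loa_95),
            figure=str(path),
        )
    (outdir / "trend_reports.json").write_text(json.dumps(meta, indent=2))
    return meta
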