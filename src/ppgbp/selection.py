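"""L1-penalised feature selection and permutation feature relevance.

Feature selection fits a Lasso over a log-spaced grid of 100 penalty weights
from the analytic lambda_max (the smallest penalty with an all-zero solution)
down to lambda_max * 1e-4, choosing the penalty that minimises 10-fold
cross-validated mean squared error with folds stratified by subject, then
refits on the full training set.  Relevance of each input is scored by the
permutation importance procedure: permute one feature's values across all
test samples, re-predict, and record the relative increase of the error
standard deviation (STDE); repeat 100 times per feature and report the mean
and sd over repetitions.

The permutation streams are derived deterministically as
``default_rng([seed, feature_index])`` with one ``permutation(n)`` draw per
repetition, which makes the report bit-reproducible and independently
recomputable from the same seed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import GroupKFold

from .types import SelectionResult

logger = logging.getLogger(__name__)


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and stds (std 1 for constant columns) from training data."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest L1 penalty (sklearn scaling) with an all-zero coefficient
    vector: ``max |X_s' (y - mean y)| / n`` on standardized columns."""
    mean, std = standardize_fit(X)
    Xs = (X - mean) / std
    yc = y - y.mean()
    return float(np.max(np.abs(Xs.T @ yc)) / len(y))


def _group_folds(groups: np.ndarray, k: int):
    uniq = np.unique(groups)
    k_eff = min(k, len(uniq))
    if k_eff < 2:
        raise ValueError("need at least two subjects for grouped CV")
    return list(GroupKFold(n_splits=k_eff).split(np.zeros(len(groups)), groups=groups))


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    k: int = 10,
    n_alphas: int = 100,
    eps: float = 1e-4,
    max_iter: int = 5000,
    max_cv_samples: int = 20000,
    seed: int = 0,
) -> SelectionResult:
    """Select the feature subset with nonzero Lasso coefficients.

    ``X`` is the raw (unstandardized) training feature table; standardization
    constants are computed here on the training data only.  Constant columns
    are dropped with a warning before the fit.  On very large sample tables
    the penalty is cross-validated on a seeded row subsample
    (``max_cv_samples``) and the final model is refit on the full table.
    """
    names = list(X.columns)
    Xm = X.to_numpy(float)
    y = np.asarray(y, float)
    const = [names[j] for j in range(Xm.shape[1]) if np.ptp(Xm[:, j]) == 0]
    if const:
        warnings.warn(f"dropping constant feature column(s): {const}")
        keep = [j for j, nm in enumerate(names) if nm not in const]
        Xm = Xm[:, keep]
        names = [names[j] for j in keep]
    mean, std = standardize_fit(Xm)
    Xs = (Xm - mean) / std
    lmax = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))
    alphas = np.logspace(np.log10(lmax), np.log10(lmax * eps), n_alphas)
    groups = np.asarray(groups)
    if len(y) > max_cv_samples:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(y), size=max_cv_samples, replace=False))
    else:
        idx = np.arange(len(y))
    cv = _group_folds(groups[idx], k)
    model = LassoCV(alphas=alphas, cv=cv, max_iter=max_iter, tol=1e-3, n_jobs=None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny alphas
        model.fit(Xs[idx], y[idx])
    refit = Lasso(alpha=model.alpha_, max_iter=max_iter)
    refit.fit(Xs, y)
    coefs = dict(zip(names, refit.coef_))
    selected = sorted(
        (nm for nm, c in coefs.items() if c != 0.0),
        key=lambda nm: -abs(coefs[nm]),
    )
    logger.info("lasso selected %d/%d features at lambda=%.4g", len(selected), len(names), model.alpha_)
    return SelectionResult(
        selected_features=selected,
        lambda_=float(model.alpha_),
        coefficients=coefs,
        n_selected=len(selected),
        intercept=float(refit.intercept_),
        dropped_constant=const,
    )


def selection_path_sizes(
    X: pd.DataFrame, y: np.ndarray, alphas: np.ndarray, max_iter: int = 5000
) -> np.ndarray:
    """Number of nonzero coefficients at each penalty (descending alphas)."""
    Xm = X.to_numpy(float)
    mean, std = standardize_fit(Xm)
    Xs = (Xm - mean) / std
    sizes = []
    for a in alphas:
        m = Lasso(alpha=a, max_iter=max_iter).fit(Xs, np.asarray(y, float))
        sizes.append(int(np.count_nonzero(m.coef_)))
    return np.asarray(sizes)


def permutation_relevance(
    model,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    n_rep: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature relevance on a held-out test set.

    For each feature, each repetition permutes that feature's values across
    all test samples, recomputes predictions and records
    ``(STDE_permuted - STDE_original) / STDE_original``.  Returns a frame
    indexed by feature with ``mean_relevance``, ``sd_relevance`` and
    ``n_permutations``, ranked by mean relevance descending (ties broken by
    feature name).

    ``model`` is anything with a ``predict(DataFrame) -> array`` method.
    """
    y_test = np.asarray(y_test, float)
    base_err = model.predict(X_test) - y_test
    stde0 = float(np.std(base_err, ddof=1))
    if stde0 == 0:
        raise ValueError("degenerate perfect fit: original STDE is zero")
    n = len(X_test)
    rows = []
    for fidx, name in enumerate(X_test.columns):
        rng = np.random.default_rng([int(seed), int(fidx)])
        rels = np.empty(n_rep)
        Xp = X_test.copy()
        col = X_test[name].to_numpy()
        for r in range(n_rep):
            Xp[name] = col[rng.permutation(n)]
            err = model.predict(Xp) - y_test
            rels[r] = (np.std(err, ddof=1) - stde0) / stde0
        rows.append(
            dict(feature=name, mean_relevance=float(rels.mean()),
                 sd_relevance=float(rels.std(ddof=1)), n_permutations=n_rep)
        )
    rep = pd.DataFrame(rows).sort_values(
        ["mean_relevance", "feature"], ascending=[False, True]
    )
    return rep.set_index("feature")


def selection_to_json(res: SelectionResult) -> str:
    """Serialize a selection result (selected names, penalty, coefficients)."""
    import json

    return json.dumps(
        dict(
            selected_features=res.selected_features,
            lambda_=res.lambda_,
            n_selected=res.n_selected,
            intercept=res.intercept,
            coefficients=res.coefficients,
            dropped_constant=res.dropped_constant,
        ),
        indent=2,
    )


def rank_report(relevance: pd.DataFrame, top_k: int | None = None, plot_path=None) -> pd.DataFrame:
    """Descending relevance ranking table, optionally with a bar chart.

    Calibration-segment features keep their ``cal.`` prefix so the two
    segments' contributions are distinguishable in the ranking.
    """
    # deterministic order: relevance descending, ties by feature name
    ordered = (
        relevance.reset_index()
        .sort_values(["mean_relevance", "feature"], ascending=[False, True], kind="mergesort")
        .set_index("feature")
    )
    if top_k is not None:
        ordered = ordered.head(top_k)
    ordered = ordered.assign(rank=np.arange(1, len(ordered) + 1))
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, max(2.5, 0.25 * len(ordered))))
        ax.barh(ordered.index[::-1], ordered["mean_relevance"][::-1],
                xerr=ordered["sd_relevance"][::-1], color="#4878d0")
        ax.set_xlabel("relevance (relative STDE increase)")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return ordered
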