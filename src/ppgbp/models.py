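"""BP regression estimators: Lasso, SVR, GPR and the flat baseline.

All models are trained per target (SBP or DBP) on a restricted feature set
and standardized inputs (constants frozen from the training data).
Hyperparameters are tuned with subject-stratified 10-fold cross-validation:
the Lasso penalty over a log-spaced grid, the SVR (RBF kernel scale, box
constraint C and epsilon-band width) by a seeded Bayesian optimization over
log-space, and the GPR noise level and kernel scales by marginal-likelihood
maximisation with L-BFGS restarts.

The flat model is the no-dynamics control: in calibration mode it predicts
the calibration reference value of each sample; in calibration-free mode it
predicts the training-set mean BP.  Its error spread is the BP variability
of the dataset itself, the natural yardstick for the learned models.

Kernel-based models scale poorly with sample count, so their training rows
are capped (seeded subsample); caps are configurable per spec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    WhiteKernel,
)
from sklearn.svm import SVR

from .selection import _group_folds, lasso_select, standardize_fit

logger = logging.getLogger(__name__)

VALID_KINDS = ("lasso", "svr", "gpr", "flat")


@dataclass
class ModelSpec:
    """Declarative description of one estimator run."""

    kind: str
    target: str = "sbp"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        for k, v in self.hyperparameters.items():
            if isinstance(v, (int, float)) and k not in ("cal_mode",) and v <= 0:
                raise ValueError(f"hyperparameter {k} must be positive, got {v}")


@dataclass
class TrainedModel:
    """A fitted estimator plus the plumbing needed to apply it safely."""

    spec: ModelSpec
    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    estimator: object | None = None
    intercept: float = 0.0
    coef: np.ndarray | None = None
    flat_value: float | None = None
    cal_ref_column: str | None = None

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        Xm = X[self.feature_names].to_numpy(float)
        return (Xm - self.mean) / self.std

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """BP estimates (mmHg), one per row of ``X``."""
        if self.spec.kind == "flat":
            if self.cal_ref_column is not None:
                if self.cal_ref_column not in X.columns:
                    raise KeyError(f"missing feature column(s): ['{self.cal_ref_column}']")
                return X[self.cal_ref_column].to_numpy(float).copy()
            return np.full(len(X), float(self.flat_value))
        Xs = self._matrix(X)
        if self.spec.kind == "lasso":
            return Xs @ self.coef + self.intercept
        out = self.estimator.predict(Xs)
        return np.asarray(out, float) + self.intercept


def _subsample(n: int, cap: int | None, seed: int) -> np.ndarray:
    if cap is None or n <= cap:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=cap, replace=False))


def _expected_improvement(gp, Xc: np.ndarray, best: float) -> np.ndarray:
    mu, sd = gp.predict(Xc, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def bayes_minimize(
    objective,
    bounds: list[tuple[float, float]],
    n_init: int = 8,
    n_iter: int = 22,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Seeded Bayesian minimisation with a GP surrogate and expected
    improvement over a random candidate pool.  Returns (best x, best f)."""
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    dim = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    X = lo + rng.random((n_init, dim)) * (hi - lo)
    y = np.array([objective(x) for x in X])
    kernel = ConstantKernel(1.0) * RBF(np.full(dim, 0.5)) + WhiteKernel(1e-3)
    for _ in range(n_iter):
        ys = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False, random_state=int(rng.integers(2**31)))
        Xn = (X - lo) / (hi - lo)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # surrogate hyperparameters at bounds are fine
            gp.fit(Xn, ys)
        cand = rng.random((256, dim))
        ei = _expected_improvement(gp, cand, ys.min())
        xn = cand[int(np.argmax(ei))]
        x = lo + xn * (hi - lo)
        fx = objective(x)
        X = np.vstack([X, x])
        y = np.append(y, fx)
    best = int(np.argmin(y))
    return X[best], float(y[best])


def _cv_mse(make_est, Xs, y, folds) -> float:
    errs = []
    for tr, va in folds:
        est = make_est()
        est.fit(Xs[tr], y[tr])
        errs.append(np.mean((est.predict(Xs[va]) - y[va]) ** 2))
    return float(np.mean(errs))


def fit(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    k: int = 10,
    cal_ref_column: str | None = None,
    max_tune_samples: int = 1500,
    max_train_samples: int | None = 4000,
) -> TrainedModel:
    """Fit one estimator with subject-stratified hyperparameter tuning.

    ``X`` should already be restricted to the selected feature subset.
    ``cal_ref_column`` switches the flat model to calibration mode.
    """
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    if spec.kind == "flat":
        return TrainedModel(
            spec, [], np.zeros(0), np.ones(0),
            flat_value=float(y.mean()), cal_ref_column=cal_ref_column,
        )

    names = list(X.columns)
    Xm = X.to_numpy(float)
    mean, std = standardize_fit(Xm)
    Xs = (Xm - mean) / std

    if spec.kind == "lasso":
        sel = lasso_select(X, y, groups, k=k,
                           n_alphas=int(spec.hyperparameters.get("n_alphas", 100)))
        coef = np.array([sel.coefficients.get(nm, 0.0) for nm in names])
        return TrainedModel(spec, names, mean, std, coef=coef, intercept=sel.intercept)

    # kernel models: tune on a (seeded) subsample, refit on a capped set
    idx_tune = _subsample(len(y), max_tune_samples, spec.seed)
    folds = _group_folds(groups[idx_tune], k)
    Xt, yt = Xs[idx_tune], y[idx_tune]
    y_off = float(yt.mean())

    if spec.kind == "svr":
        hp = spec.hyperparameters

        def make(params):
            logC, logG, logE = params
            return lambda: SVR(kernel="rbf", C=10.0**logC, gamma=10.0**logG, epsilon=10.0**logE)

        if {"C", "gamma", "epsilon"} <= set(hp):
            best = (np.log10(hp["C"]), np.log10(hp["gamma"]), np.log10(hp["epsilon"]))
        else:
            bounds = [(-1.0, 3.5), (-4.0, 0.5), (-2.0, 1.0)]
            budget = int(hp.get("budget", 30))
            n_init = max(min(8, budget - 2), 1)

            def objective(x):
                return _cv_mse(make(x), Xt, yt - y_off, folds)

            best, _ = bayes_minimize(objective, bounds, n_init=n_init,
                                     n_iter=budget - n_init, seed=spec.seed)
        idx_fit = _subsample(len(y), max_train_samples, spec.seed + 1)
        est = make(best)()
        est.fit(Xs[idx_fit], y[idx_fit] - y_off)
        logger.info("svr tuned: C=%.3g gamma=%.3g eps=%.3g",
                    10.0 ** best[0], 10.0 ** best[1], 10.0 ** best[2])
        return TrainedModel(spec, names, mean, std, estimator=est, intercept=y_off)

    # gpr
    hp = spec.hyperparameters
    sigma0 = float(hp.get("sigma", 1.0))
    cap = int(hp.get("max_train_samples", min(max_train_samples or 1000, 1000)))
    idx_fit = _subsample(len(y), cap, spec.seed + 2)
    # squared-exponential (one shared length scale; ARD off to limit
    # overfitting) plus a linear component — the feature-BP relation is
    # dominantly linear and a lone RBF cannot express it at small training
    # caps — plus the white-noise term that carries sigma
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e4))
        * RBF(length_scale=np.sqrt(Xs.shape[1]), length_scale_bounds=(1e-2, 1e4))
        + ConstantKernel(1.0, (1e-4, 1e4)) * DotProduct(1.0)
        + WhiteKernel(sigma0**2, (1e-8, 1e4))
    )
    import warnings as _warnings

    for attempt in range(2):
        try:
            est = GaussianProcessRegressor(
                kernel=kernel, normalize_y=False, random_state=spec.seed,
                n_restarts_optimizer=1 if attempt == 0 else 3,
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # kernel params at bounds are fine
                est.fit(Xs[idx_fit], y[idx_fit] - y.mean())
            break
        except (np.linalg.LinAlgError, ValueError):
            if attempt == 1:
                raise
            kernel = ConstantKernel(1.0) * RBF(1.0) + WhiteKernel(1.0)
    return TrainedModel(spec, names, mean, std, estimator=est, intercept=float(y.mean()))


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(X)
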