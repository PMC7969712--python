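"""Level-0 learners: support vector regression, kernel ridge regression and
elastic net, operating on rows of the genomic relationship matrix as
feature vectors, plus a deterministic inner-CV grid search.

SVR minimises ½‖w‖² + C·Σ L_ε(f(x_i)−y_i) with the ε-insensitive loss and a
Gaussian kernel k(x,x') = exp(−γ‖x−x'‖²); its predictor is the kernel
expansion f(x) = Σ (α̂_i−α_i) k(x,x_i) + b. KRR solves the ridge problem in
feature space with the closed-form dual (K+λI)^{-1}y. The elastic net is a
linear model penalised by a mix of L1 and L2 norms. Fitting is delegated to
scikit-learn; this module fixes conventions (our γ is sklearn's ``gamma``,
our λ is KernelRidge's ``alpha``, our (α, ρ) are ElasticNet's
(``alpha``, ``l1_ratio``)) and wraps the estimators in a uniform
fit/predict surface used by the stacking machinery.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Any

import numpy as np
import pandas as pd
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "SVRParams",
    "KRRParams",
    "ENETParams",
    "FittedLearner",
    "fit_svr",
    "fit_krr",
    "fit_enet",
    "fit_learner",
    "grid_search",
    "default_grid",
]


@dataclasses.dataclass(frozen=True)
class SVRParams:
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | str = "auto"  # "auto" = 1/n_features

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclasses.dataclass(frozen=True)
class KRRParams:
    ridge_lambda: float = 1.0
    kernel: str = "linear"  # linear | gaussian | polynomial | precomputed
    gamma: float | None = None
    degree: int = 3

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.kernel not in ("linear", "gaussian", "polynomial", "precomputed"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclasses.dataclass(frozen=True)
class ENETParams:
    alpha: float = 1e-2
    rho: float = 0.5  # l1 ratio

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


Params = SVRParams | KRRParams | ENETParams


@dataclasses.dataclass
class FittedLearner:
    """A fitted level-0 model with a deterministic ``predict``."""

    kind: str
    params: Params
    estimator: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_features(np.asarray(X, dtype=float))
        return np.asarray(self.estimator.predict(X), dtype=float)


def _check_features(X: np.ndarray) -> np.ndarray:
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    return X


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = _check_features(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("targets contain non-finite values")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} targets")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    return X, y


def fit_svr(X: np.ndarray, y: np.ndarray, p: SVRParams = SVRParams()) -> FittedLearner:
    """ε-insensitive Gaussian-kernel SVR. γ='auto' means 1/n_features."""
    X, y = _check_xy(X, y)
    gamma = 1.0 / X.shape[1] if p.gamma == "auto" else p.gamma
    est = _SkSVR(kernel="rbf", C=p.C, epsilon=p.epsilon, gamma=gamma, tol=1e-6)
    est.fit(X, y)
    return FittedLearner("svr", p, est)


class SingularKernelError(np.linalg.LinAlgError):
    pass


def fit_krr(X: np.ndarray, y: np.ndarray, p: KRRParams = KRRParams()) -> FittedLearner:
    """Kernel ridge regression, f(x) = k'(K+λI)^{-1} y.

    With ``kernel="precomputed"`` X is the training Gram matrix itself and
    prediction takes the (n_new × n_train) cross-kernel block.
    """
    X, y = _check_xy(X, y)
    kernel_map = {
        "linear": dict(kernel="linear"),
        "gaussian": dict(kernel="rbf", gamma=p.gamma),
        "polynomial": dict(kernel="polynomial", gamma=p.gamma, degree=p.degree),
        "precomputed": dict(kernel="precomputed"),
    }
    est = KernelRidge(alpha=p.ridge_lambda, **kernel_map[p.kernel])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)  # sklearn's singular warn
            est.fit(X, y)
    except (np.linalg.LinAlgError, UserWarning) as exc:
        raise SingularKernelError(
            f"K + λI singular at λ={p.ridge_lambda}; use λ > 0"
        ) from exc
    return FittedLearner("krr", p, est)


def fit_enet(X: np.ndarray, y: np.ndarray, p: ENETParams = ENETParams()) -> FittedLearner:
    """Elastic net by coordinate descent (ordinary least squares at α=0)."""
    X, y = _check_xy(X, y)
    if p.alpha == 0.0:
        est = LinearRegression()
        est.fit(X, y)
        return FittedLearner("enet", p, est)
    est = ElasticNet(alpha=p.alpha, l1_ratio=p.rho, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        est.fit(X, y)
    if est.n_iter_ is not None and est.n_iter_ >= 50_000:
        warnings.warn(
            f"elastic net hit max_iter without reaching tol (alpha={p.alpha}, rho={p.rho})",
            RuntimeWarning,
            stacklevel=2,
        )
    return FittedLearner("enet", p, est)


_FITTERS = {"svr": fit_svr, "krr": fit_krr, "enet": fit_enet}
_PARAM_CLS = {"svr": SVRParams, "krr": KRRParams, "enet": ENETParams}


def fit_learner(kind: str, X: np.ndarray, y: np.ndarray, params: Params | None = None) -> FittedLearner:
    if kind not in _FITTERS:
        raise ValueError(f"unknown learner kind {kind!r}; expected one of {sorted(_FITTERS)}")
    if params is None:
        params = _PARAM_CLS[kind]()
    return _FITTERS[kind](X, y, params)


def default_grid(kind: str, n_features: int) -> list[Params]:
    """Default hyperparameter lattices (overridable everywhere)."""
    n = n_features
    if kind == "svr":
        return [
            SVRParams(C=C, epsilon=eps, gamma=g)
            for C in (0.1, 1.0, 10.0, 100.0)
            for eps in (0.01, 0.1, 0.5)
            for g in (1.0 / n, 1.0 / (2 * n), 10.0 / n)
        ]
    if kind == "krr":
        lambdas = (1e-3, 1e-2, 0.1, 1.0, 10.0)
        grid: list[Params] = [KRRParams(ridge_lambda=l, kernel="linear") for l in lambdas]
        grid += [KRRParams(ridge_lambda=l, kernel="gaussian", gamma=1.0 / n) for l in lambdas]
        return grid
    if kind == "enet":
        return [
            ENETParams(alpha=a, rho=r)
            for a in np.logspace(-4, 0, 5)
            for r in (0.1, 0.5, 0.9)
        ]
    raise ValueError(f"unknown learner kind {kind!r}")


def grid_search(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: list[Params] | None = None,
    k_inner: int = 5,
    seed: int = 0,
) -> tuple[Params, pd.DataFrame]:
    """Pick the lattice point maximising mean inner-k-fold Pearson accuracy.

    Ties break in favour of the first point in lattice order; lattice points
    whose fit fails (or whose fold accuracy is undefined) score −inf and the
    search continues. Deterministic given ``seed``.
    """
    from .evaluation import pearson_accuracy
    from .stacking import make_fold_plan

    X, y = _check_xy(X, y)
    if grid is None:
        grid = default_grid(kind, X.shape[1])
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if len(grid) == 1:
        return grid[0], pd.DataFrame({"params": [grid[0]], "score": [np.nan]})

    plan = make_fold_plan(X.shape[0], min(k_inner, X.shape[0] // 2), seed)
    scores = []
    for params in grid:
        fold_r = []
        try:
            for f in range(plan.k):
                test = plan.assignment == f
                model = fit_learner(kind, X[~test], y[~test], params)
                fold_r.append(pearson_accuracy(y[test], model.predict(X[test])))
            scores.append(float(np.mean(fold_r)))
        except Exception as exc:  # scored -inf, search continues
            warnings.warn(
                f"grid point {params} failed during inner CV: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
            scores.append(-np.inf)
    table = pd.DataFrame({"params": grid, "score": scores})
    best = int(np.argmax(scores))
    return grid[best], table
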