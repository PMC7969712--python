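"""Stacking ensemble for genomic prediction (the SELF model).

Two-step flow: (1) each base learner produces *metadata* — out-of-fold
predictions on the training individuals from a k-fold split (default k=5),
so row i of the metadata was made by a model that never saw y_i; (2) an
ordinary-least-squares meta-learner regresses y on the metadata and
combines base-learner predictions on new individuals. Features throughout
are rows of the genomic relationship matrix: training features are
G[train, train]; test features are G[test, train].

The model-object surface follows the usual fit/results split::

    model = StackingModel(y_train, X_train, learners=default_learners())
    res = model.fit(seed=42)
    gebv = res.predict(X_test)
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from . import learners as _learners
from .learners import FittedLearner, Params

__all__ = [
    "FoldPlan",
    "Metadata",
    "LearnerSpec",
    "default_learners",
    "make_fold_plan",
    "generate_metadata",
    "fit_meta_ols",
    "StackingModel",
    "StackingResults",
    "self_fit_predict",
]


@dataclasses.dataclass
class FoldPlan:
    """Balanced random partition of n individuals into k folds."""

    n: int
    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape != (self.n,):
            raise ValueError("assignment length must equal n")
        sizes = np.bincount(self.assignment, minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1 or sizes.min() == 0:
            raise ValueError("fold sizes must differ by at most 1 and cover all folds")

    def fold_indices(self, f: int) -> np.ndarray:
        return np.where(self.assignment == f)[0]


class InvalidPlanError(ValueError):
    pass


def make_fold_plan(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Uniformly random balanced k-fold assignment, deterministic in seed."""
    if not 2 <= k <= n:
        raise InvalidPlanError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    # fold f receives positions f, f+k, f+2k, ... of the permutation;
    # sizes differ by at most one
    assignment[perm] = np.arange(n) % k
    return FoldPlan(n=n, k=k, assignment=assignment, seed=seed)


@dataclasses.dataclass
class LearnerSpec:
    """Recipe for one base learner: a kind plus fixed params or a grid.

    With a grid, hyperparameters are chosen by inner k-fold search on
    whatever training rows the spec is fitted to — inside each metadata
    fold this touches only train∖fold, so the held-out fold never leaks.
    Custom learners (mocks, plug-ins) subclass and override ``fit``: any
    object returned needs only a ``predict(X)`` method.
    """

    kind: str
    params: Params | None = None
    grid: list[Params] | None = None
    k_inner: int = 5
    tune_once: bool = False  # tune on the whole training portion, reuse per fold

    @property
    def name(self) -> str:
        return self.kind

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedLearner:
        params = self.params
        if self.grid is not None:
            params, _ = _learners.grid_search(
                self.kind, X, y, self.grid, k_inner=self.k_inner, seed=seed
            )
        return _learners.fit_learner(self.kind, X, y, params)

    def tuned(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "LearnerSpec":
        """Resolve the grid to fixed params by one search on (X, y)."""
        if self.grid is None:
            return self
        params, _ = _learners.grid_search(
            self.kind, X, y, self.grid, k_inner=self.k_inner, seed=seed
        )
        return dataclasses.replace(self, params=params, grid=None)


def default_learners(grids: bool = False, n_features: int | None = None) -> list[LearnerSpec]:
    """The canonical SVR + KRR + ENET trio.

    ``grids=True`` attaches the default hyperparameter lattices (requires
    ``n_features`` for the SVR/KRR bandwidth candidates).
    """
    kinds = ["svr", "krr", "enet"]
    if not grids:
        return [LearnerSpec(k) for k in kinds]
    if n_features is None:
        raise ValueError("n_features required to build default grids")
    return [LearnerSpec(k, grid=_learners.default_grid(k, n_features)) for k in kinds]


@dataclasses.dataclass
class Metadata:
    """Base-learner prediction matrices feeding the meta-learner.

    ``train_meta[i, j]`` is learner j's out-of-fold prediction for training
    individual i; ``test_meta`` holds predictions for the test individuals
    from learners refit on the full training set (or fold-model averages).
    """

    train_meta: np.ndarray
    test_meta: np.ndarray | None
    learner_names: list[str]


def generate_metadata(
    specs: Sequence[LearnerSpec],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray | None,
    plan: FoldPlan,
    seed: int = 0,
    average_folds: bool = False,
) -> tuple[Metadata, list[object], list[list[object]]]:
    """Out-of-fold metadata plus full-training refits of each base learner.

    For each learner and metadata fold f: fit on train∖f, predict fold f;
    with a grid attached, hyperparameters are re-searched inside train∖f
    (strictly leak-free) unless the spec has ``tune_once``, which searches
    once on the whole training portion and reuses the winner per fold — a
    documented shortcut: the held-out metadata fold then influences tuning,
    though never the outer test set. Test metadata comes from learners
    refit on all training rows (default) or, with ``average_folds``, from
    averaging the k fold models' predictions. Returns (metadata, refit
    learners, per-learner fold models).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if plan.n != X_train.shape[0]:
        raise ValueError(f"fold plan covers {plan.n} individuals, X_train has {X_train.shape[0]}")
    L = len(specs)
    train_meta = np.full((plan.n, L), np.nan)
    test_meta = None if X_test is None else np.zeros((np.asarray(X_test).shape[0], L))
    refits: list[object] = []
    all_fold_models: list[list[object]] = []
    for j, spec in enumerate(specs):
        if spec.tune_once:
            spec = spec.tuned(X_train, y_train, seed=seed)
        fold_models: list[object] = []
        for f in range(plan.k):
            test_mask = plan.assignment == f
            try:
                model = spec.fit(X_train[~test_mask], y_train[~test_mask], seed=seed + f)
            except Exception as exc:
                raise RuntimeError(
                    f"base learner {spec.name!r} failed on metadata fold {f}: {exc}"
                ) from exc
            train_meta[test_mask, j] = model.predict(X_train[test_mask])
            fold_models.append(model)
        refit = spec.fit(X_train, y_train, seed=seed)
        refits.append(refit)
        all_fold_models.append(fold_models)
        if X_test is not None:
            if average_folds:
                test_meta[:, j] = np.mean([m.predict(X_test) for m in fold_models], axis=0)
            else:
                test_meta[:, j] = refit.predict(X_test)
    assert np.isfinite(train_meta).all(), "every train_meta row must be written exactly once"
    return Metadata(train_meta, test_meta, [s.name for s in specs]), refits, all_fold_models


def fit_meta_ols(
    meta: Metadata, y_train: np.ndarray, fit_intercept: bool = True
) -> tuple[float, np.ndarray]:
    """Exact OLS of y on the out-of-fold metadata (no regularisation).

    Solved by SVD least squares (rank-revealing); rank-deficient metadata
    — e.g. two identical base learners — yields the minimum-norm solution
    with a warning. Returns (intercept, weights)."""
    y = np.asarray(y_train, dtype=float)
    Z = meta.train_meta
    if Z.shape[0] <= Z.shape[1] + 1:
        raise ValueError("need n_train > number of base learners + 1 for OLS")
    if fit_intercept:
        Zd = np.column_stack([np.ones(Z.shape[0]), Z])
    else:
        Zd = Z
    coef, _, rank, _ = np.linalg.lstsq(Zd, y, rcond=None)
    if rank < Zd.shape[1]:
        warnings.warn(
            "metadata design is rank deficient; using the minimum-norm OLS solution",
            RuntimeWarning,
            stacklevel=2,
        )
    if fit_intercept:
        return float(coef[0]), coef[1:]
    return 0.0, coef


class StackingModel:
    """SELF: stacked SVR/KRR/ENET with an OLS meta-learner.

    Parameters
    ----------
    y : array-like, training phenotypes (pre-corrected).
    X : array-like, training features — rows of the GRM over the training
        columns.
    learners : base-learner specs (default: SVR, KRR, ENET at their default
        hyperparameters; pass specs with grids for tuned fits).
    n_meta_folds : folds used to generate metadata (default 5).
    fit_intercept : include an intercept in the meta-regression.
    average_folds : derive test metadata by averaging fold models instead of
        refitting on the full training set.
    """

    def __init__(
        self,
        y,
        X,
        learners: Sequence[LearnerSpec] | None = None,
        n_meta_folds: int = 5,
        fit_intercept: bool = True,
        average_folds: bool = False,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        self.learners = list(learners) if learners is not None else default_learners()
        self.n_meta_folds = n_meta_folds
        self.fit_intercept = fit_intercept
        self.average_folds = average_folds

    def fit(self, seed: int = 0) -> "StackingResults":
        plan = make_fold_plan(self.X.shape[0], self.n_meta_folds, seed)
        meta, refits, fold_models = generate_metadata(
            self.learners, self.X, self.y, None, plan,
            seed=seed, average_folds=self.average_folds,
        )
        intercept, weights = fit_meta_ols(meta, self.y, self.fit_intercept)
        return StackingResults(self, plan, meta, refits, fold_models, intercept, weights)


@dataclasses.dataclass
class StackingResults:
    """Fitted SELF model: refit base learners + meta-learner coefficients."""

    model: StackingModel
    fold_plan: FoldPlan
    metadata: Metadata
    base_learners: list[object]
    fold_models: list[list[object]]
    intercept: float
    weights: np.ndarray

    def base_predictions(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if self.model.average_folds:
            return np.column_stack(
                [np.mean([m.predict(X_new) for m in fms], axis=0) for fms in self.fold_models]
            )
        return np.column_stack([m.predict(X_new) for m in self.base_learners])

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted GEBVs: intercept + base-prediction matrix · weights."""
        return self.intercept + self.base_predictions(X_new) @ self.weights

    def fittedvalues(self) -> np.ndarray:
        return self.intercept + self.metadata.train_meta @ self.weights

    def summary(self) -> str:
        lines = [
            "Stacking ensemble (OLS meta-learner)",
            f"  n_train = {self.model.X.shape[0]}, metadata folds = {self.fold_plan.k}",
            f"  intercept = {self.intercept: .6f}",
        ]
        for name, w in zip(self.metadata.learner_names, self.weights):
            lines.append(f"  weight[{name}] = {w: .6f}")
        return "\n".join(lines)


def self_fit_predict(
    X_train,
    y_train,
    X_test,
    learners: Sequence[LearnerSpec] | None = None,
    n_meta_folds: int = 5,
    seed: int = 0,
    fit_intercept: bool = True,
    average_folds: bool = False,
) -> np.ndarray:
    """One-shot SELF: generate metadata, fit the OLS meta-learner, predict."""
    res = StackingModel(
        y_train, X_train, learners,
        n_meta_folds=n_meta_folds,
        fit_intercept=fit_intercept,
        average_folds=average_folds,
    ).fit(seed=seed)
    return res.predict(np.asarray(X_test, dtype=float))
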