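"""K-fold cross-validation of genomic prediction methods.

Accuracy is the Pearson correlation r = cov(y, y_pre)/√(var(y)·var(y_pre))
between corrected phenotypes and predicted GEBVs in each held-out fold;
the protocol reports the mean ± sd of r over k folds (default k = 20).
Method comparisons share one fold plan so every method sees identical
train/test splits (a paired comparison).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bayesb import BayesB, BayesBConfig
from .genio import GenotypeMatrix
from .gblup import gblup_predict, reml_variance_components
from .grm import GRM, vanraden_grm
from .learners import Params
from .stacking import FoldPlan, LearnerSpec, StackingModel, default_learners, make_fold_plan

__all__ = [
    "CVResult",
    "MethodSpec",
    "pearson_accuracy",
    "cross_validate",
    "compare_methods",
]


class ConstantVectorError(ValueError):
    pass


def pearson_accuracy(y, y_pre) -> float:
    """Sample Pearson correlation between phenotypes and predictions.

    Raises on constant inputs rather than silently returning 0."""
    y = np.asarray(y, dtype=float)
    y_pre = np.asarray(y_pre, dtype=float)
    if y.shape != y_pre.shape or y.ndim != 1:
        raise ValueError("y and y_pre must be 1-D and of equal length")
    if len(y) < 3:
        raise ValueError("Pearson accuracy needs at least 3 pairs")
    yc = y - y.mean()
    pc = y_pre - y_pre.mean()
    vy = float(yc @ yc)
    vp = float(pc @ pc)
    if vy == 0.0 or vp == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float((yc @ pc) / np.sqrt(vy * vp))


@dataclasses.dataclass
class CVResult:
    """Per-fold accuracies for one method: the reporting unit (mean ± sd)."""

    method: str
    accuracies: np.ndarray  # length k, NaN where a fold's r was undefined
    seed: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        finite = self.accuracies[np.isfinite(self.accuracies)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("fold accuracies must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.accuracies))

    @property
    def sd(self) -> float:
        """Standard deviation across folds (ddof=1, the ± of the report)."""
        return float(np.nanstd(self.accuracies, ddof=1))

    @property
    def sem(self) -> float:
        k = int(np.isfinite(self.accuracies).sum())
        return self.sd / np.sqrt(k)

    def __repr__(self) -> str:
        return f"CVResult({self.method}: {self.mean:.3f} ± {self.sd:.3f}, k={len(self.accuracies)})"


@dataclasses.dataclass
class MethodSpec:
    """A registered prediction method for the CV harness.

    kinds: ``svr``/``krr``/``enet`` (base learners on GRM rows, with fixed
    ``params`` or a ``grid``), ``self`` (the stacking ensemble over
    ``learners``), ``gblup``, ``bayesb`` (with ``bayesb_config``), or
    ``custom`` with ``predictor(train_idx, test_idx, ctx) -> predictions``
    (used for mocks and plug-ins).
    """

    kind: str
    name: str | None = None
    params: Params | None = None
    grid: list[Params] | None = None
    learners: Sequence[LearnerSpec] | None = None
    n_meta_folds: int = 5
    fit_intercept: bool = True
    average_folds: bool = False
    bayesb_config: BayesBConfig | None = None
    predictor: Callable | None = None

    def __post_init__(self) -> None:
        valid = ("svr", "krr", "enet", "self", "gblup", "bayesb", "custom")
        if self.kind not in valid:
            raise ValueError(f"unknown method kind {self.kind!r}; expected one of {valid}")
        if self.kind == "custom" and self.predictor is None:
            raise ValueError("custom methods need a predictor callable")
        if self.name is None:
            self.name = self.kind


@dataclasses.dataclass
class _CVContext:
    y: np.ndarray
    G: GRM | None
    genotypes: GenotypeMatrix | None


def _predict_fold(
    m: MethodSpec, ctx: _CVContext, train_idx: np.ndarray, test_idx: np.ndarray, seed: int
) -> np.ndarray:
    y_tr = ctx.y[train_idx]
    if m.kind == "custom":
        return np.asarray(m.predictor(train_idx, test_idx, ctx), dtype=float)
    if m.kind == "bayesb":
        v = ctx.genotypes.values
        col_means = v[train_idx].mean(axis=0)  # training-frequency centering
        from .bayesb import bayesb_fit, bayesb_predict

        cfg = m.bayesb_config or BayesBConfig()
        cfg = dataclasses.replace(cfg, seed=seed)
        post = bayesb_fit(v[train_idx] - col_means, y_tr, cfg)
        return bayesb_predict(post, v[test_idx] - col_means)
    Gv = ctx.G.values
    if m.kind == "gblup":
        G_tt = Gv[np.ix_(train_idx, train_idx)]
        vc = reml_variance_components(y_tr, G_tt)
        ids = ctx.G.sample_ids
        return gblup_predict(
            y_tr, ctx.G, [ids[i] for i in train_idx], [ids[i] for i in test_idx], vc
        ).to_numpy()
    X_tr = Gv[np.ix_(train_idx, train_idx)]
    X_te = Gv[np.ix_(test_idx, train_idx)]
    if m.kind == "self":
        learners = list(m.learners) if m.learners is not None else default_learners()
        res = StackingModel(
            y_tr, X_tr, learners,
            n_meta_folds=m.n_meta_folds,
            fit_intercept=m.fit_intercept,
            average_folds=m.average_folds,
        ).fit(seed=seed)
        return res.predict(X_te)
    spec = LearnerSpec(m.kind, params=m.params, grid=m.grid)
    return spec.fit(X_tr, y_tr, seed=seed).predict(X_te)


def _resolve_inputs(genotypes, phenotypes, grm):
    if isinstance(phenotypes, pd.Series):
        y = phenotypes.to_numpy(dtype=float)
    else:
        y = np.asarray(phenotypes, dtype=float)
    G = grm
    if G is None and genotypes is not None:
        G = vanraden_grm(genotypes)
    if G is None:
        raise ValueError("provide genotypes or a precomputed GRM")
    if len(y) != G.n:
        raise ValueError("phenotype length does not match the relationship matrix")
    return _CVContext(y=y, G=G, genotypes=genotypes)


def cross_validate(
    method: MethodSpec,
    genotypes: GenotypeMatrix | None,
    phenotypes,
    k: int = 20,
    seed: int = 0,
    grm: GRM | None = None,
    plan: FoldPlan | None = None,
) -> CVResult:
    """K-fold CV of one method; each fold is held out once and predicted by
    the full pipeline (tuning, metadata, refits) run inside the remaining
    folds only. Folds whose accuracy is undefined (constant predictions)
    are recorded NaN, warned about, and excluded from the mean.
    """
    ctx = _resolve_inputs(genotypes, phenotypes, grm)
    n = len(ctx.y)
    if plan is None:
        if k * 3 > n:
            raise ValueError(
                f"k={k} gives folds of fewer than 3 individuals at n={n}; "
                "Pearson accuracy is undefined on such folds (leave-one-out is not supported)"
            )
        plan = make_fold_plan(n, k, seed)
    accs = np.full(plan.k, np.nan)
    for f in range(plan.k):
        test_idx = plan.fold_indices(f)
        train_idx = np.where(plan.assignment != f)[0]
        pred = _predict_fold(method, ctx, train_idx, test_idx, seed + 97 * f)
        try:
            accs[f] = pearson_accuracy(ctx.y[test_idx], pred)
        except ConstantVectorError:
            warnings.warn(
                f"method {method.name!r}, fold {f}: constant predictions, "
                "accuracy undefined (excluded from the mean)",
                RuntimeWarning,
                stacklevel=2,
            )
    return CVResult(method=method.name, accuracies=accs, seed=plan.seed)


def compare_methods(
    methods: Sequence[MethodSpec],
    genotypes: GenotypeMatrix | None,
    phenotypes,
    k: int = 20,
    seed: int = 0,
    grm: GRM | None = None,
) -> tuple[dict[str, CVResult], pd.DataFrame]:
    """Evaluate several methods on byte-identical folds (paired comparison).

    Returns per-method CVResults and a summary table with mean, sd and the
    pairwise matrix of mean-accuracy differences (row − column).
    """
    ctx = _resolve_inputs(genotypes, phenotypes, grm)
    n = len(ctx.y)
    if k * 3 > n:
        raise ValueError(f"k={k} gives folds of fewer than 3 individuals at n={n}")
    plan = make_fold_plan(n, k, seed)
    results = {
        m.name: cross_validate(m, genotypes, phenotypes, k=k, seed=seed, grm=ctx.G, plan=plan)
        for m in methods
    }
    names = list(results)
    summary = pd.DataFrame(
        {
            "mean": [results[m].mean for m in names],
            "sd": [results[m].sd for m in names],
        },
        index=names,
    )
    for other in names:
        summary[f"diff_vs_{other}"] = summary["mean"] - results[other].mean
    return results, summary
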