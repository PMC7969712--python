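"""GBLUP: the additive mixed model y = 1μ + g + e with g ~ N(0, G σg²),
e ~ N(0, I σe²), G the genomic relationship matrix.

Variance components are estimated by exact REML: with δ = σe²/σg² and
H(δ) = G + δI, the restricted likelihood profiles analytically over μ and
σg², leaving a one-dimensional problem in δ solved on the eigenbasis of G
(one eigendecomposition, then every likelihood evaluation is O(n)).
Prediction for unphenotyped individuals is the usual BLUP

    ĝ_test = G[test, train] (G[train, train] + δI)^{-1} (y − μ̂1),

with μ̂ the GLS mean. Heritability h² = σg²/(σg²+σe²).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .grm import GRM, grm_submatrix

__all__ = [
    "VarianceComponents",
    "reml_variance_components",
    "gblup_predict",
    "GBLUP",
    "GBLUPResults",
]

_LOG_DELTA_LO, _LOG_DELTA_HI = -8.0, 8.0  # search window for log10(σe²/σg²)


@dataclasses.dataclass
class VarianceComponents:
    """Additive genetic and residual variances with derived heritability."""

    sigma_g2: float
    sigma_e2: float
    boundary: bool = False  # optimum pinned at the edge of the δ window

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma_g2 == 0 and self.sigma_e2 == 0:
            raise ValueError("variance components cannot both be zero")

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def delta(self) -> float:
        """Variance ratio σe²/σg² (the GBLUP/ridge shrinkage parameter)."""
        if self.sigma_g2 == 0:
            return np.inf
        return self.sigma_e2 / self.sigma_g2


def _reml_neg2_profile(log10_delta: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """−2 × profiled restricted log-likelihood at δ (up to a constant).

    ``d`` are eigenvalues of G; ``yt``, ``xt`` are y and the all-ones
    design rotated into the eigenbasis.
    """
    delta = 10.0**log10_delta
    w = d + delta
    n = len(d)
    xhx = np.sum(xt * xt / w)
    xhy = np.sum(xt * yt / w)
    yhy = np.sum(yt * yt / w)
    ypy = yhy - xhy**2 / xhx
    sigma_g2 = ypy / (n - 1)
    neg2 = (n - 1) * np.log(sigma_g2) + np.sum(np.log(w)) + np.log(xhx)
    return neg2, sigma_g2


def reml_variance_components(y, G: GRM | np.ndarray, jitter: float = 0.0) -> VarianceComponents:
    """Exact REML for (σg², σe²) in the single-G mixed model.

    1-D optimisation of the profiled restricted likelihood over
    log10 δ ∈ [−8, 8] via the eigendecomposition of G. An estimate pinned
    at either end of the window (h² → 1 or → 0) is flagged ``boundary``.
    """
    Gv = G.values if isinstance(G, GRM) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Gv.shape != (n, n):
        raise ValueError(f"G shape {Gv.shape} does not match {n} phenotypes")
    if n < 10:
        raise ValueError("REML needs at least 10 phenotyped individuals")
    d, U = np.linalg.eigh(Gv + jitter * np.eye(n))
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise np.linalg.LinAlgError(
            f"G is not PSD (min eigenvalue {d.min():.3e}); check the relationship matrix"
        )
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    res = optimize.minimize_scalar(
        lambda ld: _reml_neg2_profile(ld, d, yt, xt)[0],
        bounds=(_LOG_DELTA_LO, _LOG_DELTA_HI),
        method="bounded",
        options={"xatol": 1e-8},
    )
    _, sigma_g2 = _reml_neg2_profile(res.x, d, yt, xt)
    delta = 10.0**res.x
    boundary = res.x < _LOG_DELTA_LO + 0.5 or res.x > _LOG_DELTA_HI - 0.5
    return VarianceComponents(
        sigma_g2=float(sigma_g2), sigma_e2=float(sigma_g2 * delta), boundary=boundary
    )


def restricted_loglik(y, G: GRM | np.ndarray, vc: VarianceComponents) -> float:
    """Profiled restricted log-likelihood (up to an additive constant) at the
    variance ratio implied by ``vc`` — handy for optimizer sanity checks."""
    Gv = G.values if isinstance(G, GRM) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    d, U = np.linalg.eigh(Gv)
    d = np.clip(d, 0.0, None)
    neg2, _ = _reml_neg2_profile(np.log10(vc.delta), d, U.T @ y, U.T @ np.ones(len(y)))
    return -0.5 * neg2


def _solve_mixed(G_tt: np.ndarray, y: np.ndarray, delta: float):
    """GLS mean and the solved vector (G_tt+δI)^{-1}(y−μ̂1), with one
    jittered retry on a singular system."""
    n = len(y)
    H = G_tt + delta * np.eye(n)
    ones = np.ones(n)
    for attempt in (0, 1):
        try:
            Hinv_y = np.linalg.solve(H, y)
            Hinv_1 = np.linalg.solve(H, ones)
            break
        except np.linalg.LinAlgError:
            if attempt == 1:
                raise
            H = H + 1e-8 * np.trace(G_tt) / n * np.eye(n)
    mu = (ones @ Hinv_y) / (ones @ Hinv_1)
    return mu, Hinv_y - mu * Hinv_1


def gblup_predict(
    y_train,
    G: GRM,
    train_ids: list[str],
    test_ids: list[str],
    vc: VarianceComponents,
) -> pd.Series:
    """BLUP of the genetic values of ``test_ids`` given training phenotypes.

    ``y_train`` is aligned with ``train_ids``. Requires σg² > 0.
    """
    if vc.sigma_g2 <= 0:
        raise ValueError("gblup_predict requires sigma_g2 > 0")
    y = np.asarray(y_train, dtype=float)
    if len(y) != len(train_ids):
        raise ValueError("y_train and train_ids lengths differ")
    G_tt = grm_submatrix(G, train_ids, train_ids)
    G_st = grm_submatrix(G, test_ids, train_ids)
    _, sol = _solve_mixed(G_tt, y, vc.delta)
    return pd.Series(G_st @ sol, index=[str(i) for i in test_ids], name="gebv")


class GBLUP:
    """Genomic BLUP model object.

    Parameters
    ----------
    y : pandas Series of phenotypes indexed by sample ID; IDs absent from
        ``y`` (or NaN-valued) are treated as unphenotyped candidates whose
        GEBVs are predicted by ``GBLUPResults.predict``.
    grm : the VanRaden relationship matrix over all individuals.
    """

    def __init__(self, y: pd.Series, grm: GRM):
        if not isinstance(y, pd.Series):
            y = pd.Series(np.asarray(y, dtype=float), index=grm.sample_ids)
        y = y.reindex(grm.sample_ids)
        self.grm = grm
        self.y = y
        self.train_ids = [str(i) for i in y.index[y.notna()]]
        if len(self.train_ids) < 10:
            raise ValueError("GBLUP needs at least 10 phenotyped individuals")

    def fit(self) -> "GBLUPResults":
        G_tt = grm_submatrix(self.grm, self.train_ids, self.train_ids)
        y_tr = self.y.loc[self.train_ids].to_numpy()
        vc = reml_variance_components(y_tr, G_tt)
        mu, sol = _solve_mixed(G_tt, y_tr, vc.delta)
        G_all_t = grm_submatrix(self.grm, self.grm.sample_ids, self.train_ids)
        gebv = pd.Series(G_all_t @ sol, index=self.grm.sample_ids, name="gebv")
        return GBLUPResults(self, vc, float(mu), gebv)


@dataclasses.dataclass
class GBLUPResults:
    model: GBLUP
    vc: VarianceComponents
    mu: float
    gebv: pd.Series  # BLUPs for every individual in the GRM

    def predict(self, ids: list[str] | None = None) -> pd.Series:
        """GEBVs for ``ids`` (default: all unphenotyped individuals)."""
        if ids is None:
            ids = [i for i in self.model.grm.sample_ids if i not in set(self.model.train_ids)]
        return self.gebv.loc[[str(i) for i in ids]]

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "GBLUP (REML, single genomic random effect)",
            f"  n phenotyped = {len(self.model.train_ids)} of {self.model.grm.n}",
            f"  sigma_g^2 = {vc.sigma_g2:.6f}",
            f"  sigma_e^2 = {vc.sigma_e2:.6f}",
            f"  h^2       = {vc.h2:.4f}" + ("  [boundary]" if vc.boundary else ""),
            f"  mu        = {self.mu:.6f}",
        ]
        return "\n".join(lines)
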