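"""Quantitative-trait simulator: biallelic SNPs plus additive phenotypes.

Markers are unlinked sites drawn i.i.d. Binomial(2, p_j) with p_j uniform
over a MAF window. Phenotypes are y = g + e with g a sum of centered
genotype columns times additive QTL effects and e Gaussian noise scaled to
hit a target narrow-sense heritability. Three genetic architectures are
supported, mirroring the classic dairy-trait trichotomy:

``major_gene``
    one QTL carrying a fixed share of the genetic variance plus many small
    effects (milk-fat-percentage-like, DGAT1-style);
``few_moderate``
    a handful of moderate-effect loci plus many small ones (milk-yield-like);
``polygenic``
    many i.i.d. small effects (somatic-cell-score-like).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes"]

ARCHITECTURES = ("major_gene", "few_moderate", "polygenic")

_DEFAULT_N_QTL = {"major_gene": 101, "few_moderate": 500, "polygenic": 500}


class InvalidConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    ``n_qtl`` defaults per architecture: 101 for ``major_gene`` (1 major +
    100 small), 500 for ``few_moderate`` (``n_moderate`` moderate + rest
    small) and 500 for ``polygenic``. Effects are drawn Normal; gamma-like
    heavy tails are not modelled. ``standardize`` rescales y (and g and the
    effects, consistently) to mean 0 / sd 1.
    """

    n_individuals: int
    n_markers: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    architecture: str = "polygenic"
    h2: float = 0.5
    n_qtl: int | None = None
    major_gene_var_share: float = 0.5
    n_moderate: int = 10
    moderate_var_share: float = 0.5
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_markers <= 0:
            raise InvalidConfigError("n_individuals and n_markers must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        if self.architecture not in ARCHITECTURES:
            raise InvalidConfigError(
                f"architecture {self.architecture!r} not in {ARCHITECTURES}"
            )
        if not 0.0 < self.h2 < 1.0:
            raise InvalidConfigError(f"h2={self.h2} must be in (0, 1)")
        if self.n_qtl is None:
            self.n_qtl = min(_DEFAULT_N_QTL[self.architecture], self.n_markers)
        if not 0 < self.n_qtl <= self.n_markers:
            raise InvalidConfigError(f"n_qtl={self.n_qtl} must be in [1, n_markers]")
        if not 0.0 < self.major_gene_var_share < 1.0:
            raise InvalidConfigError("major_gene_var_share must be in (0, 1)")
        if not 0.0 < self.moderate_var_share < 1.0:
            raise InvalidConfigError("moderate_var_share must be in (0, 1)")


@dataclasses.dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated phenotype vector."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float

    def __post_init__(self) -> None:
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise ValueError("qtl_indices and qtl_effects must have equal length")
        if not 0.0 <= self.realized_h2 <= 1.0:
            raise ValueError(f"realized_h2={self.realized_h2} outside [0, 1]")


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw an n×m genotype matrix of unlinked sites.

    Marker j has allele frequency p_j ~ Uniform(maf_range) and genotypes
    i.i.d. Binomial(2, p_j); there is no missingness and no LD.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_markers)
    vals = rng.binomial(2, p, size=(config.n_individuals, config.n_markers)).astype(float)
    sample_ids = [f"ind{i:05d}" for i in range(config.n_individuals)]
    marker_ids = [f"snp{j:06d}" for j in range(config.n_markers)]
    return GenotypeMatrix(vals, sample_ids, marker_ids)


def _scaled_effects(rng: np.random.Generator, Xc: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-QTL additive effects for the configured architecture.

    ``Xc`` is the centered genotype block at the QTL, columns in QTL order.
    The first column is the major gene (major_gene) / the first
    ``n_moderate`` columns are the moderate block (few_moderate).
    """
    k = Xc.shape[1]
    beta = rng.standard_normal(k)
    if config.architecture == "polygenic" or k == 1:
        return beta
    if config.architecture == "major_gene":
        small = beta[1:]
        var_small = np.var(Xc[:, 1:] @ small) if k > 1 else 0.0
        var_major_col = np.var(Xc[:, 0])
        s = config.major_gene_var_share
        if var_small == 0.0 or var_major_col == 0.0:
            return beta
        beta[0] = np.sign(beta[0]) * np.sqrt(s / (1 - s) * var_small / var_major_col)
        return beta
    # few_moderate: scale the moderate block so it carries moderate_var_share
    nm = min(config.n_moderate, k - 1)
    var_small = np.var(Xc[:, nm:] @ beta[nm:])
    var_mod = np.var(Xc[:, :nm] @ beta[:nm])
    s = config.moderate_var_share
    if var_small > 0.0 and var_mod > 0.0:
        beta[:nm] *= np.sqrt(s / (1 - s) * var_small / var_mod)
    return beta


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.Series, SimTruth]:
    """Simulate y = g + e at the configured architecture and heritability.

    g is built from centered genotypes at randomly chosen polymorphic QTL;
    e ~ Normal(0, var(g)·(1−h²)/h²). Monomorphic columns are never chosen
    as QTL (the resampling guarantee). ``realized_h2`` is var(g)/var(y) on
    the simulated sample. Deterministic given ``config.seed``.
    """
    if not genotypes.is_complete():
        raise ValueError("phenotype simulation needs complete genotypes")
    rng = np.random.default_rng((config.seed, 1))  # stream distinct from genotypes
    v = genotypes.values
    poly = np.where(v.std(axis=0) > 0)[0]
    if len(poly) < config.n_qtl:
        raise InvalidConfigError(
            f"only {len(poly)} polymorphic markers available for {config.n_qtl} QTL"
        )
    qtl = np.sort(rng.choice(poly, size=config.n_qtl, replace=False))
    Xc = v[:, qtl] - v[:, qtl].mean(axis=0)
    beta = _scaled_effects(rng, Xc, config)
    g = Xc @ beta
    var_g = float(np.var(g))
    e = rng.normal(0.0, np.sqrt(var_g * (1 - config.h2) / config.h2), size=genotypes.n)
    y = g + e
    if config.standardize:
        mu, sd = y.mean(), y.std()
        y = (y - mu) / sd
        g = (g - g.mean()) / sd  # keep y = g + e' on the same scale
        beta = beta / sd
    var_y = float(np.var(y))
    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects=beta,
        genetic_values=g,
        realized_h2=float(np.var(g)) / var_y if var_y > 0 else 0.0,
    )
    return pd.Series(y, index=genotypes.sample_ids, name="y"), truth
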