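"""VanRaden (method 1) genomic relationship matrix.

G = M M' / Σ_j 2 p_j q_j, where M is the n×m genotype matrix with 2p_j
subtracted from column j and p_j the in-sample frequency of the counted
(second) allele. Rows of G are the feature vectors handed to every learner
and the covariance structure of the GBLUP random effect.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = ["GRM", "vanraden_grm", "grm_submatrix", "read_grm", "write_grm"]


class DegenerateGenotypesError(ValueError):
    pass


@dataclasses.dataclass
class GRM:
    """n×n genomic relationship matrix with sample IDs and the VanRaden
    denominator Σ 2 p_j q_j used to scale it."""

    values: np.ndarray
    sample_ids: list[str]
    denominator: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM shape {self.values.shape} does not match {n} IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample IDs must be unique")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample ID {exc.args[0]!r} not present in GRM") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def vanraden_grm(g: GenotypeMatrix) -> GRM:
    """Build G = MM'/Σ 2p_j q_j from complete genotypes.

    Allele frequencies are estimated from all samples passed in; with
    in-sample frequencies the columns of M are mean-zero, so every row of G
    sums to zero and G is PSD. Monomorphic markers contribute nothing to
    numerator or denominator; if every marker is monomorphic the
    denominator is zero and the input is rejected.
    """
    if not g.is_complete():
        raise ValueError("GRM requires complete genotypes; run impute_missing first")
    if g.m < 1:
        raise ValueError("GRM requires at least one marker")
    v = g.values
    p = v.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateGenotypesError(
            "all markers monomorphic: VanRaden denominator Σ2pq is zero"
        )
    M = v - 2.0 * p
    G = (M @ M.T) / denom
    return GRM(G, list(g.sample_ids), denom)


def grm_submatrix(G: GRM, rows: list[str], cols: list[str]) -> np.ndarray:
    """Extract the block G[rows, cols] in the requested ID order."""
    ri = G.index_of(list(rows))
    ci = G.index_of(list(cols))
    return G.values[np.ix_(ri, ci)]


def write_grm(G: GRM, path: str | Path) -> None:
    G.to_dataframe().to_csv(path, sep="\t")


def read_grm(path: str | Path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    # denominator is not stored in the TSV; recoverable only approximately,
    # recorded as NaN on read
    return GRM(vals, list(df.index.astype(str)), float("nan"))
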