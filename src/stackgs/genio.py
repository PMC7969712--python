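"""Genotype/phenotype file handling and marker quality control.

Genotypes are held as an additive-coded n×m matrix (count of the second
allele: 0, 1 or 2, NaN for missing) with sample and marker identifiers.
Supported on-disk dialects are PLINK ``.raw``-style additive text, VCF
(diploid GT field, biallelic sites only) and plain CSV. QC applies the
standard chip filters — minor allele frequency, call rate and a 1-df
chi-square Hardy–Weinberg test — with strict ``>`` threshold semantics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "QC_PRESETS",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "marker_stats",
    "apply_qc",
    "impute_missing",
]

_VALID_CODES = (0.0, 1.0, 2.0)


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive-coded SNP genotypes for ``n`` samples × ``m`` markers.

    ``values`` is a float array with entries in {0, 1, 2} or NaN (missing).
    """

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample IDs must be unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker IDs must be unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, _VALID_CODES).all():
            bad = finite[~np.isin(finite, _VALID_CODES)]
            raise ValueError(f"genotype entries must be 0/1/2 or missing; saw {bad[:5]}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.marker_ids)


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Marker filters: keep markers with maf > maf_min, call rate >
    call_rate_min and HWE p-value > hwe_p_min (strict inequalities)."""

    maf_min: float
    call_rate_min: float
    hwe_p_min: float

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


#: Presets mirroring common beef-chip (MAF>0.05, CR>0.95, HWE p>1e-5) and
#: dairy-chip (MAF>0.01, CR>0.95, HWE p>1e-4) pipelines.
QC_PRESETS: dict[str, QCThresholds] = {
    "beef": QCThresholds(0.05, 0.95, 1e-5),
    "dairy": QCThresholds(0.01, 0.95, 1e-4),
}


@dataclasses.dataclass
class QCReport:
    n_markers_in: int
    n_failed_maf: int
    n_failed_cr: int
    n_failed_hwe: int
    n_markers_out: int
    stats: pd.DataFrame  # per-marker maf / call_rate / hwe_p, all input markers


# ---------------------------------------------------------------------------
# File IO


class GenotypeParseError(ValueError):
    pass


def _parse_numeric_block(df: pd.DataFrame, path: str) -> np.ndarray:
    try:
        vals = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise GenotypeParseError(f"{path}: non-numeric genotype entry ({exc})") from exc
    return vals


def _read_csv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    return GenotypeMatrix(_parse_numeric_block(df, path), list(df.index), list(df.columns))


_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_raw(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    missing_meta = [c for c in _RAW_META_COLS if c not in df.columns]
    if missing_meta:
        raise GenotypeParseError(f"{path}: missing .raw columns {missing_meta}")
    samples = df["IID"].astype(str).tolist()
    geno = df.drop(columns=_RAW_META_COLS)
    return GenotypeMatrix(_parse_numeric_block(geno, path), samples, list(geno.columns))


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    marker_ids: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}) is unsupported"
            )
        col = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            a1, a2 = gt[0], gt[1]
            col[i] = np.nan if (a1 < 0 or a2 < 0) else float(a1 + a2)
        cols.append(col)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise GenotypeParseError(f"{path}: VCF contains no variant records")
    return GenotypeMatrix(np.column_stack(cols), samples, marker_ids)


def read_genotypes(path: str | Path, format: str = "raw") -> GenotypeMatrix:
    """Read genotypes from ``path`` in one of the dialects {raw, vcf, csv}.

    Additive coding counts copies of the alternate/second allele; VCF GT
    fields map 0/0→0, 0/1 or 1/0→1, 1/1→2, ./.→missing.
    """
    path = str(path)
    readers = {"raw": _read_raw, "vcf": _read_vcf, "csv": _read_csv}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path)


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "raw") -> None:
    path = str(path)
    if format == "csv":
        g.to_dataframe().to_csv(path)
    elif format == "raw":
        df = g.to_dataframe().reset_index(drop=True)
        meta = pd.DataFrame(
            {
                "FID": g.sample_ids,
                "IID": g.sample_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        out = pd.concat([meta, df], axis=1)
        # integers where complete, NA for missing
        out.to_csv(path, sep=" ", index=False, na_rep="NA", float_format="%g")
    else:
        raise ValueError(f"unsupported write format {format!r} (raw or csv)")


def read_phenotypes(path: str | Path) -> pd.Series:
    """Read a two-column (id, value) TSV into a float Series indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: phenotype file needs (id, value) columns")
    s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str))
    s.name = df.columns[1]
    return s


def write_phenotypes(y: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"id": y.index.astype(str), "y": y.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Marker statistics & QC


def marker_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, call rate and Hardy–Weinberg chi-square p-value.

    The HWE test is the classic 1-df goodness of fit of observed genotype
    counts (n_AA, n_Aa, n_aa) against expectations (n·p̂², 2n·p̂q̂, n·q̂²)
    from the non-missing samples, with no continuity correction. Markers
    with all entries missing get NaN maf/hwe_p and call rate 0.
    """
    if g.n < 2:
        raise ValueError("marker statistics need at least 2 samples")
    v = g.values
    obs = np.isfinite(v)
    n_obs = obs.sum(axis=0).astype(float)
    call_rate = n_obs / g.n

    with np.errstate(invalid="ignore", divide="ignore"):
        n0 = ((v == 0) & obs).sum(axis=0).astype(float)
        n1 = ((v == 1) & obs).sum(axis=0).astype(float)
        n2 = ((v == 2) & obs).sum(axis=0).astype(float)
        p = (n1 + 2 * n2) / (2 * n_obs)  # second-allele frequency
        q = 1.0 - p
        maf = np.minimum(p, q)

        exp0 = n_obs * q**2
        exp1 = 2 * n_obs * p * q
        exp2 = n_obs * p**2
        chi2 = np.zeros(g.m)
        for o, e in ((n0, exp0), (n1, exp1), (n2, exp2)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            chi2 = chi2 + term
        hwe_p = stats.chi2.sf(chi2, df=1)

    empty = n_obs == 0
    maf[empty] = np.nan
    hwe_p[empty] = np.nan
    return pd.DataFrame(
        {"maf": maf, "call_rate": call_rate, "hwe_p": hwe_p}, index=g.marker_ids
    )


class EmptyQCResultError(ValueError):
    pass


def apply_qc(g: GenotypeMatrix, t: QCThresholds) -> tuple[GenotypeMatrix, QCReport]:
    """Retain markers passing ALL of maf/call-rate/HWE (strict ``>``).

    Failure reasons are counted independently: a marker can fail several.
    NaN statistics (all-missing markers) fail every comparison.
    """
    st = marker_stats(g)
    with np.errstate(invalid="ignore"):
        pass_maf = st["maf"].to_numpy() > t.maf_min
        pass_cr = st["call_rate"].to_numpy() > t.call_rate_min
        pass_hwe = st["hwe_p"].to_numpy() > t.hwe_p_min
    keep = pass_maf & pass_cr & pass_hwe
    report = QCReport(
        n_markers_in=g.m,
        n_failed_maf=int((~pass_maf).sum()),
        n_failed_cr=int((~pass_cr).sum()),
        n_failed_hwe=int((~pass_hwe).sum()),
        n_markers_out=int(keep.sum()),
        stats=st,
    )
    if report.n_markers_out == 0:
        raise EmptyQCResultError(
            "no markers survive QC; review thresholds "
            f"(maf>{t.maf_min}, cr>{t.call_rate_min}, hwe_p>{t.hwe_p_min})"
        )
    kept = GenotypeMatrix(
        g.values[:, keep],
        g.sample_ids,
        [mid for mid, k in zip(g.marker_ids, keep) if k],
    )
    return kept, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries with the marker mean genotype 2p̂_j.

    Preserves per-marker allele frequencies exactly; raises on any marker
    with no observed genotypes (such markers should have failed QC).
    """
    if g.is_complete():
        return GenotypeMatrix(g.values.copy(), g.sample_ids, g.marker_ids)
    v = g.values.copy()
    obs = np.isfinite(v)
    if (~obs.any(axis=0)).any():
        bad = [mid for mid, ok in zip(g.marker_ids, obs.any(axis=0)) if not ok]
        raise ValueError(f"cannot impute markers with all genotypes missing: {bad[:5]}")
    col_mean = np.nanmean(v, axis=0)
    idx = np.where(~obs)
    v[idx] = col_mean[idx[1]]
    out = GenotypeMatrix.__new__(GenotypeMatrix)  # imputed values are fractional
    out.values = v
    out.sample_ids = list(g.sample_ids)
    out.marker_ids = list(g.marker_ids)
    return out
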