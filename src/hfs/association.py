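"""HFS-trait association.

Phenotypes are adjusted for covariates once, inverse-normal transformed,
and then each locus's HFS column is tested by simple linear regression
with no further covariates. A fixed genome-wide threshold of
p < 5e-8 defines significance; independent hits are the best locus per
200-kb neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreparedTrait",
    "AssocResult",
    "inverse_normal_transform",
    "prepare_phenotype",
    "associate",
    "lambda_gc",
    "independent_hits",
    "GENOME_WIDE_ALPHA",
]

GENOME_WIDE_ALPHA = 5e-8
# median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class PreparedTrait:
    """Covariate-adjusted, rank inverse-normal transformed trait."""

    values: np.ndarray
    binary: bool = False
    covariate_names: tuple[str, ...] = ()


@dataclass
class AssocResult:
    locus_id: str
    beta: float
    se: float
    p: float
    n: int
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    excluded: bool = False
    reason: str | None = None

    @property
    def chisq(self) -> float:
        return (self.beta / self.se) ** 2 if self.se > 0 else np.nan

    @property
    def midpoint(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return (self.start + self.end) // 2


def inverse_normal_transform(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    z_i = Phi^-1((rank_i - c) / (n - 2c + 1)); ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def prepare_phenotype(
    values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    binary: bool = False,
) -> PreparedTrait:
    """Adjust a phenotype for covariates and inverse-normal transform it.

    Quantitative traits are residualized by ordinary least squares;
    binary traits by a logistic model's deviance residuals. The
    residuals are then rank inverse-normal transformed (Blom offset
    3/8), giving a mean-0, variance-~1 trait used without covariates in
    all downstream regressions.
    """
    y = np.asarray(values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    names: tuple[str, ...] = ()
    if covariates is not None:
        C = pd.DataFrame(covariates)
        if C.isna().any().any():
            raise ValueError("covariates contain missing values")
        names = tuple(str(c) for c in C.columns)
        X = np.column_stack([np.ones(len(y)), C.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular covariate design")
    else:
        X = np.ones((len(y), 1))
    if binary:
        import statsmodels.api as sm

        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binary trait must be coded 0/1")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        resid = fit.resid_deviance
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    return PreparedTrait(inverse_normal_transform(resid), binary=binary, covariate_names=names)


def associate(
    x: np.ndarray, trait: PreparedTrait | np.ndarray, locus_id: str = "", **meta
) -> AssocResult:
    """Simple linear regression of the prepared trait on one HFS column.

    Constant HFS columns are not an error: the result is flagged
    ``excluded`` with a reason code so callers can drop it downstream.
    """
    y = trait.values if isinstance(trait, PreparedTrait) else np.asarray(trait, float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 non-missing pairs")
    if np.ptp(x) == 0:
        return AssocResult(locus_id, np.nan, np.nan, np.nan, n,
                           excluded=True, reason="constant_hfs", **meta)
    res = stats.linregress(x, y)
    return AssocResult(locus_id, float(res.slope), float(res.stderr),
                       float(res.pvalue), n, **meta)


def lambda_gc(chisq: np.ndarray) -> float:
    """Genomic-control inflation factor.

    Median of the association chi-square statistics divided by the
    theoretical chi-square(1) median (0.4549...), so a well-calibrated
    test gives lambda ~= 1.
    """
    chisq = np.asarray(chisq, dtype=float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no finite chi-square statistics")
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def independent_hits(
    results: list[AssocResult],
    window: int = 200_000,
    alpha: float = GENOME_WIDE_ALPHA,
) -> list[AssocResult]:
    """Greedy selection of independent associations.

    Repeatedly takes the most significant remaining locus and suppresses
    every significant locus whose midpoint lies within +-``window`` of
    its midpoint on the same chromosome. Results must carry coordinates.
    """
    sig = [r for r in results if not r.excluded and r.p < alpha]
    for r in sig:
        if r.midpoint is None:
            raise ValueError(f"{r.locus_id}: no coordinates for hit selection")
    sig.sort(key=lambda r: (r.p, r.chrom, r.start))
    hits: list[AssocResult] = []
    suppressed: set[str] = set()
    for r in sig:
        if r.locus_id in suppressed:
            continue
        hits.append(r)
        for other in sig:
            if (
                other.chrom == r.chrom
                and abs(other.midpoint - r.midpoint) <= window
            ):
                suppressed.add(other.locus_id)
    hits.sort(key=lambda r: (r.chrom, r.start))
    return hits
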