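"""HFS-weighted polygenic scores and LASSO integration with a SNP PRS.

The HFS PRS of an individual is the weighted sum of its HFS values,
weighted by the SuSiE posterior effect sizes. Per-block partial scores
(one per independent LD block) are combined with an externally computed
SNP-based PRS by L1-penalized regression fitted in a tuning sample that
is disjoint from the evaluation sample; prediction accuracy is the
squared correlation between score and trait in the evaluation sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "hfs_prs",
    "block_scores",
    "IntegrationModel",
    "integrate_lasso",
    "evaluate_r2",
]

MIN_TUNING_N = 50


def hfs_prs(
    hfs: pd.DataFrame,
    effects: pd.Series,
    pip: pd.Series | None = None,
    pip_threshold: float | None = None,
) -> pd.Series:
    """Weighted sum of HFS columns: score_i = sum_j w_j HFS_ij.

    ``effects`` must be indexed by locus id and align with the HFS
    columns. When ``pip`` and ``pip_threshold`` are given, only loci
    with PIP strictly above the threshold contribute.
    """
    missing = effects.index.difference(hfs.columns)
    if len(missing):
        raise ValueError(f"effects refer to unknown loci, e.g. {list(missing[:3])}")
    w = effects.copy()
    if pip_threshold is not None:
        if pip is None:
            raise ValueError("pip_threshold given without pip values")
        w = w[pip.reindex(w.index) > pip_threshold]
    if w.empty:
        return pd.Series(0.0, index=hfs.index, name="hfs_prs")
    score = hfs[w.index].fillna(0.0).to_numpy() @ w.to_numpy()
    return pd.Series(score, index=hfs.index, name="hfs_prs")


def block_scores(
    hfs: pd.DataFrame, effects: pd.Series, block_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-block partial PRS: weighted HFS sums within each LD block.

    Every weighted locus must be assigned to a block; the block columns
    sum exactly to the genome-wide :func:`hfs_prs`.
    """
    unassigned = [l for l in effects.index if l not in block_map]
    if unassigned:
        raise ValueError(f"loci without a block: {unassigned[:3]}")
    cols: dict[str, np.ndarray] = {}
    for locus, w in effects.items():
        blk = block_map[locus]
        contrib = hfs[locus].fillna(0.0).to_numpy() * w
        cols[blk] = cols.get(blk, 0.0) + contrib
    all_blocks = sorted(set(block_map.values()))
    out = pd.DataFrame(
        {blk: cols.get(blk, np.zeros(len(hfs))) for blk in all_blocks},
        index=hfs.index,
    )
    return out


@dataclass
class IntegrationModel:
    """L1-integrated predictor over [SNP PRS | block scores]."""

    intercept: float
    weights: pd.Series  # on the original predictor scale
    penalty: float
    seed: int
    predictor_means: pd.Series
    predictor_scales: pd.Series
    tuning_ids: tuple = ()

    def predict(self, predictors: pd.DataFrame) -> pd.Series:
        X = predictors[self.weights.index]
        return pd.Series(
            self.intercept + X.to_numpy() @ self.weights.to_numpy(),
            index=predictors.index,
            name="integrated_score",
        )


def integrate_lasso(
    block_scores_df: pd.DataFrame,
    snp_prs: pd.Series,
    trait: pd.Series,
    tuning_ids: Sequence,
    seed: int = 0,
    l1_ratio: float = 1.0,
) -> IntegrationModel:
    """Combine block scores and a SNP PRS by cross-validated LASSO.

    The penalty is chosen by 5-fold cross-validation within the tuning
    sample only; weights are returned on the original predictor scale.
    ``l1_ratio`` < 1 switches to elastic net with that mixing weight.
    """
    from sklearn.linear_model import ElasticNetCV, LassoCV
    from sklearn.model_selection import KFold

    tuning_ids = list(tuning_ids)
    if len(tuning_ids) < MIN_TUNING_N:
        raise ValueError(
            f"tuning sample too small ({len(tuning_ids)} < {MIN_TUNING_N})"
        )
    predictors = pd.concat([snp_prs.rename("snp_prs"), block_scores_df], axis=1)
    X = predictors.loc[tuning_ids]
    y = trait.loc[tuning_ids].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant trait in the tuning sample")
    mean = X.mean()
    scale = X.std(ddof=0).replace(0.0, 1.0)
    Z = ((X - mean) / scale).to_numpy()
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    if l1_ratio >= 1.0:
        model = LassoCV(cv=cv, alphas=100, max_iter=50_000, random_state=seed)
    else:
        model = ElasticNetCV(
            cv=cv, alphas=100, l1_ratio=l1_ratio, max_iter=50_000, random_state=seed
        )
    model.fit(Z, y)
    w_std = pd.Series(model.coef_, index=predictors.columns)
    weights = w_std / scale
    intercept = float(model.intercept_ - (weights * mean).sum())
    return IntegrationModel(
        intercept=intercept,
        weights=weights,
        penalty=float(model.alpha_),
        seed=seed,
        predictor_means=mean,
        predictor_scales=scale,
        tuning_ids=tuple(tuning_ids),
    )


def evaluate_r2(
    score: pd.Series, trait: pd.Series, evaluation_ids: Sequence,
    tuning_ids: Sequence | None = None,
) -> float | None:
    """Squared Pearson correlation between score and trait on held-out ids.

    When ``tuning_ids`` is supplied, any overlap with the evaluation ids
    is an error — the integration model must never be scored on the
    individuals it was tuned on. A constant score yields ``None``.
    """
    evaluation_ids = list(evaluation_ids)
    if tuning_ids is not None:
        overlap = set(evaluation_ids) & set(tuning_ids)
        if overlap:
            raise ValueError(f"evaluation ids overlap tuning ids: {sorted(overlap)[:3]}")
    s = score.loc[evaluation_ids].to_numpy(dtype=float)
    t = trait.loc[evaluation_ids].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        return None
    r = np.corrcoef(s, t)[0, 1]
    return float(r * r)
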