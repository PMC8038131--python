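"""Risk-allele-count polygenic risk scores over a selected SNP set.

The risk allele at each SNP is the allele whose carriage raises disease
odds (the minor allele when its per-SNP OR exceeds 1, otherwise the
major allele); each subject's score is the unweighted sum of risk-allele
counts, 0..2m over m SNPs.  Scores are banded into low/medium/high
categories — fixed presets for 5-SNP (0-3 / 4-5 / >=6) and 6-SNP
(0-3 / 4-6 / >=7) models, or empirical tertiles — and category odds
ratios are estimated by adjusted logistic regression with the low band
as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EffectEstimate, GenotypeMatrix
from .screen import logistic_assoc

__all__ = [
    "PRSModel",
    "preset_bands",
    "orient_risk_alleles",
    "compute_prs",
    "categorize",
    "prs_category_or",
    "PolygenicRiskScorer",
]

CATEGORIES = ("low", "medium", "high")

#: Fixed tertile-band presets (upper bound of low, upper bound of medium).
PRESET_BANDS: dict[int, tuple[int, int]] = {5: (3, 5), 6: (3, 6)}


def preset_bands(n_snps: int) -> tuple[int, int]:
    """Published tertile cutpoints for 5- and 6-SNP models."""
    try:
        return PRESET_BANDS[n_snps]
    except KeyError:
        raise KeyError(
            f"no preset bands for a {n_snps}-SNP model; pass explicit bounds "
            "or use empirical tertiles"
        ) from None


@dataclass(frozen=True)
class PRSModel:
    """SNP set with risk-allele orientation and category cutpoints.

    ``risk_allele`` maps snp id -> base symbol; ``risk_is_minor`` maps
    snp id -> whether that symbol is the minor allele (i.e. whether the
    0/1/2 minor-allele count is used as-is or flipped to 2/1/0).
    ``bounds`` = (b1, b2): score <= b1 is low, b1 < score <= b2 medium,
    score > b2 high.
    """

    snp_ids: tuple[str, ...]
    risk_allele: dict[str, str] = field(default_factory=dict)
    risk_is_minor: dict[str, bool] = field(default_factory=dict)
    bounds: tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be strictly increasing")
        missing = [s for s in self.snp_ids if s not in self.risk_is_minor]
        if missing:
            raise ValueError(f"risk orientation missing for {missing}")

    @property
    def max_score(self) -> int:
        return 2 * len(self.snp_ids)


def orient_risk_alleles(
    genotypes: GenotypeMatrix,
    effects: Mapping[str, EffectEstimate],
    snp_ids: Sequence[str],
    bounds: tuple[int, int] | None = None,
) -> PRSModel:
    """Choose each SNP's risk allele from its per-SNP odds ratio.

    OR of the minor-allele count > 1 -> minor allele is the risk allele;
    < 1 -> major allele.  An OR of exactly 1 carries no direction and is
    rejected (orient manually).
    """
    snp_ids = tuple(snp_ids)
    risk_allele: dict[str, str] = {}
    risk_is_minor: dict[str, bool] = {}
    for sid in snp_ids:
        if sid not in effects:
            raise KeyError(f"no effect estimate for SNP {sid!r}")
        orv = effects[sid].or_value
        if not np.isfinite(orv) or orv == 1.0:
            raise ValueError(
                f"SNP {sid!r}: OR={orv} gives no risk-allele direction; orient manually"
            )
        meta = genotypes.snps.loc[sid]
        if orv > 1.0:
            risk_allele[sid] = meta["minor_allele"]
            risk_is_minor[sid] = True
        else:
            risk_allele[sid] = meta["major_allele"]
            risk_is_minor[sid] = False
    if bounds is None:
        bounds = preset_bands(len(snp_ids)) if len(snp_ids) in PRESET_BANDS else None
    if bounds is None:
        raise ValueError("no preset bands for this model size; pass bounds explicitly")
    return PRSModel(snp_ids, risk_allele, risk_is_minor, bounds)


def compute_prs(
    genotypes: GenotypeMatrix, model: PRSModel, missing: str = "exclude"
) -> pd.DataFrame:
    """Integer risk-allele-count score and band per subject.

    Minor-allele counts are used directly where the risk allele is
    minor and flipped 0/1/2 -> 2/1/0 where it is major.  Subjects
    missing any model SNP are excluded by default; ``missing="mean"``
    imputes the SNP's mean risk-allele count before rounding the total.
    """
    absent = [s for s in model.snp_ids if s not in genotypes.dosage.columns]
    if absent:
        raise KeyError(f"model SNPs absent from genotypes: {absent}")
    if missing not in ("exclude", "mean"):
        raise ValueError(f"unknown missing policy {missing!r}")
    cols = []
    for sid in model.snp_ids:
        counts = genotypes.dosage[sid].to_numpy(dtype=float)
        if not model.risk_is_minor[sid]:
            counts = 2.0 - counts
        cols.append(counts)
    mat = np.column_stack(cols)
    any_missing = np.isnan(mat).any(axis=1)
    if missing == "mean":
        col_means = np.nanmean(mat, axis=0)
        mat = np.where(np.isnan(mat), col_means, mat)
        score = np.rint(mat.sum(axis=1)).astype(int)
        keep = np.ones(len(score), dtype=bool)
    else:
        keep = ~any_missing
        score = np.zeros(len(keep), dtype=int)
        score[keep] = mat[keep].sum(axis=1).astype(int)
    out = pd.DataFrame(
        {"score": score, "n_missing_snps": np.isnan(np.column_stack(cols)).sum(axis=1)},
        index=genotypes.subject_ids,
    )
    out = out.loc[keep]
    out["category"] = categorize(out["score"], model.bounds)
    return out


def categorize(
    scores: pd.Series | np.ndarray, bounds: tuple[int, int]
) -> pd.Categorical:
    """Band integer scores into low (<= b1), medium (b1 < s <= b2) and
    high (> b2) categories."""
    b1, b2 = bounds
    if not b1 < b2:
        raise ValueError("bounds must be strictly increasing")
    s = np.asarray(scores)
    codes = np.where(s <= b1, 0, np.where(s <= b2, 1, 2))
    return pd.Categorical.from_codes(codes, categories=list(CATEGORIES), ordered=True)


def empirical_tertile_bounds(scores: pd.Series | np.ndarray) -> tuple[int, int]:
    """Integer cutpoints from the empirical tertiles of the score
    distribution (floor of the 1/3 and 2/3 quantiles)."""
    s = np.asarray(scores, dtype=float)
    b1 = int(np.floor(np.quantile(s, 1 / 3)))
    b2 = int(np.floor(np.quantile(s, 2 / 3)))
    if b2 <= b1:
        b2 = b1 + 1
    return b1, b2


def prs_category_or(
    categories: pd.Series | pd.Categorical,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict[str, EffectEstimate]:
    """Adjusted odds ratios for medium- and high-PRS vs the low band.

    Medium/high are dummy-coded against the low reference in one
    logistic fit; the reference's OR is fixed at 1 by construction.
    """
    cat = pd.Series(pd.Categorical(categories, categories=list(CATEGORIES), ordered=True))
    cat = cat.reset_index(drop=True)
    y = np.asarray(outcome, dtype=float)
    if (cat == "low").sum() == 0:
        raise ValueError("reference (low) category is empty")
    design = pd.DataFrame(
        {
            "prs_medium": (cat == "medium").astype(float),
            "prs_high": (cat == "high").astype(float),
        }
    )
    if covariates is not None and covariates.shape[1]:
        design = pd.concat(
            [design, pd.DataFrame(np.asarray(covariates, float), columns=list(covariates.columns))],
            axis=1,
        )
    out: dict[str, EffectEstimate] = {
        "low": EffectEstimate("prs_low", 1.0, 1.0, 1.0, 1.0, beta=0.0, se=0.0, n=int((cat == "low").sum()))
    }
    for name, term in (("medium", "prs_medium"), ("high", "prs_high")):
        est = logistic_assoc(
            design[term].to_numpy(),
            y,
            design.drop(columns=[term]),
            coding="additive",
            term="snp",
        )
        # relabel the generic term
        out[name] = EffectEstimate(
            term=f"prs_{name}",
            or_value=est.or_value,
            ci_low=est.ci_low,
            ci_high=est.ci_high,
            p_value=est.p_value,
            beta=est.beta,
            se=est.se,
            n=est.n,
            covariates=tuple(c for c in design.columns if c != term),
            converged=est.converged,
        )
    return out


class PolygenicRiskScorer(BaseEstimator, TransformerMixin):
    """Risk-allele-count PRS as a scikit-learn style transformer.

    ``fit(X, y)`` orients the risk allele of every SNP from per-SNP
    logistic fits (optionally covariate-adjusted via the ``covariates``
    fit parameter); ``transform(X)`` returns the integer score and band
    per subject.  ``X`` is a :class:`GenotypeMatrix` or a DataFrame of
    minor-allele counts (a DataFrame needs ``snp_meta`` at construction
    so allele symbols can be reported).

    Parameters
    ----------
    snp_ids:
        SNPs entering the score (default: all columns of X).
    bands:
        "preset" (published 5-/6-SNP tertile cutpoints), "tertile"
        (empirical) or an explicit (b1, b2) pair.
    missing:
        "exclude" subjects missing a model SNP (default) or "mean"
        impute.
    weighted:
        Off by default (pure allele counting).  When on, each SNP's
        risk-allele count is weighted by its |log OR|.
    """

    def __init__(
        self,
        snp_ids: Sequence[str] | None = None,
        bands: str | tuple[int, int] = "preset",
        missing: str = "exclude",
        weighted: bool = False,
        snp_meta: pd.DataFrame | None = None,
    ) -> None:
        self.snp_ids = snp_ids
        self.bands = bands
        self.missing = missing
        self.weighted = weighted
        self.snp_meta = snp_meta

    def _as_matrix(self, X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            if self.snp_meta is None:
                meta = pd.DataFrame(
                    {
                        "chrom": "0",
                        "position": 0,
                        "minor_allele": "A",
                        "major_allele": "B",
                    },
                    index=X.columns,
                )
            else:
                meta = self.snp_meta.loc[X.columns]
            return GenotypeMatrix(X, meta)
        raise TypeError("X must be a GenotypeMatrix or DataFrame of 0/1/2 counts")

    def fit(self, X, y, covariates: pd.DataFrame | None = None) -> "PolygenicRiskScorer":
        gm = self._as_matrix(X)
        snp_ids = tuple(self.snp_ids) if self.snp_ids is not None else tuple(gm.snp_ids)
        effects = {
            sid: logistic_assoc(gm.dosage[sid], y, covariates, term="snp")
            for sid in snp_ids
        }
        bounds: tuple[int, int] | None
        if self.bands == "preset":
            bounds = preset_bands(len(snp_ids))
        elif self.bands == "tertile":
            bounds = (0, 1)  # placeholder, replaced from the fitted scores below
        else:
            bounds = tuple(self.bands)  # type: ignore[assignment]
        self.effects_ = effects
        self.model_ = orient_risk_alleles(gm, effects, snp_ids, bounds=bounds)
        if self.bands == "tertile":
            scores = compute_prs(gm, self.model_, missing=self.missing)["score"]
            self.model_ = PRSModel(
                self.model_.snp_ids,
                self.model_.risk_allele,
                self.model_.risk_is_minor,
                empirical_tertile_bounds(scores),
            )
        self.weights_ = (
            {s: abs(effects[s].beta) for s in snp_ids} if self.weighted else None
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise RuntimeError("PolygenicRiskScorer is not fitted")
        gm = self._as_matrix(X)
        out = compute_prs(gm, self.model_, missing=self.missing)
        if self.weights_ is not None:
            w_cols = []
            for sid in self.model_.snp_ids:
                counts = gm.dosage[sid].to_numpy(dtype=float)
                if not self.model_.risk_is_minor[sid]:
                    counts = 2.0 - counts
                w_cols.append(self.weights_[sid] * counts)
            wsum = pd.Series(np.column_stack(w_cols).sum(axis=1), index=gm.subject_ids)
            out["weighted_score"] = wsum.loc[out.index]
        return out
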