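"""Per-SNP QC (MAF, Hardy-Weinberg) and covariate-adjusted logistic
association, with threshold-based candidate selection.

This is the screening stage that precedes LD pruning and the multilocus
model search: each SNP is tested marginally under an additive (or,
optionally, dominant/recessive) coding in a logistic model adjusted for
the declared covariates, and candidates are kept when they clear the
association p-value, MAF and HWE thresholds.  All thresholds are
configuration, never hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import CohortTable, EffectEstimate, GenotypeMatrix

__all__ = [
    "SNPStats",
    "hwe_test",
    "hwe_exact_test",
    "compute_maf",
    "genotype_counts",
    "snp_qc_table",
    "logistic_assoc",
    "association_table",
    "select_candidates",
]

_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class SNPStats:
    """Per-SNP QC summary: genotype counts, MAF, HWE p, call rate."""

    snp_id: str
    n0: int
    n1: int
    n2: int
    maf: float
    hwe_p: float
    call_rate: float


def genotype_counts(column: pd.Series | np.ndarray) -> tuple[int, int, int]:
    vals = np.asarray(column, dtype=float)
    called = vals[~np.isnan(vals)]
    return (
        int((called == 0).sum()),
        int((called == 1).sum()),
        int((called == 2).sum()),
    )


def compute_maf(column: pd.Series | np.ndarray) -> float:
    """Minor-allele frequency min(q, 1-q); missing genotypes excluded."""
    n0, n1, n2 = genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no called genotypes")
    q = (n1 + 2 * n2) / (2 * n)
    return float(min(q, 1 - q))


def hwe_test(n0: int, n1: int, n2: int, method: str = "chi2") -> float:
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    ``chi2`` is the one-df chi-squared test against expectations from
    the sample allele frequency; ``exact`` is the standard exact test on
    heterozygote counts, recommended for rare alleles (MAF < 0.05).
    Monomorphic SNPs return p = 1 with a warning.
    """
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError("genotype counts must be non-negative with at least one call")
    n = n0 + n1 + n2
    q = (n1 + 2 * n2) / (2 * n)
    if q == 0.0 or q == 1.0:
        warnings.warn("monomorphic SNP: HWE p defined as 1", stacklevel=2)
        return 1.0
    if method == "exact":
        return hwe_exact_test(n0, n1, n2)
    if method != "chi2":
        raise ValueError(f"unknown HWE method {method!r}")
    expected = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test: sum of heterozygote-count probabilities no more
    likely than the observed one, conditional on allele counts."""
    n = n0 + n1 + n2
    rare = min(n1 + 2 * n0, n1 + 2 * n2)  # copies of the rarer allele
    # heterozygote count shares the parity of the rare-allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    # unnormalized probabilities by the standard two-sided recurrence:
    # P(h+2)/P(h) = [ (rare-h)(2n-rare-h) ] / [ (h+2)(h+1)/... ] form
    probs = {}
    h = rare % 2
    probs[h] = 1.0
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    obs = n1 if n1 in probs else min(het_values, key=lambda v: abs(v - n1))
    p_obs = probs[obs]
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return float(min(1.0, p))


def snp_qc_table(genotypes: GenotypeMatrix, hwe_method: str = "chi2") -> pd.DataFrame:
    rows = []
    for sid in genotypes.snp_ids:
        col = genotypes.dosage[sid]
        n0, n1, n2 = genotype_counts(col)
        n = n0 + n1 + n2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hwe_p = hwe_test(n0, n1, n2, method=hwe_method) if n else float("nan")
        rows.append(
            SNPStats(
                snp_id=sid,
                n0=n0,
                n1=n1,
                n2=n2,
                maf=compute_maf(col) if n else float("nan"),
                hwe_p=hwe_p,
                call_rate=n / len(col),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("snp_id")


def _code_genotype(g: np.ndarray, coding: str) -> np.ndarray:
    if coding == "additive":
        return g
    if coding == "dominant":
        return (g > 0).astype(float)
    if coding == "recessive":
        return (g == 2).astype(float)
    raise ValueError(f"unknown genotype coding {coding!r}")


def logistic_assoc(
    snp: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    coding: str = "additive",
    term: str = "snp",
) -> EffectEstimate:
    """Wald OR, 95% CI and p for one SNP in an adjusted logistic model.

    Fitted by iteratively reweighted least squares (Newton); with no
    covariates the dominant-coded fit equals the classic 2x2
    cross-product odds ratio.  Separation (|beta| > 15 or
    non-convergence) is flagged rather than reported as a finite OR.
    """
    g = np.asarray(snp, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mask = ~np.isnan(g)
    X = pd.DataFrame({term: _code_genotype(g[mask], coding)})
    cov_names: tuple[str, ...] = ()
    if covariates is not None and covariates.shape[1]:
        if len(covariates) != len(g):
            raise ValueError("covariates must align row-wise with the SNP column")
        cov = pd.DataFrame(
            np.asarray(covariates, dtype=float)[mask], columns=list(covariates.columns)
        )
        cov_names = tuple(covariates.columns)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X, has_constant="add")
    yv = y[mask]
    # drop collinear columns (keep the SNP term and intercept)
    model = sm.Logit(yv, X.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=100, tol=1e-10)
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        converged = bool(fit.mle_retvals.get("converged", True)) and abs(beta) <= _SEPARATION_BETA and np.isfinite(se)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        beta, se, converged = float("nan"), float("nan"), False
    except Exception as exc:  # statsmodels raises PerfectSeparationWarning-as-error variants
        if "eparation" in type(exc).__name__ or "ingular" in type(exc).__name__:
            beta, se, converged = float("nan"), float("nan"), False
        else:
            raise
    if not converged:
        return EffectEstimate(
            term=term, or_value=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_value=float("nan"), beta=beta, se=se, n=int(mask.sum()),
            covariates=cov_names, converged=False,
        )
    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        term=term,
        or_value=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(2 * stats.norm.sf(abs(beta / se))),
        beta=beta,
        se=se,
        n=int(mask.sum()),
        covariates=cov_names,
    )


def association_table(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    covariates: Sequence[str] | None = None,
    coding: str = "additive",
    hwe_method: str = "chi2",
) -> pd.DataFrame:
    """Per-SNP QC + adjusted association results, one row per SNP.

    Columns mirror a GWAS candidate table: chrom, position, minor,
    major, OR with CI, p, MAF, HWE p, call rate.
    """
    qc = snp_qc_table(genotypes, hwe_method=hwe_method)
    cov_frame = cohort.covariate_frame(covariates) if covariates is not None else (
        cohort.covariate_frame() if cohort.manifest is not None and cohort.manifest.covariates else None
    )
    y = cohort.outcome
    rows = []
    for sid in genotypes.snp_ids:
        est = logistic_assoc(genotypes.dosage[sid], y, cov_frame, coding=coding, term="snp")
        meta = genotypes.snps.loc[sid]
        rows.append(
            {
                "snp_id": sid,
                "chrom": meta["chrom"],
                "position": meta["position"],
                "minor_allele": meta["minor_allele"],
                "major_allele": meta["major_allele"],
                "or_value": est.or_value,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p_value": est.p_value,
                "maf": qc.loc[sid, "maf"],
                "hwe_p": qc.loc[sid, "hwe_p"],
                "call_rate": qc.loc[sid, "call_rate"],
                "converged": est.converged,
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


def select_candidates(
    table: pd.DataFrame,
    p_threshold: float = 1e-6,
    maf_min: float = 0.01,
    hwe_min: float = 0.05,
) -> list[str]:
    """SNPs passing association p < ``p_threshold``, MAF > ``maf_min``
    and HWE p > ``hwe_min``, sorted by ascending association p."""
    for name, value in (("p_threshold", p_threshold), ("maf_min", maf_min), ("hwe_min", hwe_min)):
        if not (0.0 < value < 1.0):
            raise ValueError(f"{name} must be in (0, 1)")
    ok = (
        (table["p_value"] < p_threshold)
        & (table["maf"] > maf_min)
        & (table["hwe_p"] > hwe_min)
        & table.get("converged", True)
    )
    kept = table.loc[ok].sort_values("p_value")
    return list(kept.index)
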