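"""PRS x lifestyle interaction analysis.

Exposures are dichotomized at declared cutoffs (high includes the
cutoff value; percentile cutoffs — e.g. the 70th percentile of a diet
pattern score — are computed on the full analysis sample), PRS-category
odds ratios are estimated within each exposure stratum with the low-PRS
band as reference, and the PRS x exposure interaction is tested by a
likelihood-ratio test of product terms (Wald by option).  The PRS
enters the interaction as an ordered 0/1/2 category score by default
(1 df); a categorical 2-df variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import EffectEstimate
from .prs import CATEGORIES, prs_category_or

__all__ = [
    "ExposureCut",
    "dichotomize",
    "stratified_prs_or",
    "interaction_test",
    "InteractionResult",
]


@dataclass(frozen=True)
class ExposureCut:
    """How to split one exposure into low/high.

    ``high`` declares which side of the cutoff is the "high" group;
    the boundary value itself always belongs to high when ``high="ge"``
    (the default) and to low when ``high="lt"``.  With
    ``percentile=True`` the cutoff is a percentile (0-100) evaluated on
    the analysis sample.
    """

    name: str
    cutoff: float
    high: str = "ge"
    percentile: bool = False
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError(f"{self.name}: cutoff must be finite")
        if self.high not in ("ge", "lt"):
            raise ValueError(f"{self.name}: high side must be 'ge' or 'lt'")
        if self.percentile and not (0 < self.cutoff < 100):
            raise ValueError(f"{self.name}: percentile cutoff must be in (0, 100)")


def dichotomize(
    data: pd.DataFrame, cuts: list[ExposureCut] | ExposureCut, suffix: str = "_high"
) -> pd.DataFrame:
    """Binary high/low columns (``<name>_high`` in {0,1}) per cut.

    Raises when a column is constant or ends up all on one side —
    a one-sided "exposure" cannot stratify anything.
    """
    if isinstance(cuts, ExposureCut):
        cuts = [cuts]
    out = data.copy()
    for cut in cuts:
        if cut.name not in data.columns:
            raise KeyError(f"exposure column {cut.name!r} absent")
        x = data[cut.name].astype(float)
        thr = float(np.percentile(x.dropna(), cut.cutoff)) if cut.percentile else cut.cutoff
        hi = x >= thr if cut.high == "ge" else x < thr
        hi = hi.astype(int)
        if hi.nunique() < 2:
            raise ValueError(
                f"exposure {cut.name!r}: all subjects fall on one side of the cutoff {thr}"
            )
        out[cut.name + suffix] = hi
    return out


@dataclass
class InteractionResult:
    """Stratified PRS-category ORs plus the interaction p-value."""

    exposure: str
    strata: pd.DataFrame  # rows: (exposure level, PRS category) -> OR, CI, p
    interaction_p: float
    method: str
    df: int


def _check_rank(X: pd.DataFrame) -> None:
    arr = sm.add_constant(np.asarray(X, float), has_constant="add")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (a covariate duplicates the exposure "
            "or a PRS term); drop the colliding column"
        )


def stratified_prs_or(
    categories: pd.Series,
    exposure_high: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
) -> pd.DataFrame:
    """Adjusted medium-/high-PRS odds ratios within each exposure level.

    Returns one row per (level, category) — exactly 2 levels x 3
    categories — with the low-PRS reference fixed at OR 1.  Sparse or
    separated cells are reported as non-estimable (``converged`` False),
    never silently dropped.
    """
    cat = pd.Series(pd.Categorical(categories, categories=list(CATEGORIES), ordered=True)).reset_index(drop=True)
    hi = np.asarray(exposure_high, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = None
    rows = []
    for level, label in ((0, "low"), (1, "high")):
        m = hi == level
        if covariates is not None:
            cov = pd.DataFrame(np.asarray(covariates, float)[m], columns=list(covariates.columns))
        try:
            ests = prs_category_or(cat[m], y[m], cov)
        except ValueError:
            ests = {
                c: EffectEstimate(f"prs_{c}", float("nan"), float("nan"), float("nan"),
                                  float("nan"), n=int(m.sum()), converged=False)
                for c in CATEGORIES
            }
        for c in CATEGORIES:
            e = ests[c]
            rows.append(
                {
                    "exposure": exposure_name, "level": label, "category": c,
                    "or_value": e.or_value, "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "p_value": e.p_value, "n": int(m.sum()), "estimable": e.converged,
                }
            )
    return pd.DataFrame(rows)


def interaction_test(
    categories: pd.Series,
    exposure_high: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    method: str = "lr",
    prs_coding: str = "ordinal",
) -> tuple[float, dict]:
    """Test PRS x exposure effect modification in an adjusted model.

    Compares the main-effects logistic model (PRS terms + exposure +
    covariates) against the model with PRS x exposure product terms.
    ``prs_coding="ordinal"`` uses the 0/1/2 category score (1 df);
    ``"categorical"`` uses both category dummies (2 df).  ``method`` is
    "lr" (likelihood ratio, default) or "wald".
    """
    cat = pd.Categorical(categories, categories=list(CATEGORIES), ordered=True)
    codes = np.asarray(cat.codes, dtype=float)
    if (codes < 0).any():
        raise ValueError("categories contain values outside low/medium/high")
    hi = np.asarray(exposure_high, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if prs_coding == "ordinal":
        main = {"prs_score": codes, "exposure": hi}
        inter = {"prs_score:exposure": codes * hi}
    elif prs_coding == "categorical":
        main = {
            "prs_medium": (codes == 1).astype(float),
            "prs_high": (codes == 2).astype(float),
            "exposure": hi,
        }
        inter = {
            "prs_medium:exposure": (codes == 1) * hi,
            "prs_high:exposure": (codes == 2) * hi,
        }
    else:
        raise ValueError(f"unknown prs_coding {prs_coding!r}")

    def build(extra: dict) -> pd.DataFrame:
        cols = dict(main)
        cols.update(extra)
        X = pd.DataFrame({k: np.asarray(v, float) for k, v in cols.items()})
        if covariates is not None and covariates.shape[1]:
            X = pd.concat(
                [X, pd.DataFrame(np.asarray(covariates, float), columns=list(covariates.columns))],
                axis=1,
            )
        return X

    X0, X1 = build({}), build(inter)
    _check_rank(X1)
    fit0 = sm.Logit(y, sm.add_constant(X0.astype(float), has_constant="add")).fit(disp=0, maxiter=100)
    fit1 = sm.Logit(y, sm.add_constant(X1.astype(float), has_constant="add")).fit(disp=0, maxiter=100)
    df = len(inter)
    detail = {"llf_main": float(fit0.llf), "llf_inter": float(fit1.llf), "df": df}
    if not (fit0.mle_retvals.get("converged", True) and fit1.mle_retvals.get("converged", True)):
        raise RuntimeError("interaction model did not converge (possible separation)")
    if method == "lr":
        lr = 2.0 * (fit1.llf - fit0.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df))
        detail["statistic"] = float(lr)
    elif method == "wald":
        terms = list(inter)
        r = np.zeros((len(terms), len(fit1.params)))
        names = list(fit1.params.index)
        for i, t in enumerate(terms):
            r[i, names.index(t)] = 1.0
        wt = fit1.wald_test(r, scalar=True)
        p = float(wt.pvalue)
        detail["statistic"] = float(wt.statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, detail


def interaction_table(
    categories: pd.Series,
    cohort_data: pd.DataFrame,
    cuts: list[ExposureCut],
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    drop_colliding_covariates: bool = True,
    method: str = "lr",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Stratified OR grid + interaction p for each exposure cut.

    When the tested exposure also appears among the covariates it is
    dropped from the adjustment set for that exposure's models (the
    collision otherwise makes the design singular).
    """
    di = dichotomize(cohort_data, cuts)
    all_rows = []
    pvals: dict[str, float] = {}
    for cut in cuts:
        cov = covariates
        if cov is not None and drop_colliding_covariates:
            collide = [c for c in cov.columns if c == cut.name or c.startswith(cut.name + "_")]
            if collide:
                cov = cov.drop(columns=collide)
        hi = di[cut.name + "_high"]
        grid = stratified_prs_or(categories, hi, outcome, cov, exposure_name=cut.name)
        try:
            p, _ = interaction_test(categories, hi, outcome, cov, method=method)
        except RuntimeError:
            # sparse stratum / separation: the test is non-estimable here
            p = float("nan")
        grid["interaction_p"] = p
        pvals[cut.name] = p
        all_rows.append(grid)
    return pd.concat(all_rows, ignore_index=True), pvals
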