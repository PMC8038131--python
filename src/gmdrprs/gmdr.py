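"""Generalized multifactor dimensionality reduction (GMDR).

The engine pools multilocus genotype cells into high- and low-risk
classes using per-subject score residuals from a covariate-only
(null) logistic model: a cell is high-risk when its training-score sum
exceeds a threshold (default 0, ties low).  Each candidate SNP subset is
evaluated by 10-fold stratified cross-validation with balanced accuracy
(mean of sensitivity and specificity) on the training nine-tenths
(TRBA) and the held-out tenth (TEBA); model selection reports the
number of folds whose test balanced accuracy beats 0.5 (the MDR sign
test, an exact binomial(n_folds, 1/2) tail) and cross-validation
consistency (how many folds' training-best subset equals the overall
best).

With no covariates and an intercept-only null model the scores reduce
to y - mean(y), and the cell-labeling rule coincides with classic MDR's
case:control-ratio rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "GMDRResult",
    "CellPartition",
    "compute_scores",
    "partition_cells",
    "balanced_accuracy",
    "cross_validate",
    "sign_test",
    "search_best_models",
    "GMDRSearch",
]


@dataclass(frozen=True)
class GMDRResult:
    """One row of a GMDR model-selection table."""

    snps: tuple[str, ...]
    trba: float
    teba: float
    fold_wins: int
    sign_p: float
    cvc: int
    n_folds: int
    n_evaluated: int = 1

    @property
    def k(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class CellPartition:
    """High/low labels over the 3^k multilocus genotype cells.

    ``high`` is a boolean array of length 3^k; cells never observed in
    training are labeled low (``observed`` False).  Cell index is
    sum_j g_j * 3^j over the combination's SNPs in order.
    """

    snps: tuple[str, ...]
    high: np.ndarray
    observed: np.ndarray
    score_sums: np.ndarray
    threshold: float

    @property
    def n_cells(self) -> int:
        return len(self.high)


def compute_scores(
    outcome: np.ndarray | pd.Series, covariates: pd.DataFrame | None = None
) -> np.ndarray:
    """Per-subject GMDR scores: response residuals y - p-hat from the
    covariate-only logistic null model (y - mean(y) with no covariates).

    With an intercept in the null model the scores sum to ~0.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    X = sm.add_constant(np.asarray(covariates, dtype=float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
    except Exception as exc:
        raise RuntimeError(
            f"null model with covariates {list(covariates.columns)} did not converge: {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"null model with covariates {list(covariates.columns)} did not converge"
        )
    return y - fit.predict(X)


def _cell_codes(geno: np.ndarray) -> np.ndarray:
    """Integer cell index per subject for an n x k genotype slice;
    subjects with any missing genotype get code -1."""
    g = np.asarray(geno, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    codes = np.zeros(len(g), dtype=np.int64)
    ok = np.ones(len(g), dtype=bool)
    for j in range(g.shape[1]):
        col = g[:, j]
        ok &= ~np.isnan(col)
        codes += np.nan_to_num(col).astype(np.int64) * (3**j)
    codes[~ok] = -1
    return codes


def partition_cells(
    geno: np.ndarray | pd.DataFrame,
    scores: np.ndarray,
    threshold: float = 0.0,
    snps: Sequence[str] | None = None,
) -> CellPartition:
    """Label each multilocus cell high (score sum > threshold) or low.

    Ties at the threshold and cells with no training subjects are low.
    """
    if isinstance(geno, pd.DataFrame):
        if snps is None:
            snps = tuple(geno.columns)
        geno = geno.to_numpy()
    geno = np.atleast_2d(np.asarray(geno, dtype=float))
    if geno.shape[0] == 1 and len(scores) != 1:
        geno = geno.T
    k = geno.shape[1]
    n_cells = 3**k
    codes = _cell_codes(geno)
    valid = codes >= 0
    sums = np.bincount(codes[valid], weights=np.asarray(scores)[valid], minlength=n_cells)
    counts = np.bincount(codes[valid], minlength=n_cells)
    observed = counts > 0
    high = (sums > threshold) & observed
    return CellPartition(
        snps=tuple(snps) if snps is not None else tuple(f"snp{j}" for j in range(k)),
        high=high,
        observed=observed,
        score_sums=sums,
        threshold=threshold,
    )


def _ba_from_cell_counts(case: np.ndarray, ctrl: np.ndarray, high: np.ndarray) -> float:
    tp = case[high].sum()
    fn = case[~high].sum()
    tn = ctrl[~high].sum()
    fp = ctrl[high].sum()
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("balanced accuracy undefined: a class is absent")
    return float(0.5 * (tp / (tp + fn) + tn / (tn + fp)))


def balanced_accuracy(
    partition: CellPartition, geno: np.ndarray | pd.DataFrame, outcome: np.ndarray
) -> float:
    """Mean of sensitivity and specificity when predicting case for
    subjects whose cell is labeled high."""
    if isinstance(geno, pd.DataFrame):
        geno = geno.to_numpy()
    codes = _cell_codes(np.atleast_2d(np.asarray(geno, float)).reshape(len(outcome), -1))
    y = np.asarray(outcome, dtype=float)
    valid = codes >= 0
    case = np.bincount(codes[valid], weights=y[valid], minlength=partition.n_cells)
    tot = np.bincount(codes[valid], minlength=partition.n_cells)
    return _ba_from_cell_counts(case, tot - case, partition.high)


def sign_test(fold_wins: int, n_folds: int = 10) -> float:
    """One-sided exact binomial tail P(X >= fold_wins | n_folds, 1/2)."""
    if not (0 <= fold_wins <= n_folds):
        raise ValueError("fold_wins must be between 0 and n_folds")
    total = sum(math.comb(n_folds, i) for i in range(fold_wins, n_folds + 1))
    return float(total / 2**n_folds)


def fold_assignments(
    subject_ids: Sequence, outcome: np.ndarray, n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Stratified fold ids keyed to subject id + seed, not row order.

    Subjects are sorted by id within each outcome class, shuffled with
    the seeded generator, and dealt round-robin, so permuting the input
    rows permutes the fold ids identically.
    """
    ids = np.asarray([str(s) for s in subject_ids])
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique for fold assignment")
    y = np.asarray(outcome, dtype=int)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(ids), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) == 0:
            continue
        order = idx[np.argsort(ids[idx])]  # row-order-invariant canonical order
        shuffled = rng.permutation(order)
        folds[shuffled] = np.arange(len(shuffled)) % n_folds
    return folds


def _check_folds(y: np.ndarray, folds: np.ndarray, n_folds: int) -> None:
    for f in range(n_folds):
        test = folds == f
        if y[test].sum() == 0 or (1 - y[test]).sum() == 0:
            raise ValueError(
                f"fold {f} lacks a class; use stratified folds / another seed "
                "or fewer folds for this sample size"
            )


def _evaluate_combos(
    geno: np.ndarray,
    combos: list[tuple[int, ...]],
    y: np.ndarray,
    scores: np.ndarray,
    folds: np.ndarray,
    n_folds: int,
    threshold: float,
    empty_cell: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and test balanced accuracy per (combo, fold).

    Cell bookkeeping is done with bincounts of case/control/score sums,
    so each combo-fold costs O(n + 3^k).
    """
    n = len(y)
    train_ba = np.empty((len(combos), n_folds))
    test_ba = np.empty((len(combos), n_folds))
    for ci, combo in enumerate(combos):
        codes = _cell_codes(geno[:, combo])
        n_cells = 3 ** len(combo)
        valid = codes >= 0
        for f in range(n_folds):
            tr = valid & (folds != f)
            te = valid & (folds == f)
            sums = np.bincount(codes[tr], weights=scores[tr], minlength=n_cells)
            case_tr = np.bincount(codes[tr], weights=y[tr], minlength=n_cells)
            tot_tr = np.bincount(codes[tr], minlength=n_cells)
            high = (sums > threshold) & (tot_tr > 0)
            train_ba[ci, f] = _ba_from_cell_counts(case_tr, tot_tr - case_tr, high)
            codes_te = codes[te]
            y_te = y[te]
            if empty_cell == "exclude":
                seen = tot_tr[codes_te] > 0
                codes_te, y_te = codes_te[seen], y_te[seen]
            case_te = np.bincount(codes_te, weights=y_te, minlength=n_cells)
            tot_te = np.bincount(codes_te, minlength=n_cells)
            test_ba[ci, f] = _ba_from_cell_counts(case_te, tot_te - case_te, high)
    return train_ba, test_ba


def _select_best(
    combos: list[tuple[int, ...]], train_ba: np.ndarray, test_ba: np.ndarray
) -> tuple[int, np.ndarray, np.ndarray]:
    """Best combo index by mean TEBA (ties: higher CVC, then the
    lexicographically earliest combination), plus per-combo CVC."""
    teba = test_ba.mean(axis=1)
    fold_best = np.argmax(train_ba, axis=0)  # ties -> lowest index = lexicographic
    cvc = np.bincount(fold_best, minlength=len(combos))
    order = sorted(
        range(len(combos)), key=lambda i: (-round(teba[i], 12), -cvc[i], combos[i])
    )
    return order[0], teba, cvc


def cross_validate(
    geno: pd.DataFrame | np.ndarray,
    outcome: np.ndarray | pd.Series,
    scores: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.0,
    empty_cell: str = "low",
    subject_ids: Sequence | None = None,
) -> GMDRResult:
    """Cross-validate a single SNP combination; returns its GMDRResult
    (CVC is trivially n_folds for a single candidate)."""
    if isinstance(geno, pd.DataFrame):
        snps = tuple(geno.columns)
        if subject_ids is None:
            subject_ids = list(geno.index)
        geno_arr = geno.to_numpy(dtype=float)
    else:
        geno_arr = np.atleast_2d(np.asarray(geno, dtype=float))
        if geno_arr.shape[0] == 1 and len(outcome) != 1:
            geno_arr = geno_arr.T
        snps = tuple(f"snp{j}" for j in range(geno_arr.shape[1]))
    y = np.asarray(outcome, dtype=float)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(len(y))]
    if scores is None:
        scores = compute_scores(y, covariates)
    folds = fold_assignments(subject_ids, y, n_folds, seed)
    _check_folds(y, folds, n_folds)
    combo = tuple(range(geno_arr.shape[1]))
    train_ba, test_ba = _evaluate_combos(
        geno_arr, [combo], y, np.asarray(scores), folds, n_folds, threshold, empty_cell
    )
    wins = int((test_ba[0] > 0.5).sum())
    return GMDRResult(
        snps=snps,
        trba=float(train_ba[0].mean()),
        teba=float(test_ba[0].mean()),
        fold_wins=wins,
        sign_p=sign_test(wins, n_folds),
        cvc=n_folds,
        n_folds=n_folds,
        n_evaluated=1,
    )


def search_best_models(
    geno: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    k_range: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.0,
    empty_cell: str = "low",
    strategy: str = "exhaustive",
) -> list[GMDRResult]:
    """Best SNP combination per model size k, GMDR-style.

    ``exhaustive`` evaluates every k-subset of the candidates (the
    default; candidate counts are expected to be small after LD
    pruning).  ``forward`` grows the model greedily one SNP at a time,
    reproducing nested model sequences.
    """
    snp_ids = list(geno.columns)
    m = len(snp_ids)
    y = np.asarray(outcome, dtype=float)
    scores = compute_scores(y, covariates)
    folds = fold_assignments(list(geno.index), y, n_folds, seed)
    _check_folds(y, folds, n_folds)
    geno_arr = geno.to_numpy(dtype=float)

    results: list[GMDRResult] = []
    selected: tuple[int, ...] = ()
    for k in k_range:
        if k > m:
            raise ValueError(f"model size k={k} exceeds {m} candidate SNPs")
        if strategy == "exhaustive":
            combos = list(combinations(range(m), k))
        elif strategy == "forward":
            combos = [
                tuple(sorted(selected + (j,))) for j in range(m) if j not in selected
            ]
        else:
            raise ValueError(f"unknown search strategy {strategy!r}")
        train_ba, test_ba = _evaluate_combos(
            geno_arr, combos, y, scores, folds, n_folds, threshold, empty_cell
        )
        best_i, teba, cvc = _select_best(combos, train_ba, test_ba)
        wins = int((test_ba[best_i] > 0.5).sum())
        results.append(
            GMDRResult(
                snps=tuple(snp_ids[j] for j in combos[best_i]),
                trba=float(train_ba[best_i].mean()),
                teba=float(teba[best_i]),
                fold_wins=wins,
                sign_p=sign_test(wins, n_folds),
                cvc=int(cvc[best_i]),
                n_folds=n_folds,
                n_evaluated=len(combos),
            )
        )
        selected = combos[best_i]
    return results


def results_table(results: Sequence[GMDRResult]) -> pd.DataFrame:
    """GMDR model-selection rows: one per model size."""
    return pd.DataFrame(
        {
            "k": [r.k for r in results],
            "model": [" ".join(r.snps) for r in results],
            "trba": [r.trba for r in results],
            "teba": [r.teba for r in results],
            "fold_wins": [r.fold_wins for r in results],
            "sign_p": [r.sign_p for r in results],
            "cvc": [f"{r.cvc}/{r.n_folds}" for r in results],
            "n_evaluated": [r.n_evaluated for r in results],
        }
    )


class GMDRSearch(BaseEstimator, ClassifierMixin):
    """Exhaustive GMDR model search as a scikit-learn style classifier.

    Parameters
    ----------
    k_min, k_max:
        Range of model sizes (numbers of SNPs) to search; ``k_max=None``
        searches up to all candidates.
    n_folds:
        Stratified cross-validation folds (10 for cohorts above ~1000).
    seed:
        Seed for fold construction.
    threshold:
        Cell score-sum threshold separating high from low risk
        (default 0; ties and empty cells are low risk).
    strategy:
        "exhaustive" (every k-subset) or "forward" (greedy nesting).
    empty_cell:
        Test-time policy for genotype cells unseen in training:
        predict "low" (default) or "exclude" the subject.

    After ``fit(X, y, covariates=...)``:

    - ``results_``: one :class:`GMDRResult` per model size,
    - ``best_result_`` / ``best_snps_``: overall winner by sign-test p,
      then test balanced accuracy, then CVC,
    - ``partition_``: high/low cell labels of the best model refit on
      the full sample (used by :meth:`predict`).
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int | None = None,
        n_folds: int = 10,
        seed: int = 0,
        threshold: float = 0.0,
        strategy: str = "exhaustive",
        empty_cell: str = "low",
    ) -> None:
        self.k_min = k_min
        self.k_max = k_max
        self.n_folds = n_folds
        self.seed = seed
        self.threshold = threshold
        self.strategy = strategy
        self.empty_cell = empty_cell

    def fit(self, X, y, covariates: pd.DataFrame | None = None) -> "GMDRSearch":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"snp{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        k_max = self.k_max if self.k_max is not None else X.shape[1]
        self.results_ = search_best_models(
            X,
            y,
            covariates=covariates,
            k_range=range(self.k_min, k_max + 1),
            n_folds=self.n_folds,
            seed=self.seed,
            threshold=self.threshold,
            empty_cell=self.empty_cell,
            strategy=self.strategy,
        )
        self.best_result_ = min(
            self.results_, key=lambda r: (r.sign_p, -r.teba, -r.cvc, r.k)
        )
        self.best_snps_ = list(self.best_result_.snps)
        self.scores_ = compute_scores(y, covariates)
        self.partition_ = partition_cells(
            X[self.best_snps_], self.scores_, self.threshold, snps=self.best_snps_
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        """Predict case (1) for subjects whose best-model cell is high risk."""
        if not hasattr(self, "partition_"):
            raise RuntimeError("GMDRSearch is not fitted")
        if isinstance(X, pd.DataFrame):
            geno = X[self.best_snps_].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            idx = [list(self.feature_names_in_).index(s) for s in self.best_snps_]
            geno = X[:, idx]
        codes = _cell_codes(geno)
        pred = np.zeros(len(codes), dtype=int)
        ok = codes >= 0
        pred[ok] = self.partition_.high[codes[ok]].astype(int)
        return pred

    def results_table(self) -> pd.DataFrame:
        return results_table(self.results_)
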