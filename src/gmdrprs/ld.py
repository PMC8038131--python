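"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are estimated by the EM algorithm (only the
double-heterozygote class is ambiguous for two biallelic loci), then
summarized as D, |D'| and r^2.  Candidate SNP pairs on the same
chromosome with |D'| at or above a threshold (default 0.4) are pruned
greedily, keeping the more significant SNP of each pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["LDResult", "em_haplotypes", "dprime", "ld_table", "prune_by_ld"]


@dataclass(frozen=True)
class LDResult:
    """Pairwise LD summary; haplotype order is (AB, Ab, aB, ab) with
    A/B the minor alleles at the two loci."""

    snp_a: str
    snp_b: str
    hap_freqs: tuple[float, float, float, float]
    d: float
    d_prime: float
    r2: float
    n: int


def _two_locus_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    mask = ~(np.isnan(ga) | np.isnan(gb))
    a = ga[mask].astype(int)
    b = gb[mask].astype(int)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    return counts


def em_haplotypes(
    ga: np.ndarray | pd.Series,
    gb: np.ndarray | pd.Series,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[float, float, float, float]:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Inputs are additive minor-allele counts; subjects missing either
    genotype are excluded.  Returns (f_AB, f_Ab, f_aB, f_ab) where
    upper-case letters denote minor alleles.  The EM likelihood is
    non-decreasing; iteration stops when no frequency moves more than
    ``tol``.
    """
    counts = _two_locus_counts(np.asarray(ga, float), np.asarray(gb, float))
    n_subj = counts.sum()
    if n_subj < 1:
        raise ValueError("no doubly-called subjects")
    # haplotype counts fully determined outside the (1,1) cell:
    # genotype (i, j) contributes i copies of A and j copies of B
    base = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 1): (0, 0, 0, 0), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for (i, j), hap in contrib.items():
        base += counts[i, j] * np.asarray(hap, float)
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    total = 2.0 * n_subj
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        w = 0.5 if denom == 0 else f[0] * f[3] / denom  # P(AB/ab | double het)
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= total
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return tuple(float(v) for v in f)  # type: ignore[return-value]


def dprime(hap_freqs: Sequence[float]) -> float:
    """Normalized |D'| in [0, 1] from (AB, Ab, aB, ab) frequencies."""
    f = np.asarray(hap_freqs, dtype=float)
    if f.min() < -1e-12 or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("hap_freqs must be non-negative and sum to 1")
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        warnings.warn("monomorphic locus: D' defined as 0", stacklevel=2)
        return 0.0
    d = f[0] - p_a * p_b
    if d > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if dmax == 0.0:
        return 0.0
    return float(abs(d) / dmax)


def ld_pair(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> LDResult:
    ga = genotypes.dosage[snp_a].to_numpy()
    gb = genotypes.dosage[snp_b].to_numpy()
    f = em_haplotypes(ga, gb)
    p_a, p_b = f[0] + f[1], f[0] + f[2]
    d = f[0] - p_a * p_b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dp = dprime(f)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = float(d * d / denom) if denom > 0 else 0.0
    n = int(np.sum(~(np.isnan(ga) | np.isnan(gb))))
    return LDResult(snp_a, snp_b, f, float(d), dp, r2, n)


def ld_table(
    genotypes: GenotypeMatrix, snp_ids: Sequence[str] | None = None, within_chrom: bool = True
) -> pd.DataFrame:
    """Pairwise LD rows for the given SNPs (all pairs, or same-chromosome
    pairs only, the default — cross-chromosome LD is not informative
    for pruning)."""
    ids = list(snp_ids) if snp_ids is not None else genotypes.snp_ids
    chrom = genotypes.snps["chrom"]
    rows = []
    for a, b in combinations(ids, 2):
        if within_chrom and chrom[a] != chrom[b]:
            continue
        r = ld_pair(genotypes, a, b)
        rows.append(
            {
                "snp_a": a, "snp_b": b, "chrom": chrom[a],
                "f_AB": r.hap_freqs[0], "f_Ab": r.hap_freqs[1],
                "f_aB": r.hap_freqs[2], "f_ab": r.hap_freqs[3],
                "d": r.d, "d_prime": r.d_prime, "r2": r.r2, "n": r.n,
            }
        )
    cols = ["snp_a", "snp_b", "chrom", "f_AB", "f_Ab", "f_aB", "f_ab", "d", "d_prime", "r2", "n"]
    return pd.DataFrame(rows, columns=cols)


def prune_by_ld(
    candidates: Sequence[str],
    genotypes: GenotypeMatrix,
    p_values: Mapping[str, float],
    threshold: float = 0.4,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy same-chromosome LD pruning at |D'| >= ``threshold``.

    Candidates are visited in order of ascending association p-value
    (most significant first); a candidate is dropped when it is in
    strong LD with an already-kept SNP on the same chromosome.  Returns
    the kept list (original candidate order) and a removal log with one
    row per dropped SNP (partner and |D'|).  Given distinct p-values the
    result does not depend on the input order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    missing = [s for s in candidates if s not in p_values]
    if missing:
        raise ValueError(f"no p-value for candidates {missing[:5]}")
    chrom = genotypes.snps["chrom"]
    by_sig = sorted(candidates, key=lambda s: (p_values[s], s))
    kept: list[str] = []
    removals = []
    for snp in by_sig:
        partner = None
        dp_hit = None
        for other in kept:
            if chrom[other] != chrom[snp]:
                continue
            dp = ld_pair(genotypes, snp, other).d_prime
            if dp >= threshold:
                partner, dp_hit = other, dp
                break
        if partner is None:
            kept.append(snp)
        else:
            removals.append(
                {"removed": snp, "kept_partner": partner, "d_prime": dp_hit,
                 "removed_p": p_values[snp], "kept_p": p_values[partner]}
            )
    kept_in_order = [s for s in candidates if s in set(kept)]
    log = pd.DataFrame(removals, columns=["removed", "kept_partner", "d_prime", "removed_p", "kept_p"])
    return kept_in_order, log
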