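"""Synthetic case-control cohorts with the structure the pipeline assumes.

Emulates a large hospital-based Korean cohort (~0.9% thyroid-cancer
prevalence) at desk scale: tens of biallelic SNPs in Hardy-Weinberg
proportions with realistic minor-allele frequencies (0.02-0.38),
per-SNP odds ratios in the 0.76-1.94 range, optional two-locus
epistatic penetrance cells, optional two-locus LD blocks, and
covariates/exposures (gender, age, BMI, white-blood-cell count, energy
percent of requirement, alcohol g/day, seaweed g/day, 29 food-group
intakes with a four-factor latent diet-pattern structure).

All randomness flows from one explicit seed through
:class:`numpy.random.SeedSequence`; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import CohortTable, ColumnManifest, GenotypeMatrix

__all__ = [
    "SNPSpec",
    "LDBlock",
    "EpistasisTerm",
    "DiseaseModel",
    "ExposureSpec",
    "DEFAULT_SNP_SPECS",
    "DEFAULT_EXPOSURE_SPECS",
    "FOOD_GROUPS",
    "DIET_PATTERN_BLOCKS",
    "simulate_genotypes",
    "simulate_outcome",
    "simulate_exposures",
    "simulate_food_groups",
    "simulate_study",
]


@dataclass(frozen=True)
class SNPSpec:
    """A biallelic SNP: id, location, allele symbols and population MAF."""

    snp_id: str
    chrom: str
    position: int
    minor_allele: str
    major_allele: str
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.minor_allele == self.major_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")


#: Ten biallelic markers with the chromosome, position, allele and MAF
#: profile of a published thyroid-cancer candidate set (MAF 0.020-0.378).
DEFAULT_SNP_SPECS: tuple[SNPSpec, ...] = (
    SNPSpec("rs6759952", "2", 218271719, "T", "C", 0.2491),
    SNPSpec("rs1369535", "2", 142636357, "G", "A", 0.3784),
    SNPSpec("rs13059137", "3", 115347556, "C", "T", 0.3443),
    SNPSpec("rs72616195", "4", 16043608, "T", "C", 0.3467),
    SNPSpec("rs76981250", "8", 18761954, "T", "C", 0.02597),
    SNPSpec("rs78371177", "8", 23224452, "G", "A", 0.03784),
    SNPSpec("rs7834206", "8", 32406148, "G", "A", 0.209),
    SNPSpec("rs605859", "11", 126407440, "C", "T", 0.06575),
    SNPSpec("rs11175834", "12", 65992636, "C", "T", 0.1554),
    SNPSpec("rs2276010", "22", 22142501, "C", "T", 0.02019),
)

#: Per-SNP odds ratios matching the candidate set above (0.76-1.94);
#: note the first marker's risk sits on the MAJOR allele (minor OR < 1).
DEFAULT_SNP_ORS: dict[str, float] = {
    "rs6759952": 0.76,
    "rs1369535": 1.27,
    "rs13059137": 1.29,
    "rs72616195": 1.29,
    "rs76981250": 1.77,
    "rs78371177": 1.66,
    "rs7834206": 1.46,
    "rs605859": 1.51,
    "rs11175834": 1.39,
    "rs2276010": 1.94,
}


@dataclass(frozen=True)
class LDBlock:
    """Request that two simulated SNPs be in LD at a given |D'|."""

    snp_a: str
    snp_b: str
    d_prime: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_prime <= 1.0):
            raise ValueError("d_prime must be in [0, 1]")


@dataclass(frozen=True)
class EpistasisTerm:
    """Penetrance increments on specific two-locus genotype cells.

    ``cell_effects`` maps (minor-count at snp_a, minor-count at snp_b)
    -> additive log-odds increment.  Cell-pattern effects (rather than
    product terms) are what MDR-type methods detect, which keeps the
    downstream recovery experiments well-posed.
    """

    snp_a: str
    snp_b: str
    cell_effects: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (ga, gb), eff in self.cell_effects.items():
            if ga not in (0, 1, 2) or gb not in (0, 1, 2):
                raise ValueError(f"invalid genotype cell ({ga}, {gb})")
            if not np.isfinite(eff):
                raise ValueError("cell effect must be finite")


def both_carrier_cells(log_odds: float) -> dict[tuple[int, int], float]:
    """Cell-effect dict adding ``log_odds`` wherever both loci carry >= 1 minor allele."""
    return {(i, j): log_odds for i in (1, 2) for j in (1, 2)}


@dataclass
class DiseaseModel:
    """Additive-logistic disease model with optional epistatic cells.

    The intercept is calibrated by bisection so the realized expected
    prevalence matches ``prevalence_target`` (tolerance 1e-4, <= 50
    iterations); set ``prevalence_target=None`` to use ``intercept``
    verbatim.
    """

    intercept: float = 0.0
    snp_log_or: dict[str, float] = field(default_factory=dict)
    epistasis_terms: list[EpistasisTerm] = field(default_factory=list)
    covariate_log_or: dict[str, float] = field(default_factory=dict)
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        effs = [*self.snp_log_or.values(), *self.covariate_log_or.values(), self.intercept]
        if not np.all(np.isfinite(effs)):
            raise ValueError("all effects must be finite")
        if self.prevalence_target is not None and not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must be in (0, 1)")


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure/covariate column: name, kind and distribution.

    kind "continuous": ``dist`` in {"normal", "lognormal"}, ``params``
    (mean, sd) on the natural / log scale respectively, optional
    ``lower`` truncation bound and ``case_shift`` (additive mean shift
    applied to cases when outcome-dependence is enabled, emulating
    post-diagnosis behaviour change).
    kind "categorical": ``levels`` with sampling ``probs`` (and optional
    ``case_probs``).
    """

    name: str
    kind: str
    dist: str = "normal"
    params: tuple[float, float] = (0.0, 1.0)
    lower: float | None = None
    cutoff: float | None = None
    case_shift: float = 0.0
    levels: tuple = ()
    probs: tuple[float, ...] = ()
    case_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"{self.name}: unknown exposure kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) != len(self.probs) or not self.levels:
                raise ValueError(f"{self.name}: levels/probs mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: probs must sum to 1")
        else:
            if self.dist not in ("normal", "lognormal"):
                raise ValueError(f"{self.name}: unknown dist {self.dist!r}")
            if self.cutoff is not None and self.lower is not None and self.cutoff < self.lower:
                raise ValueError(f"{self.name}: cutoff below distribution support")


#: Marginals loosely matched to the source cohort's summary tables:
#: WBC mean 5.7e9/L (cutoff 4), energy ~96% of estimated requirement
#: (cutoff 100), seaweed intake cutoff 2.65 g/day, alcohol cutoff 20 g/day.
DEFAULT_EXPOSURE_SPECS: tuple[ExposureSpec, ...] = (
    ExposureSpec("age", "continuous", "normal", (53.6, 8.0), lower=40.0, cutoff=55.0),
    ExposureSpec(
        "gender", "categorical", levels=("male", "female"), probs=(0.35, 0.65)
    ),
    ExposureSpec("bmi", "continuous", "normal", (23.9, 3.0), lower=14.0, cutoff=25.0),
    ExposureSpec("wbc", "continuous", "normal", (5.7, 1.5), lower=0.0, cutoff=4.0),
    ExposureSpec("energy_pct", "continuous", "normal", (96.1, 25.0), lower=0.0, cutoff=100.0),
    ExposureSpec("alcohol_g", "continuous", "lognormal", (1.5, 1.3), lower=0.0, cutoff=20.0),
    ExposureSpec("seaweed_g", "continuous", "lognormal", (0.5, 1.0), lower=0.0, cutoff=2.65),
    ExposureSpec(
        "residence_area",
        "categorical",
        levels=("urban", "suburban", "rural"),
        probs=(0.6, 0.25, 0.15),
    ),
    ExposureSpec(
        "education",
        "categorical",
        levels=("lt_high_school", "high_school", "college"),
        probs=(0.19, 0.22, 0.59),
    ),
    ExposureSpec(
        "income",
        "categorical",
        levels=("low", "middle", "high"),
        probs=(0.31, 0.44, 0.25),
    ),
)

#: 29 food groups in the style of a Korean semiquantitative FFQ.
FOOD_GROUPS: tuple[str, ...] = (
    "rice", "noodles", "bread", "cereals", "potatoes", "sweets", "beans",
    "nuts", "green_vegetables", "other_vegetables", "kimchi", "mushrooms",
    "fruits", "red_meat", "poultry", "processed_meat", "eggs", "white_fish",
    "blue_fish", "shellfish", "seaweeds", "milk", "dairy", "oils",
    "sugary_beverages", "tea", "coffee", "soups", "snacks",
)

#: Latent diet patterns (factor -> food groups loading on it); the four
#: blocks emulate traditional-balanced, prudent, noodle/meat and
#: rice-based Korean patterns.
DIET_PATTERN_BLOCKS: dict[str, tuple[str, ...]] = {
    "traditional_balanced": (
        "beans", "green_vegetables", "other_vegetables", "mushrooms",
        "white_fish", "seaweeds",
    ),
    "prudent": ("fruits", "nuts", "milk", "dairy", "blue_fish", "tea"),
    "noodle_meat": (
        "noodles", "bread", "red_meat", "poultry", "processed_meat", "sweets",
    ),
    "rice_based": ("rice", "kimchi", "soups", "potatoes", "eggs"),
}


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _specs_to_frame(specs: Sequence[SNPSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in specs],
            "position": [s.position for s in specs],
            "minor_allele": [s.minor_allele for s in specs],
            "major_allele": [s.major_allele for s in specs],
            "maf": [s.maf for s in specs],
        },
        index=pd.Index([s.snp_id for s in specs], name="snp_id"),
    )


def _subject_index(n_subjects: int) -> pd.Index:
    width = len(str(n_subjects))
    return pd.Index([f"S{i:0{width}d}" for i in range(1, n_subjects + 1)], name="subject_id")


def simulate_genotypes(
    n_subjects: int,
    specs: Sequence[SNPSpec] = DEFAULT_SNP_SPECS,
    seed: int = 0,
    ld_blocks: Sequence[LDBlock] = (),
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Draw genotypes in Hardy-Weinberg proportions, SNP-independent by default.

    Each SNP is sampled i.i.d. with genotype probabilities
    ((1-q)^2, 2q(1-q), q^2) for MAF q.  SNPs named in an ``ld_blocks``
    entry are instead sampled as haplotype pairs whose haplotype
    frequencies realize the requested |D'| given the two MAFs.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    specs = list(specs)
    by_id = {s.snp_id: s for s in specs}
    if len(by_id) != len(specs):
        raise ValueError("duplicate snp ids in specs")
    in_block: set[str] = set()
    for blk in ld_blocks:
        for sid in (blk.snp_a, blk.snp_b):
            if sid not in by_id:
                raise ValueError(f"LD block references unknown SNP {sid!r}")
            if sid in in_block:
                raise ValueError(f"SNP {sid!r} appears in more than one LD block")
            in_block.add(sid)

    rng_geno, rng_block, rng_miss = _child_rngs(seed, 3)
    n_snps = len(specs)
    g = np.empty((n_subjects, n_snps), dtype=float)
    col = {s.snp_id: j for j, s in enumerate(specs)}

    for s in specs:
        if s.snp_id in in_block:
            continue
        q = s.maf
        probs = ((1 - q) ** 2, 2 * q * (1 - q), q**2)
        g[:, col[s.snp_id]] = rng_geno.choice(3, size=n_subjects, p=probs)

    for blk in ld_blocks:
        qa, qb = by_id[blk.snp_a].maf, by_id[blk.snp_b].maf
        # D >= 0 by convention: minor alleles positively associated.
        d = blk.d_prime * min(qa * (1 - qb), (1 - qa) * qb)
        hap = np.array(
            [qa * qb + d, qa * (1 - qb) - d, (1 - qa) * qb - d, (1 - qa) * (1 - qb) + d]
        )
        if (hap < -1e-12).any():
            raise ValueError(f"infeasible haplotype frequencies for block {blk}")
        hap = np.clip(hap, 0.0, None)
        hap /= hap.sum()
        draws = rng_block.choice(4, size=(n_subjects, 2), p=hap)
        carries_a = (draws <= 1).sum(axis=1)  # haplotypes 0,1 carry minor at a
        carries_b = ((draws == 0) | (draws == 2)).sum(axis=1)
        g[:, col[blk.snp_a]] = carries_a
        g[:, col[blk.snp_b]] = carries_b

    if missing_rate > 0.0:
        g[rng_miss.random(g.shape) < missing_rate] = np.nan

    dosage = pd.DataFrame(g, index=_subject_index(n_subjects), columns=[s.snp_id for s in specs])
    return GenotypeMatrix(dosage, _specs_to_frame(specs))


def _linear_predictor(
    genotypes: GenotypeMatrix, cohort: CohortTable | None, model: DiseaseModel
) -> np.ndarray:
    eta = np.zeros(genotypes.n_subjects)
    for sid, beta in model.snp_log_or.items():
        if sid not in genotypes.dosage.columns:
            raise ValueError(f"disease model references unknown SNP {sid!r}")
        eta += beta * np.nan_to_num(genotypes.dosage[sid].to_numpy())
    for term in model.epistasis_terms:
        ga = np.nan_to_num(genotypes.dosage[term.snp_a].to_numpy()).astype(int)
        gb = np.nan_to_num(genotypes.dosage[term.snp_b].to_numpy()).astype(int)
        inc = np.zeros((3, 3))
        for (i, j), eff in term.cell_effects.items():
            inc[i, j] = eff
        eta += inc[ga, gb]
    for name, beta in model.covariate_log_or.items():
        if cohort is None or name not in cohort.data.columns:
            raise ValueError(f"disease model references unknown covariate {name!r}")
        eta += beta * cohort.data[name].to_numpy(dtype=float)
    return eta


def calibrate_intercept(
    eta: np.ndarray, target: float, tol: float = 1e-4, max_iter: int = 50
) -> float:
    """Bisection on the intercept so mean(expit(c + eta)) hits ``target``."""
    lo, hi = -50.0, 50.0
    if not (np.mean(expit(lo + eta)) <= target <= np.mean(expit(hi + eta))):
        raise ValueError(f"prevalence target {target} unresolvable for given effects")
    c = 0.0
    for _ in range(max_iter):
        c = 0.5 * (lo + hi)
        prev = float(np.mean(expit(c + eta)))
        if abs(prev - target) < tol:
            return c
        if prev < target:
            lo = c
        else:
            hi = c
    return c


def simulate_outcome(
    genotypes: GenotypeMatrix,
    cohort: CohortTable | None,
    model: DiseaseModel,
    seed: int = 0,
    outcome_name: str = "case",
) -> CohortTable:
    """Draw Bernoulli outcomes from the logistic disease model.

    Returns the cohort with the outcome column attached (a fresh cohort
    is created when ``cohort`` is None).
    """
    eta = _linear_predictor(genotypes, cohort, model)
    c = model.intercept
    if model.prevalence_target is not None:
        c = calibrate_intercept(eta, model.prevalence_target)
    (rng,) = _child_rngs(seed, 1)
    y = (rng.random(len(eta)) < expit(c + eta)).astype(int)
    data = cohort.data.copy() if cohort is not None else pd.DataFrame(index=genotypes.subject_ids)
    data[outcome_name] = y
    manifest = None
    if cohort is not None and cohort.manifest is not None:
        manifest = cohort.manifest
    return CohortTable(data, manifest)


def simulate_exposures(
    n_subjects: int,
    specs: Sequence[ExposureSpec] = DEFAULT_EXPOSURE_SPECS,
    seed: int = 0,
    outcome: np.ndarray | None = None,
    outcome_dependent: bool = False,
    index: pd.Index | None = None,
) -> pd.DataFrame:
    """Draw exposure/covariate columns from their declared distributions.

    When ``outcome_dependent`` is True and an outcome vector is given,
    continuous exposures are shifted by their ``case_shift`` for cases
    and categorical exposures use ``case_probs``; otherwise exposures
    are independent of outcome.
    """
    rngs = _child_rngs(seed, len(specs))
    if index is None:
        index = _subject_index(n_subjects)
    cols: dict[str, np.ndarray | pd.Series] = {}
    for spec, rng in zip(specs, rngs):
        if spec.kind == "continuous":
            mu, sd = spec.params
            if spec.dist == "normal":
                x = rng.normal(mu, sd, size=n_subjects)
            else:
                x = rng.lognormal(mu, sd, size=n_subjects)
            if outcome_dependent and outcome is not None and spec.case_shift:
                x = x + spec.case_shift * np.asarray(outcome)
            if spec.lower is not None:
                # resample below the bound (truncation, not clipping)
                bad = x < spec.lower
                for _ in range(100):
                    if not bad.any():
                        break
                    if spec.dist == "normal":
                        x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
                    else:
                        x[bad] = rng.lognormal(mu, sd, size=int(bad.sum()))
                    bad = x < spec.lower
                x = np.maximum(x, spec.lower)
            cols[spec.name] = x
        else:
            probs = np.asarray(spec.probs, dtype=float)
            draws = rng.choice(len(spec.levels), size=n_subjects, p=probs)
            if outcome_dependent and outcome is not None and spec.case_probs is not None:
                case_idx = np.flatnonzero(np.asarray(outcome) == 1)
                draws[case_idx] = rng.choice(
                    len(spec.levels), size=len(case_idx), p=np.asarray(spec.case_probs)
                )
            cols[spec.name] = pd.Categorical.from_codes(draws, categories=list(spec.levels))
    return pd.DataFrame(cols, index=index)


def simulate_food_groups(
    n_subjects: int,
    seed: int = 0,
    blocks: dict[str, tuple[str, ...]] | None = None,
    food_groups: Sequence[str] = FOOD_GROUPS,
    loading: float = 0.75,
    index: pd.Index | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Food-group intakes with a latent-factor (diet pattern) structure.

    Each block's food groups load on one latent factor with the given
    loading plus independent noise; groups outside every block are pure
    noise.  Returns (intakes, latent factor scores) so tests can check
    pattern recovery against the truth.
    """
    if blocks is None:
        blocks = DIET_PATTERN_BLOCKS
    rng_f, rng_e = _child_rngs(seed, 2)
    if index is None:
        index = _subject_index(n_subjects)
    factors = pd.DataFrame(
        rng_f.standard_normal((n_subjects, len(blocks))), index=index, columns=list(blocks)
    )
    noise_sd = float(np.sqrt(1.0 - loading**2))
    data = {}
    member = {g: pat for pat, groups in blocks.items() for g in groups}
    for grp in food_groups:
        e = rng_e.standard_normal(n_subjects)
        if grp in member:
            data[grp] = loading * factors[member[grp]].to_numpy() + noise_sd * e
        else:
            data[grp] = e
    return pd.DataFrame(data, index=index), factors


def default_manifest(outcome: str = "case") -> ColumnManifest:
    exposures = {}
    for spec in DEFAULT_EXPOSURE_SPECS:
        if spec.kind == "continuous" and spec.cutoff is not None:
            exposures[spec.name] = {"cutoff": float(spec.cutoff), "high": "ge"}
    return ColumnManifest(
        outcome=outcome,
        covariates={
            "age": "continuous",
            "gender": "categorical",
            "bmi": "continuous",
            "residence_area": "categorical",
            "education": "categorical",
            "income": "categorical",
        },
        exposures=exposures,
        food_groups=list(FOOD_GROUPS),
    )


def simulate_study(
    n_subjects: int = 20_000,
    seed: int = 0,
    snp_specs: Sequence[SNPSpec] = DEFAULT_SNP_SPECS,
    snp_ors: dict[str, float] | None = None,
    epistasis_terms: Sequence[EpistasisTerm] = (),
    prevalence: float = 0.009,
    ld_blocks: Sequence[LDBlock] = (),
    outcome_name: str = "case",
) -> tuple[GenotypeMatrix, CohortTable]:
    """One-call study generator: genotypes + exposures + outcome + manifest.

    Defaults emulate the source study's conditions: the ten-SNP
    candidate panel with its published per-SNP odds ratios, case
    prevalence 0.9%, and exposure marginals loosely matched to the
    cohort's summary tables.
    """
    if snp_ors is None:
        snp_ors = {k: v for k, v in DEFAULT_SNP_ORS.items() if k in {s.snp_id for s in snp_specs}}
    s_geno, s_expo, s_out = (
        int(s.generate_state(1, dtype=np.uint64)[0] >> 33)
        for s in np.random.SeedSequence(seed).spawn(3)
    )
    genotypes = simulate_genotypes(n_subjects, snp_specs, seed=s_geno, ld_blocks=ld_blocks)
    expo = simulate_exposures(n_subjects, seed=s_expo, index=genotypes.subject_ids)
    cohort = CohortTable(expo, None)
    model = DiseaseModel(
        snp_log_or={k: float(np.log(v)) for k, v in snp_ors.items()},
        epistasis_terms=list(epistasis_terms),
        prevalence_target=prevalence,
    )
    cohort = simulate_outcome(genotypes, cohort, model, seed=s_out, outcome_name=outcome_name)
    foods, _ = simulate_food_groups(n_subjects, seed=s_expo + 1, index=genotypes.subject_ids)
    data = pd.concat([cohort.data, foods], axis=1)
    return genotypes, CohortTable(data, default_manifest(outcome_name))
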