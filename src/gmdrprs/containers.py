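"""Core in-memory containers shared across the pipeline.

Genotypes travel as additive minor-allele counts (0/1/2, ``NaN`` for
missing) in a subjects x SNPs :class:`pandas.DataFrame`, with per-SNP
metadata (chromosome, position, minor/major allele) alongside.  Cohort
phenotype/covariate/exposure data travel as a second DataFrame indexed
by the same subject ids, with a :class:`ColumnManifest` declaring the
semantic role of each column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ("chrom", "position", "minor_allele", "major_allele")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive minor-allele counts with SNP metadata.

    Parameters
    ----------
    dosage:
        DataFrame indexed by subject id; one column per SNP; values in
        {0, 1, 2} counting copies of the *minor* allele, ``NaN`` missing.
        Risk-allele orientation is applied later (in the PRS stage),
        never here.
    snps:
        DataFrame indexed by snp id with columns ``chrom``, ``position``,
        ``minor_allele``, ``major_allele`` (and optionally ``maf``).
    """

    dosage: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = self.dosage.astype(float)
        missing_meta = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing_meta:
            raise ValueError(f"snps metadata lacks columns {missing_meta}")
        if list(self.dosage.columns) != list(self.snps.index):
            raise ValueError("dosage columns and snps index do not match")
        vals = self.dosage.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage.columns[np.where(~ok)[1][0]]
            raise ValueError(f"non-additive genotype code in SNP {bad!r}")
        for sid, row in self.snps.iterrows():
            if row["minor_allele"] == row["major_allele"]:
                raise ValueError(f"SNP {sid!r}: minor and major allele identical")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def subject_ids(self) -> pd.Index:
        return self.dosage.index

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(self.dosage[snp_ids], self.snps.loc[snp_ids])

    def sort_subjects(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.sort_index(), self.snps)


@dataclass
class ColumnManifest:
    """Declared semantic roles for cohort-table columns.

    ``covariates`` maps name -> {"continuous", "categorical"};
    ``exposures`` maps name -> dict with at least ``cutoff`` (number) and
    optionally ``high`` ("ge" when high includes values >= cutoff, the
    default, or "lt") and ``percentile`` (cutoff expressed as a sample
    percentile instead of a raw value).
    """

    outcome: str
    covariates: dict[str, str] = field(default_factory=dict)
    exposures: dict[str, dict] = field(default_factory=dict)
    food_groups: list[str] = field(default_factory=list)

    def validate(self, table: pd.DataFrame) -> None:
        names = [self.outcome, *self.covariates, *self.exposures, *self.food_groups]
        absent = [n for n in names if n not in table.columns]
        if absent:
            raise ValueError(f"manifest names absent columns: {absent}")
        out = table[self.outcome]
        uniq = set(pd.unique(out.dropna()))
        if not uniq <= {0, 1}:
            raise ValueError(
                f"outcome column {self.outcome!r} must be binary 0/1; "
                f"found values {sorted(uniq)[:6]} (recode e.g. 1/2 -> 0/1)"
            )
        for cov, kind in self.covariates.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"covariate {cov!r}: unknown type {kind!r}")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "covariates": dict(self.covariates),
            "exposures": {k: dict(v) for k, v in self.exposures.items()},
            "food_groups": list(self.food_groups),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnManifest":
        return cls(
            outcome=d["outcome"],
            covariates=dict(d.get("covariates", {})),
            exposures={k: dict(v) for k, v in d.get("exposures", {}).items()},
            food_groups=list(d.get("food_groups", [])),
        )


@dataclass
class CohortTable:
    """Per-subject outcome/covariate/exposure table plus its manifest."""

    data: pd.DataFrame
    manifest: ColumnManifest | None = None

    def __post_init__(self) -> None:
        if self.manifest is not None:
            self.manifest.validate(self.data)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def outcome(self) -> pd.Series:
        if self.manifest is None:
            raise ValueError("cohort has no manifest; outcome column unknown")
        return self.data[self.manifest.outcome].astype(int)

    def covariate_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric design columns for the named covariates.

        Categorical covariates are dummy-coded (first level dropped).
        """
        if self.manifest is None:
            raise ValueError("cohort has no manifest")
        if names is None:
            names = list(self.manifest.covariates)
        blocks = []
        for name in names:
            kind = self.manifest.covariates.get(name, "continuous")
            col = self.data[name]
            if kind == "categorical" or col.dtype == object:
                blocks.append(pd.get_dummies(col, prefix=name, drop_first=True, dtype=float))
            else:
                blocks.append(col.astype(float).to_frame(name))
        if not blocks:
            return pd.DataFrame(index=self.data.index)
        return pd.concat(blocks, axis=1)


def align_subjects(
    genotypes: GenotypeMatrix, cohort: CohortTable
) -> tuple[GenotypeMatrix, CohortTable]:
    """Align genotypes and cohort on their common subject ids (sorted).

    Raises if either side has ids the other lacks, naming a few of them.
    """
    gid, cid = set(genotypes.subject_ids), set(cohort.subject_ids)
    only_g, only_c = sorted(gid - cid), sorted(cid - gid)
    if only_g or only_c:
        raise ValueError(
            f"subject id mismatch: {len(only_g)} only in genotypes "
            f"(e.g. {only_g[:3]}), {len(only_c)} only in cohort (e.g. {only_c[:3]})"
        )
    order = sorted(gid)
    return (
        GenotypeMatrix(genotypes.dosage.loc[order], genotypes.snps),
        CohortTable(cohort.data.loc[order], cohort.manifest),
    )


@dataclass
class EffectEstimate:
    """An odds ratio with Wald 95% CI and p-value from a logistic fit."""

    term: str
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float = float("nan")
    se: float = float("nan")
    n: int = 0
    covariates: tuple[str, ...] = ()
    stratum: str | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (
            self.ci_low <= self.or_value <= self.ci_high
        ):
            raise ValueError("CI does not bracket the odds ratio")
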