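"""Readers and writers for the pipeline's file formats.

Two genotype dialects are supported:

* ``additive_tsv`` — a TSV with a ``subject_id`` column followed by one
  column per SNP holding minor-allele counts 0/1/2 (``NA`` missing),
  plus a ``<prefix>.snps.tsv`` sidecar with the SNP metadata.
* ``ped_map`` — whitespace PLINK text pedigree/map pair; genotypes are
  allele pairs (``0 0`` missing) recoded against the stated minor
  allele on read.

Readers reject malformed input rather than coerce it, and every
writer/reader pair round-trips valid data bit-exactly.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CohortTable, ColumnManifest, GenotypeMatrix

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_cohort",
    "read_cohort",
    "write_manifest",
    "read_manifest",
]

_MISSING_TSV = "NA"


def write_genotypes(genotypes: GenotypeMatrix, prefix: str | Path, dialect: str = "additive_tsv") -> list[Path]:
    """Write genotypes under ``prefix``; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "additive_tsv":
        return _write_additive(genotypes, prefix)
    if dialect == "ped_map":
        return _write_ped_map(genotypes, prefix)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_genotypes(prefix: str | Path, dialect: str = "additive_tsv", snps: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read genotypes written by :func:`write_genotypes`.

    ``snps`` metadata (chrom/position/minor_allele/major_allele indexed
    by snp id) may be passed explicitly; otherwise the
    ``<prefix>.snps.tsv`` sidecar is required.
    """
    prefix = Path(prefix)
    if snps is None:
        sidecar = prefix.with_suffix(prefix.suffix + ".snps.tsv")
        if not sidecar.exists():
            raise FileNotFoundError(f"SNP metadata sidecar not found: {sidecar}")
        snps = pd.read_csv(sidecar, sep="\t", index_col="snp_id", dtype={"chrom": str})
    if dialect == "additive_tsv":
        return _read_additive(prefix, snps)
    if dialect == "ped_map":
        return _read_ped_map(prefix, snps)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _sidecar(prefix: Path) -> Path:
    return prefix.with_suffix(prefix.suffix + ".snps.tsv")


def _write_sidecar(genotypes: GenotypeMatrix, prefix: Path) -> Path:
    path = _sidecar(prefix)
    genotypes.snps.rename_axis("snp_id").to_csv(path, sep="\t")
    return path


def _write_additive(genotypes: GenotypeMatrix, prefix: Path) -> list[Path]:
    path = prefix.with_suffix(prefix.suffix + ".tsv")
    out = genotypes.dosage.copy()
    # integers where called, NA where missing
    out = out.astype(object)
    for col in out.columns:
        vals = genotypes.dosage[col]
        out[col] = vals.map(lambda v: _MISSING_TSV if math.isnan(v) else str(int(v)))
    out.rename_axis("subject_id").to_csv(path, sep="\t")
    return [path, _write_sidecar(genotypes, prefix)]


def _read_additive(prefix: Path, snps: pd.DataFrame) -> GenotypeMatrix:
    path = prefix.with_suffix(prefix.suffix + ".tsv")
    raw = pd.read_csv(path, sep="\t", index_col="subject_id", dtype=str, na_values=[_MISSING_TSV], keep_default_na=False)
    vals = raw.apply(pd.to_numeric)
    bad = ~(vals.isna() | vals.isin((0, 1, 2)))
    if bad.to_numpy().any():
        col = bad.columns[np.where(bad.to_numpy())[1][0]]
        raise ValueError(f"{path}: non-additive genotype code in SNP {col!r}")
    vals.index = vals.index.astype(str)
    return GenotypeMatrix(vals.astype(float), snps.loc[list(vals.columns)])


def _write_ped_map(genotypes: GenotypeMatrix, prefix: Path) -> list[Path]:
    ped = prefix.with_suffix(prefix.suffix + ".ped")
    map_ = prefix.with_suffix(prefix.suffix + ".map")
    snps = genotypes.snps
    with map_.open("w") as fh:
        for sid, row in snps.iterrows():
            fh.write(f"{row['chrom']}\t{sid}\t0\t{int(row['position'])}\n")
    minor = snps["minor_allele"].to_numpy()
    major = snps["major_allele"].to_numpy()
    with ped.open("w") as fh:
        for subj, row in genotypes.dosage.iterrows():
            fields = [str(subj), str(subj), "0", "0", "0", "-9"]
            for j, v in enumerate(row.to_numpy()):
                if math.isnan(v):
                    fields.append("0 0")
                elif v == 0:
                    fields.append(f"{major[j]} {major[j]}")
                elif v == 1:
                    fields.append(f"{minor[j]} {major[j]}")
                else:
                    fields.append(f"{minor[j]} {minor[j]}")
            fh.write("\t".join(fields) + "\n")
    return [ped, map_, _write_sidecar(genotypes, prefix)]


def _read_ped_map(prefix: Path, snps: pd.DataFrame) -> GenotypeMatrix:
    ped = prefix.with_suffix(prefix.suffix + ".ped")
    map_ = prefix.with_suffix(prefix.suffix + ".map")
    map_rows = []
    with map_.open() as fh:
        for line in fh:
            chrom, sid, _cm, pos = line.split()
            map_rows.append((chrom, sid, int(pos)))
    snp_ids = [r[1] for r in map_rows]
    unknown = [s for s in snp_ids if s not in snps.index]
    if unknown:
        raise ValueError(f"{map_}: SNPs absent from metadata: {unknown[:5]}")
    meta = snps.loc[snp_ids]
    minor = meta["minor_allele"].to_numpy()
    major = meta["major_allele"].to_numpy()
    subjects: list[str] = []
    rows: list[list[float]] = []
    with ped.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 6 + 2 * len(snp_ids):
                raise ValueError(f"{ped} line {lineno}: expected {6 + 2 * len(snp_ids)} fields, got {len(fields)}")
            subjects.append(fields[1])
            geno: list[float] = []
            for j in range(len(snp_ids)):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" and a2 == "0":
                    geno.append(float("nan"))
                    continue
                count = 0
                for a in (a1, a2):
                    if a == minor[j]:
                        count += 1
                    elif a != major[j]:
                        raise ValueError(
                            f"{ped} line {lineno}: SNP {snp_ids[j]!r} allele {a!r} "
                            f"not in declared alleles {{{minor[j]!r}, {major[j]!r}}}"
                        )
                geno.append(float(count))
            rows.append(geno)
    dosage = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"), columns=snp_ids)
    return GenotypeMatrix(dosage, meta)


def write_manifest(manifest: ColumnManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)
    return path


def read_manifest(path: str | Path) -> ColumnManifest:
    with Path(path).open() as fh:
        return ColumnManifest.from_dict(yaml.safe_load(fh))


def write_cohort(cohort: CohortTable, path: str | Path, manifest_path: str | Path | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.data.rename_axis("subject_id").to_csv(path, sep="\t")
    if manifest_path is not None and cohort.manifest is not None:
        write_manifest(cohort.manifest, manifest_path)
    return path


def read_cohort(
    path: str | Path,
    manifest: ColumnManifest | str | Path,
    genotypes: GenotypeMatrix | None = None,
) -> CohortTable:
    """Read a cohort TSV, validate it against the manifest, and
    (optionally) canonicalize subject order to match a genotype matrix.

    Subjects are aligned by id; id mismatches between the two files are
    reported, never silently dropped.
    """
    if not isinstance(manifest, ColumnManifest):
        manifest = read_manifest(manifest)
    data = pd.read_csv(path, sep="\t", index_col="subject_id")
    data.index = data.index.astype(str)
    manifest.validate(data)
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][:3].tolist()
        raise ValueError(f"{path}: duplicate subject ids (e.g. {dup})")
    data = data.sort_index()
    cohort = CohortTable(data, manifest)
    if genotypes is not None:
        from .containers import align_subjects

        _, cohort = align_subjects(genotypes, cohort)
    return cohort
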