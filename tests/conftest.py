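import numpy as np
import pandas as pd
import pytest

from gmdrprs.containers import GenotypeMatrix
from gmdrprs.synthetic import SNPSpec, simulate_genotypes


@pytest.fixture(scope="session")
def snp_specs():
    return [
        SNPSpec("snpA", "1", 100, "A", "G", 0.30),
        SNPSpec("snpB", "1", 5000, "T", "C", 0.25),
        SNPSpec("snpC", "2", 700, "C", "T", 0.40),
        SNPSpec("snpD", "2", 9000, "G", "A", 0.10),
    ]


@pytest.fixture(scope="session")
def small_genotypes(snp_specs):
    return simulate_genotypes(500, snp_specs, seed=11)


def make_genotype_matrix(values, snp_ids=None, mafs=None):
    """GenotypeMatrix from a plain array, with placeholder metadata."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if snp_ids is None:
        snp_ids = [f"s{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "position": np.arange(1, m + 1) * 1000,
            "minor_allele": ["A"] * m,
            "major_allele": ["G"] * m,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    if mafs is not None:
        meta["maf"] = mafs
    dosage = pd.DataFrame(
        values, index=[f"S{i:04d}" for i in range(n)], columns=snp_ids
    )
    return GenotypeMatrix(dosage, meta)
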