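import numpy as np
import pandas as pd
import pytest

from tohkit.io_plink import GenotypeMatrix, PED_SAMPLE_COLUMNS, SnpMap


def make_map(n_snps, chrom="1", spacing=1000, start=1000):
    return SnpMap(
        pd.DataFrame(
            {
                "chrom": chrom,
                "snp_id": [f"rs{chrom}_{i}" for i in range(n_snps)],
                "cm": 0.0,
                "bp": start + spacing * np.arange(n_snps, dtype=np.int64),
            }
        )
    )


def make_genotypes(allele_rows):
    """GenotypeMatrix from a list of per-subject lists of 'XY' call strings."""
    n = len(allele_rows)
    arr = np.array(
        [[[c[0], c[1]] for c in row] for row in allele_rows], dtype="U8"
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"S{i}" for i in range(n)],
            "father": "0",
            "mother": "0",
            "sex": "1",
            "phenotype": "1",
        },
        columns=PED_SAMPLE_COLUMNS,
    )
    return GenotypeMatrix(samples, arr)


def random_calls(rng, n, p_het=0.3, p_missing=0.05):
    """Random call-string vector: hom A/C, het, or missing."""
    out = []
    for _ in range(n):
        r = rng.random()
        if r < p_missing:
            out.append("00")
        elif r < p_missing + p_het:
            out.append("AC")
        else:
            out.append("AA" if rng.random() < 0.5 else "CC")
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
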