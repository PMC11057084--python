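import numpy as np
import pandas as pd
import pytest

from summr.gwas_io import AssociationTable, LDMatrix, pair_from_arrays


def make_table(
    trait_name="trait",
    trait_type="quantitative",
    variant_id=("rs1", "rs2", "rs3"),
    chrom="1",
    pos=(1000, 2000, 3000),
    effect_allele=("A", "A", "A"),
    other_allele=("G", "G", "G"),
    eaf=(0.3, 0.3, 0.3),
    beta=(0.1, 0.2, 0.3),
    se=(0.05, 0.05, 0.05),
    pval=(1e-6, 1e-7, 1e-8),
    n=100_000,
) -> AssociationTable:
    k = len(variant_id)
    df = pd.DataFrame(
        {
            "variant_id": list(variant_id),
            "chrom": [chrom] * k if isinstance(chrom, str) else list(chrom),
            "pos": list(pos),
            "effect_allele": list(effect_allele),
            "other_allele": list(other_allele),
            "eaf": list(eaf),
            "beta": list(beta),
            "se": list(se),
            "pval": list(pval),
            "n": [n] * k if np.isscalar(n) else list(n),
        }
    )
    return AssociationTable(trait_name, trait_type, df)


@pytest.fixture
def simple_table():
    return make_table()


@pytest.fixture
def identity_ld():
    def _make(variant_ids):
        return LDMatrix(list(variant_ids), np.eye(len(variant_ids)))

    return _make


@pytest.fixture
def proportional_pair():
    """Exact proportionality Γ = 0.3·γ: IVW should find beta 0.3, Q = 0."""
    g = np.array([1.0, 2.0, 3.0])
    return pair_from_arrays(g, 0.1 * np.ones(3), 0.3 * g, 0.1 * np.ones(3))
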