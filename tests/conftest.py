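import numpy as np
import pytest

from splicefate.synthetic_data import (
    Individual,
    Pedigree,
    VariantPanel,
    VariantRecord,
    kinship_from_pedigree,
)


def make_pedigree(rows):
    """rows: (id, father, mother, family) tuples; sex alternates."""
    return Pedigree(
        [Individual(r[0], r[1], r[2], 1 + i % 2, r[3] if len(r) > 3 else "F1")
         for i, r in enumerate(rows)]
    )


@pytest.fixture
def trio():
    return make_pedigree([("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")])


@pytest.fixture
def sib_quartet():
    return make_pedigree(
        [("dad", None, None), ("mom", None, None),
         ("sib1", "dad", "mom"), ("sib2", "dad", "mom")]
    )


@pytest.fixture
def half_sib_family():
    return make_pedigree(
        [("dad", None, None), ("mom1", None, None), ("mom2", None, None),
         ("h1", "dad", "mom1"), ("h2", "dad", "mom2")]
    )


@pytest.fixture
def single_variant_panel():
    return VariantPanel([VariantRecord("snp1", "chr9", 6_000_000, "G", "C", 0.3)])


@pytest.fixture
def sib_cohort():
    """600 individuals in nuclear families with kinship, for LMM tests."""
    from splicefate.synthetic_data import simulate_family_cohort

    ped = simulate_family_cohort(600, seed=42)
    return ped, kinship_from_pedigree(ped)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
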