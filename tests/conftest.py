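import numpy as np
import pandas as pd
import pytest

from pedscan.io import GenotypeTable
from pedscan.pedigree import Individual, Pedigree, index_family


@pytest.fixture(scope="session")
def family():
    """The built-in three-generation multiplex family (5 affected)."""
    return index_family()


@pytest.fixture(scope="session")
def sib_pair():
    """Two founders with two affected children: the textbook NPL case."""
    return Pedigree(
        [
            Individual("F", sex="male"),
            Individual("M", sex="female"),
            Individual("S1", "F", "M", affected="yes"),
            Individual("S2", "F", "M", affected="yes"),
        ]
    )


@pytest.fixture(scope="session")
def family_engine(family):
    from pedscan.linkage import FamilyLinkage

    return FamilyLinkage(family)


@pytest.fixture
def trio_ped(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text("FAM1 dad 0 0 1 1\nFAM1 mum 0 0 2 1\nFAM1 kid dad mum 1 2\n")
    return p


def make_genotype_table(n, chrom="1", start=1_000_000, step=1_000, af=0.3,
                        individuals=("A", "B"), seed=0):
    rng = np.random.default_rng(seed)
    variants = pd.DataFrame(
        {
            "CHROM": chrom,
            "POS": start + step * np.arange(n),
            "REF": "A",
            "ALT": "G",
            "AF": af,
            "CM": np.arange(n, dtype=float),
        }
    )
    calls = pd.DataFrame(
        {i: rng.integers(0, 3, size=n).astype(float) for i in individuals}
    )
    return GenotypeTable(variants, calls)
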