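import numpy as np
import pandas as pd
import pytest

from metahet import synthgen
from metahet.hetcalc import GenotypeTable


def make_genotype_table(calls, nest_ids=None, patch_ids=None, years=None):
    """Build a GenotypeTable from a nested list of calls (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    meta = pd.DataFrame(
        {
            "individual_id": [f"I{i}" for i in range(n)],
            "nest_id": nest_ids if nest_ids is not None else ["N1"] * n,
            "patch_id": patch_ids if patch_ids is not None else ["P1"] * n,
            "year": years if years is not None else [2009] * n,
        }
    )
    return GenotypeTable(meta=meta, calls=calls, locus_names=[f"locus_{j+1:04d}" for j in range(L)])


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size generator configuration for fast unit tests."""
    return synthgen.GeneratorConfig(
        n_patches=120, extent_km=(12.0, 12.0), n_years=6, n_loci=60, burn_in=30, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthgen.simulate(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the calibrated default study conditions."""
    return synthgen.simulate(synthgen.GeneratorConfig(seed=1))
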