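import numpy as np
import pandas as pd
import pytest

from isletorigin import synthetic_data as sd
from isletorigin.bisulfite import AmpliconRef


@pytest.fixture(scope="session")
def default_panel() -> pd.DataFrame:
    """The default synthetic tissue panel (12 samples per tissue/condition)."""
    return sd.gen_tissue_panel(seed=1)


@pytest.fixture(scope="session")
def small_beta_matrix():
    """A small islet-vs-control beta matrix with 10 true markers."""
    return sd.gen_beta_matrix(
        n_islet=12, n_control=12, n_true_dm=10, n_null=60, effect=0.7, seed=7
    )


@pytest.fixture()
def toy_amplicon() -> AmpliconRef:
    """Short amplicon with two CpGs (positions 2 and 6) and one non-CpG C."""
    return AmpliconRef.from_sequence("toy", "ACGTCCGT")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
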