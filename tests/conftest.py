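import numpy as np
import pandas as pd
import pytest

from mbresil import AbundanceTable
from mbresil.synthetic import SynthConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_table(values, sample_ids=None, taxon_ids=None) -> AbundanceTable:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, d = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"t{j}" for j in range(d)]
    return AbundanceTable(pd.DataFrame(values, index=sample_ids, columns=taxon_ids))


@pytest.fixture(scope="session")
def default_study():
    """Default-sized noisy study: 15 subjects × 3 conditions × 6 timepoints."""
    return generate_study(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free single-condition study used for exact pipeline checks."""
    cfg = SynthConfig(
        n_subjects=20,
        conditions=("exercise",),
        n_taxa=40,
        sequencing_depth=None,
        sparsity_zeros_frac=0.0,
        seed=23,
    )
    return generate_study(cfg)
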