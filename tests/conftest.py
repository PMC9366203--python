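import numpy as np
import pandas as pd
import pytest

from isletview.simulate import SimulationConfig, simulate_cohort
from isletview import normalization as norm


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with planted DE, purity, module and eQTL effects."""
    cfg = SimulationConfig(
        n_genes=600,
        n_donors=100,
        n_t2d=18,
        n_t2d_hba1c_only=7,
        n_igt=10,
        n_de_genes=40,
        n_eqtl_genes=15,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def normalized(small_cohort):
    counts, meta, ann, geno, truth = small_cohort
    lengths = pd.Series({a.gene_id: a.length for a in ann})
    ds, log = norm.normalize_dataset(counts, lengths)
    return ds, meta.loc[ds.counts.columns], ann, geno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
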