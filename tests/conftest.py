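import numpy as np
import pandas as pd
import pytest

from radpop.matrix import GenotypeMatrix
from radpop.sim import SimulationConfig, simulate_genotypes


def make_matrix(dosages, populations=None, tag_ids=None,
                ref="A", alt="G") -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array for tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    if populations is None:
        populations = ["P1"] * n_ind
    samples = [f"{p}_{i}" for i, p in enumerate(populations)]
    sites = pd.DataFrame({
        "tag_id": tag_ids if tag_ids is not None
        else [f"tag{j}" for j in range(n_sites)],
        "pos_in_tag": [0] * n_sites,
        "ref": [ref] * n_sites,
        "alt": [alt] * n_sites,
    })
    return GenotypeMatrix(dosages, sites, samples, np.asarray(populations))


@pytest.fixture
def two_pop_truth():
    """Two mildly diverged populations, genotypes only (fast)."""
    cfg = SimulationConfig(n_populations=2, n_individuals_per_pop=15,
                           n_sites=1500, global_fst=0.1,
                           ancestral_freq_beta=(1.0, 1.0), seed=11)
    return simulate_genotypes(cfg)
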