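import numpy as np
import pandas as pd
import pytest

from metabsex.synthetic import ModuleSpec, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Targeted-platform cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_participants=300,
        n_metabolites=40,
        module_spec=(ModuleSpec(15, 0.8, 0.2, 0.6), ModuleSpec(10, 0.7)),
        seed=11,
    )
    return generate_cohort(cfg)


def block_matrix(seed, n=500, sizes=(20, 20, 20), rho=0.8):
    """Latent-factor block design: equal loadings sqrt(rho), noise sqrt(1-rho)."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for b, s in enumerate(sizes):
        g = rng.normal(size=n)
        cols.append(np.sqrt(rho) * g[:, None] + np.sqrt(1 - rho) * rng.normal(size=(n, s)))
        labels += [b] * s
    X = pd.DataFrame(np.hstack(cols), columns=[f"m{j:03d}" for j in range(sum(sizes))])
    return X, np.array(labels)
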