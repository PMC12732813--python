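import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import her2mtgx as hx

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: defaults shrunk to 20 samples/group and 300 genes."""
    return hx.SimulationConfig(n_her2=20, n_basal=20, n_luminal=20,
                               n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return hx.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full default study conditions (3x60, 2000 genes)."""
    return hx.simulate_cohort(hx.SimulationConfig(seed=7))


def make_blobs(k=3, n_per=20, dim=10, separation=5.0, spread=1.0, seed=0):
    """Planted Gaussian blobs as a genes x samples frame (samples=points)."""
    rng = np.random.default_rng(seed)
    # axis-aligned centers: pairwise distance separation*spread*sqrt(2)
    centers = np.zeros((k, dim))
    for i in range(k):
        centers[i, i % dim] = separation * spread * (1 + i // dim)
    pts, labels = [], []
    for i in range(k):
        pts.append(rng.normal(centers[i], spread, size=(n_per, dim)))
        labels += [i + 1] * n_per
    x = np.vstack(pts)
    cols = [f"S{i:03d}" for i in range(len(labels))]
    return (pd.DataFrame(x.T, index=[f"F{j}" for j in range(dim)],
                         columns=cols),
            np.array(labels))
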