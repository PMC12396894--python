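import numpy as np
import pytest

import fcgnn


@pytest.fixture(scope="session")
def parcel_table():
    return fcgnn.ParcelTable.schaefer100()


def random_connectivity(rng: np.random.Generator, n: int,
                        subject_id: str = "sub") -> fcgnn.ConnectivityMatrix:
    """A random symmetric zero-diagonal Fisher-z matrix."""
    r = rng.uniform(-0.8, 0.8, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    return fcgnn.ConnectivityMatrix(np.arctanh(r), subject_id)


def toy_graphs(seed: int, n_subjects: int, n_nodes: int, k: int = 3):
    rng = np.random.default_rng(seed)
    return [fcgnn.build_graph(random_connectivity(rng, n_nodes, f"s{i}"), k)
            for i in range(n_subjects)]


@pytest.fixture(scope="session")
def small_cohort():
    """20+20 subjects, 20 regions: cheap but structured."""
    spec = fcgnn.CohortSpec(n_per_group=20, n_regions=20, series_length=120,
                            planted_effects=(fcgnn.PlantedEffect(2, 11, 0.4),),
                            seed=42)
    subjects, matrices = fcgnn.generate_cohort(spec)
    return spec, subjects, matrices
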