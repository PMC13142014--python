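import numpy as np
import pytest

from pirf import (ClusterAssignment, DistanceMatrix, SimulationConfig,
                  simulate_dataset)


@pytest.fixture(scope="session")
def line_dist():
    """Six points on a line forming two tight groups (distance = |a - b|)."""
    pts = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
    d = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix(tuple("abcdef"), d), pts


@pytest.fixture(scope="session")
def small_data():
    """A quick clade-signal classification dataset shared by slow-ish tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_samples=60,
                                             n_features=20))


def make_assignment(labels, cluster_of, k):
    """Assemble a ClusterAssignment without running PAM (medoid = first
    member of each cluster; costs are irrelevant to the probability math)."""
    cluster_of = np.asarray(cluster_of, dtype=int)
    medoids = np.array([int(np.flatnonzero(cluster_of == j)[0])
                        for j in range(k)])
    return ClusterAssignment(labels=tuple(labels), cluster_of=cluster_of,
                             medoids=medoids, k=k, cost=0.0, build_cost=0.0)
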