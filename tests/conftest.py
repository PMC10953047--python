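import numpy as np
import pytest
from hypothesis import settings

from lupustrat import CohortConfig, default_registry, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort shared across read-only tests."""
    config = CohortConfig(seed=11)
    ct, clinical, truth = generate_cohort(config)
    return config, ct, clinical, truth


def brute_force_complete_linkage(dist: np.ndarray, k: int) -> list[set[int]]:
    """Reference agglomerator: rescans the full point-pair distance matrix
    to evaluate every cluster pair at every step (no distance updates)."""
    clusters = [{i} for i in range(dist.shape[0])]
    while len(clusters) > k:
        best, pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    dist[i, j] for i in clusters[a] for j in clusters[b]
                )
                if d < best:
                    best, pair = d, (a, b)
        a, b = pair
        clusters[a] |= clusters[b]
        del clusters[b]
    return clusters
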