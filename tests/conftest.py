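import numpy as np
import pytest

from mergetraj.merging import PhenotypeMap
from mergetraj.synthetic import gen_region_geometry
from mergetraj.transcriptome import _one_surrogate, _smooth_kernel


@pytest.fixture(scope="session")
def geometry():
    return gen_region_geometry(68, seed=1)


@pytest.fixture(scope="session")
def sa_map(geometry):
    """Spatially autocorrelated phenotype map on the shared geometry."""
    rng = np.random.default_rng(5)
    kernel = _smooth_kernel(geometry.distances, 30.0)
    vals = kernel @ rng.standard_normal(len(geometry.region_ids))
    vals = (vals - vals.mean()) / vals.std()
    return PhenotypeMap(list(geometry.region_ids), vals)


def sa_map_from_seed(geometry, seed, scale_mm=30.0):
    """Draw an SA map from the surrogate family itself (exchangeable null)."""
    rng = np.random.default_rng(seed)
    kernel = _smooth_kernel(geometry.distances, scale_mm)
    base = np.sort(rng.standard_normal(len(geometry.region_ids)))
    return PhenotypeMap(list(geometry.region_ids), _one_surrogate(base, kernel, rng))


def random_connected_graph(n, rng):
    """Random connected weighted graph with distinct weights."""
    while True:
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        mask = rng.random(iu[0].size) < 0.5
        vals = rng.random(mask.sum()) * 0.9 + 0.05
        w[iu[0][mask], iu[1][mask]] = vals
        w = w + w.T
        # connectivity check via BFS
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(w[u] > 0):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        if len(seen) == n and len(set(vals)) == len(vals):
            return w
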