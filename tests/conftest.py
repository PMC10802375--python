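import numpy as np
import pytest

import tensorparc as tp


@pytest.fixture(scope="session")
def ico2():
    return tp.build_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return tp.build_icosphere(3)


@pytest.fixture(scope="session")
def standard_fixture(ico3):
    """Planted hemisphere: 10 contiguous parcels driven by 6 overlapping
    networks, 8 subjects (two with a single duplicated session),
    moderate noise, random orthogonal temporal mixing."""
    truth = tp.make_ground_truth(ico3, n_parcels=10, R=6, n_timepoints=120,
                                 n_subjects=8, noise_sd=0.3, seed=0)
    sessions = [2, 2, 2, 1, 2, 2, 1, 2]
    subjects, tensor = tp.make_dataset(truth, 8, 60, sessions, seed=1)
    return {"mesh": ico3, "truth": truth, "subjects": subjects,
            "tensor": tensor, "sessions": sessions}


@pytest.fixture(scope="session")
def pipeline_networks(standard_fixture):
    """Synchronized + decomposed networks for the standard fixture."""
    subs = standard_fixture["subjects"]
    normalized = [tp.normalize_timeseries(s)[0] for s in subs]
    res = tp.sync_group(normalized)
    tensor = tp.GroupTensor(np.stack([a.T for a in res.aligned], axis=2))
    nets = tp.cp_decompose(tensor, R=6, seed=0)
    return {"sync": res, "networks": nets,
            "features": tp.feature_matrix(nets)}


def random_hop_graph(n, nb, seed, density=0.5):
    """Random symmetric positive-weight graph restricted to a hop mask of
    a random mesh-like ring-of-cliques topology; guaranteed connected."""
    rng = np.random.default_rng(seed)
    # ring backbone keeps it connected; extra random chords
    rows = list(range(n))
    cols = [(i + 1) % n for i in range(n)]
    extra = rng.integers(0, n, size=(int(density * n), 2))
    import scipy.sparse as sp

    i = np.concatenate([rows, extra[:, 0]])
    j = np.concatenate([cols, extra[:, 1]])
    keep = i != j
    i, j = i[keep], j[keep]
    base = sp.coo_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    base = ((base + base.T) > 0).astype(float)
    # hop-mask the weighted complete-ish similarity
    from scipy.sparse import csgraph

    dist = csgraph.dijkstra(base, unweighted=True)
    W = rng.uniform(0.5, 2.0, size=(n, n))
    W = (W + W.T) / 2
    A = np.where((dist <= nb) & (dist > 0), W, 0.0)
    return sp.csr_matrix(A)
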