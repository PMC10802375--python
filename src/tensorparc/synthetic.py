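"""Seeded synthetic cortical data with the structure the pipeline assumes.

The generator plants R overlapping, spatially smooth network maps on a
mesh (sums of hop-distance Gaussian bumps around seed vertices), shared
temporally autocorrelated time courses, positive per-subject
participation, and per-subject Haar-random orthogonal temporal mixing.
Each subject's recording is the rank-R signal plus i.i.d. Gaussian
noise; subjects with a single session have it duplicated and
concatenated so all subjects share the same (doubled) time length. The
planted parcellation — each vertex's argmax network, split into
contiguous pieces — is the recovery target for the full pipeline.

Noise levels are expressed relative to the clean signal's standard
deviation, so they mean the same thing at any mesh resolution or
network scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import csgraph

from .cp import GroupTensor, NetworkSet
from .embedding import Parcellation, relabel_by_size
from .mesh import SurfaceMesh

__all__ = ["GroundTruth", "make_networks", "make_ground_truth", "make_dataset",
           "make_task_contrasts"]


@dataclass
class GroundTruth:
    """Planted generative state: networks, parcellation, mixers, noise."""

    networks: NetworkSet
    parcellation: Parcellation
    subject_mixers: list[np.ndarray]   # per-subject orthogonal (T, T)
    noise_sd: float                    # relative to clean-signal std
    centers: np.ndarray | None = None  # bump-center vertices
    center_network: np.ndarray | None = None  # which network owns each center


def _farthest_point_centers(mesh: SurfaceMesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """n well-separated vertices by greedy farthest-point sampling in hops."""
    adj = mesh.adjacency().astype(np.int8)
    centers = [int(rng.integers(mesh.n_vertices))]
    mind = csgraph.dijkstra(adj, unweighted=True, indices=centers[0])
    for _ in range(n - 1):
        nxt = int(np.argmax(mind))
        centers.append(nxt)
        d = csgraph.dijkstra(adj, unweighted=True, indices=nxt)
        mind = np.minimum(mind, d)
    return np.array(centers)


def _assign_networks(center_dists: np.ndarray, R: int) -> np.ndarray:
    """Deterministically assign centers to R networks, balanced counts,
    maximizing the hop distance between same-network centers (so a
    network's territories stay spatially separated and the argmax
    parcellation keeps one contiguous parcel per center)."""
    n = center_dists.shape[0]
    owner = np.full(n, -1, dtype=int)
    quota = np.full(R, n // R)
    quota[: n % R] += 1
    if n <= R:
        owner[:] = np.arange(n)
        return owner
    if quota.max() <= 2:
        # pair up centers for the doubled networks, most-distant pairs first
        n_pairs = int((quota == 2).sum())
        order = np.dstack(np.triu_indices(n, k=1))[0]
        order = order[np.argsort(-center_dists[order[:, 0], order[:, 1]], kind="stable")]
        taken = np.zeros(n, dtype=bool)
        net = 0
        for a, b in order:
            if net >= n_pairs:
                break
            if not (taken[a] or taken[b]):
                owner[[a, b]] = net
                taken[[a, b]] = True
                net += 1
        for c in np.flatnonzero(~taken):
            owner[c] = net
            net += 1
        return owner
    counts = np.zeros(R, dtype=int)
    for c in range(n):  # greedy fallback for quotas above 2
        best, best_d = -1, -np.inf
        for r in range(R):
            if counts[r] >= quota[r]:
                continue
            mine = np.flatnonzero(owner == r)
            d = center_dists[c, mine].min() if mine.size else np.inf
            if d > best_d:
                best, best_d = r, d
        owner[c] = best
        counts[best] += 1
    return owner


def _bump_maps(mesh: SurfaceMesh, centers: np.ndarray, owner: np.ndarray, R: int,
               smoothness: float, overlap: float,
               dists: np.ndarray | None = None) -> np.ndarray:
    """(V, R) nonnegative-peaked smooth maps from hop-distance bumps.

    Each bump is confined to its center's nearest-center cell when
    overlap = 0 and unrestricted when overlap = 1; intermediate values
    blend the two, so adjacent networks share vertices iff overlap > 0.
    """
    if dists is None:
        adj = mesh.adjacency().astype(np.int8)
        dists = csgraph.dijkstra(adj, unweighted=True, indices=centers)  # (C, V)
    cell = np.argmin(dists, axis=0)                                   # nearest center
    bumps = np.exp(-(dists**2) / (2.0 * smoothness**2))
    maps = np.zeros((mesh.n_vertices, R))
    for c, ctr in enumerate(centers):
        in_cell = (cell == c).astype(float)
        contrib = bumps[c] * (overlap + (1.0 - overlap) * in_cell)
        maps[:, owner[c]] += contrib
    norms = np.linalg.norm(maps, axis=0)
    maps /= np.maximum(norms, 1e-300)
    return maps


def _smooth_unit_timecourses(T: int, R: int, rng: np.random.Generator) -> np.ndarray:
    B = gaussian_filter1d(rng.standard_normal((T, R)), sigma=4.0, axis=0)
    B /= np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    return B


def _haar_orthogonal(T: int, rng: np.random.Generator) -> np.ndarray:
    Q, Rm = np.linalg.qr(rng.standard_normal((T, T)))
    return Q * np.sign(np.diag(Rm))[np.newaxis, :]


def make_networks(
    mesh: SurfaceMesh,
    R: int,
    smoothness: float = 3.0,
    overlap: float = 0.5,
    seed: int = 0,
    n_timepoints: int = 240,
    n_subjects: int = 8,
    centers: np.ndarray | None = None,
) -> NetworkSet:
    """R planted networks: bump spatial maps, smooth unit-norm time
    courses, positive subject loadings. Deterministic given the seed.

    ``centers`` overrides the default farthest-point bump centers (one
    per network); passing duplicate centers makes networks coincide.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > mesh.n_vertices:
        raise ValueError("more networks than vertices")
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = _farthest_point_centers(mesh, R, rng)
    centers = np.asarray(centers)
    owner = np.arange(len(centers)) % R
    maps = _bump_maps(mesh, centers, owner, R, smoothness, overlap)
    B = _smooth_unit_timecourses(n_timepoints, R, rng)
    C = rng.uniform(0.5, 1.5, size=(n_subjects, R))
    C /= np.linalg.norm(C, axis=0)
    lam = np.sort(rng.uniform(1.0, 3.0, size=R))[::-1]
    return NetworkSet(magnitudes=lam, spatial_maps=maps, time_courses=B,
                      subject_loadings=C)


def _argmax_parcellation(mesh: SurfaceMesh, maps: np.ndarray) -> Parcellation:
    """Assign each vertex to its argmax network, then split each
    network's territory into connected components."""
    owner = np.argmax(maps, axis=1)
    adj = mesh.adjacency()
    labels = np.full(mesh.n_vertices, -1, dtype=np.int32)
    nxt = 0
    for r in range(maps.shape[1]):
        idx = np.flatnonzero(owner == r)
        if idx.size == 0:
            continue
        sub = adj[idx, :][:, idx]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        labels[idx] = nxt + comp
        nxt += n_comp
    labels, n = relabel_by_size(labels)
    return Parcellation(labels=labels, n_parcels=n)


def make_ground_truth(
    mesh: SurfaceMesh,
    n_parcels: int = 10,
    R: int = 6,
    smoothness: float = 3.0,
    overlap: float = 0.5,
    n_timepoints: int = 120,
    n_subjects: int = 8,
    noise_sd: float = 0.3,
    seed: int = 0,
    identity_mixers: bool = False,
    uniform_loadings: bool = False,
) -> GroundTruth:
    """Planted state for one hemisphere.

    ``n_parcels`` bump centers are spread by farthest-point sampling and
    assigned round-robin to R networks, so networks own 1-2 spatially
    separated territories and the argmax parcellation has ~n_parcels
    contiguous parcels. ``uniform_loadings`` gives every subject the
    same participation (useful when identical vertex-pair correlation
    structure across subjects is required); ``identity_mixers`` disables
    the random orthogonal temporal mixing.
    """
    rng = np.random.default_rng(seed)
    centers = _farthest_point_centers(mesh, n_parcels, rng)
    adj = mesh.adjacency().astype(np.int8)
    dists = csgraph.dijkstra(adj, unweighted=True, indices=centers)
    owner = _assign_networks(dists[:, centers], R)
    maps = _bump_maps(mesh, centers, owner, R, smoothness, overlap, dists=dists)
    B = _smooth_unit_timecourses(n_timepoints, R, rng)
    if uniform_loadings:
        C = np.ones((n_subjects, R))
    else:
        C = rng.uniform(0.5, 1.5, size=(n_subjects, R))
    C /= np.linalg.norm(C, axis=0)
    lam = np.sort(rng.uniform(1.0, 3.0, size=R))[::-1]
    networks = NetworkSet(magnitudes=lam, spatial_maps=maps, time_courses=B,
                          subject_loadings=C)
    parc = _argmax_parcellation(mesh, maps)
    if identity_mixers:
        mixers = [np.eye(n_timepoints) for _ in range(n_subjects)]
    else:
        mixers = [_haar_orthogonal(n_timepoints, rng) for _ in range(n_subjects)]
    return GroundTruth(networks=networks, parcellation=parc, subject_mixers=mixers,
                       noise_sd=float(noise_sd), centers=centers, center_network=owner)


def make_dataset(
    truth: GroundTruth,
    S: int,
    T_session: int,
    sessions_per_subject: list[int],
    seed: int = 0,
) -> tuple[list[np.ndarray], GroupTensor]:
    """Per-subject (2*T_session, V) recordings and the stacked group tensor.

    Subject s's clean signal is sum_r lambda_r c_rs (Q_s b_r) a_r^T over
    the full 2*T_session time axis. Subjects with a single session keep
    only the first T_session rows, duplicated and concatenated, so every
    subject contributes the same doubled time length. Gaussian noise with
    sd = truth.noise_sd * std(clean signal) is added per session (and
    duplicated along with a duplicated session).
    """
    if len(sessions_per_subject) != S:
        raise ValueError("sessions_per_subject must have length S")
    if any(n not in (1, 2) for n in sessions_per_subject):
        raise ValueError("sessions_per_subject entries must be 1 or 2")
    if truth.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    net = truth.networks
    if T_session < net.rank:
        warnings.warn("T_session < rank: decomposition is underdetermined",
                      stacklevel=2)
    T = 2 * T_session
    if net.time_courses.shape[0] != T:
        raise ValueError("ground truth time courses must have length 2*T_session")
    if net.subject_loadings.shape[0] < S:
        raise ValueError("ground truth has fewer subjects than requested")
    rng = np.random.default_rng(seed)
    A, B, C, lam = (net.spatial_maps, net.time_courses, net.subject_loadings,
                    net.magnitudes)
    V = A.shape[0]

    cleans = []
    for s in range(S):
        Q = truth.subject_mixers[s]
        W = (Q @ B) * (lam * C[s])[np.newaxis, :]   # (T, R)
        cleans.append(W @ A.T)                      # (T, V)
    scale = float(np.std(np.stack(cleans)))
    noise_sd = truth.noise_sd * (scale if scale > 0 else 1.0)

    subjects = []
    for s in range(S):
        clean = cleans[s]
        if sessions_per_subject[s] == 1:
            half = clean[:T_session] + rng.normal(0.0, noise_sd, (T_session, V))
            data = np.vstack([half, half])
        else:
            data = clean + rng.normal(0.0, noise_sd, (T, V))
        subjects.append(data)
    tensor = GroupTensor(np.stack([d.T for d in subjects], axis=2))
    return subjects, tensor


def make_task_contrasts(
    truth: GroundTruth,
    n_contrasts: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Contrast maps as noisy nonnegative combinations of planted maps.

    Returns a (V, n_contrasts) array and a task grouping assigning
    contrasts round-robin to named tasks (about three contrasts per
    task) for the two-level variance aggregation.
    """
    if n_contrasts < 1:
        raise ValueError("n_contrasts must be >= 1")
    rng = np.random.default_rng(seed)
    maps = truth.networks.spatial_maps
    V, R = maps.shape
    contrasts = np.empty((V, n_contrasts))
    for j in range(n_contrasts):
        w = rng.uniform(0.0, 1.0, size=R)
        w[int(rng.integers(R))] += 1.0   # one dominant network per contrast
        c = maps @ w
        if noise_sd > 0:
            c = c + rng.normal(0.0, noise_sd * float(c.std()), size=V)
        contrasts[:, j] = c
    n_tasks = max(1, int(np.ceil(n_contrasts / 3)))
    grouping: dict[str, list[int]] = {f"task_{t}": [] for t in range(n_tasks)}
    for j in range(n_contrasts):
        grouping[f"task_{j % n_tasks}"].append(j)
    return contrasts, grouping
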