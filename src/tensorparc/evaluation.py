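"""Parcellation evaluation: connectivity homogeneity, task-contrast
variance, clustering agreement, random-parcellation nulls, and
parcel-network statistics.

Homogeneity of a parcellation is the parcel-size-weighted mean of the
within-parcel average Fisher-z connectivity,

    rho = sum_i rho_i * V_i / |V|,

where rho_i averages z over distinct unordered vertex pairs inside
parcel i. Task variance replaces rho_i by the within-parcel population
variance of a task-contrast map; lower is better. Random region-growing
parcellations with matched parcel counts serve as the null model for
ratio curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .embedding import Parcellation, gaussian_kernel, relabel_by_size
from .mesh import SurfaceMesh

__all__ = [
    "HomogeneityReport",
    "TaskVarianceReport",
    "rsfc_z",
    "homogeneity",
    "task_variance",
    "aggregate_task_variance",
    "adjusted_rand_index",
    "match_parcels",
    "random_parcellation",
    "ratio_curve",
    "parcel_networks",
    "degree_map",
    "paired_comparison",
]


@dataclass
class HomogeneityReport:
    per_parcel: np.ndarray       # rho_i
    weighted_average: float      # rho
    parcel_sizes: np.ndarray     # V_i
    n_parcels: int
    total_vertices: int          # |V| = evaluated (valid, labeled) vertices


@dataclass
class TaskVarianceReport:
    per_parcel: np.ndarray       # sigma_i^2
    weighted_average: float      # sigma^2 for this contrast
    parcel_sizes: np.ndarray
    n_parcels: int
    total_vertices: int


def rsfc_z(timeseries: np.ndarray, clip_epsilon: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z vertex-pair connectivity of a (T, V) series.

    Pearson correlations are clipped to [-1 + eps, 1 - eps] before
    atanh so duplicated series stay finite. Constant series are flagged
    invalid; their rows/columns are zero.

    Returns (z, valid).
    """
    X = np.asarray(timeseries, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    Y = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Y, axis=0)
    valid = norms > 1e-12 * max(1.0, float(np.abs(X).max(initial=0.0)))
    Yn = np.zeros_like(Y)
    Yn[:, valid] = Y[:, valid] / norms[valid]
    r = np.clip(Yn.T @ Yn, -1.0 + clip_epsilon, 1.0 - clip_epsilon)
    z = np.arctanh(r)
    z[~valid, :] = 0.0
    z[:, ~valid] = 0.0
    return z, valid


def _parcel_indices(parc: Parcellation) -> list[np.ndarray]:
    labels = parc.labels
    return [np.flatnonzero(labels == i) for i in range(parc.n_parcels)]


def homogeneity(z: np.ndarray, parcellation: Parcellation) -> HomogeneityReport:
    """Size-weighted within-parcel mean pairwise Fisher-z connectivity.

    rho_i averages z over the V_i*(V_i-1)/2 distinct unordered pairs
    inside parcel i (the diagonal never contributes). Singleton parcels
    get rho_i = 0 with a warning. The weights V_i / |V| use the number
    of evaluated vertices, so they form a convex combination.
    """
    z = np.asarray(z, dtype=float)
    labels = parcellation.labels
    if labels.shape[0] != z.shape[0]:
        raise ValueError("parcellation and z matrix disagree on |V|")
    if labels[labels >= 0].size and labels.max() >= parcellation.n_parcels:
        raise ValueError("label out of range")
    groups = _parcel_indices(parcellation)
    sizes = np.array([g.size for g in groups])
    rho_i = np.zeros(parcellation.n_parcels)
    for i, g in enumerate(groups):
        if g.size < 2:
            if g.size == 1:
                warnings.warn(f"singleton parcel {i}: homogeneity set to 0", stacklevel=2)
            continue
        block = z[np.ix_(g, g)]
        rho_i[i] = (block.sum() - np.trace(block)) / (g.size * (g.size - 1))
    total = int(sizes.sum())
    rho = float(rho_i @ (sizes / total)) if total else 0.0
    return HomogeneityReport(per_parcel=rho_i, weighted_average=rho,
                             parcel_sizes=sizes, n_parcels=parcellation.n_parcels,
                             total_vertices=total)


def task_variance(contrast: np.ndarray, parcellation: Parcellation) -> TaskVarianceReport:
    """Size-weighted within-parcel population variance of one contrast map."""
    c = np.asarray(contrast, dtype=float).ravel()
    if c.shape[0] != parcellation.labels.shape[0]:
        raise ValueError("contrast and parcellation disagree on |V|")
    groups = _parcel_indices(parcellation)
    sizes = np.array([g.size for g in groups])
    var_i = np.array([c[g].var() if g.size else 0.0 for g in groups])
    total = int(sizes.sum())
    sigma2 = float(var_i @ (sizes / total)) if total else 0.0
    return TaskVarianceReport(per_parcel=var_i, weighted_average=sigma2,
                              parcel_sizes=sizes, n_parcels=parcellation.n_parcels,
                              total_vertices=total)


def aggregate_task_variance(per_contrast: dict[str, list[float]]) -> float:
    """Two-level mean: unweighted within each task, then across tasks."""
    if not per_contrast:
        raise ValueError("empty task grouping")
    task_means = []
    for task, values in per_contrast.items():
        if len(values) == 0:
            raise ValueError(f"task {task!r} has no contrasts")
        task_means.append(float(np.mean(values)))
    return float(np.mean(task_means))


def adjusted_rand_index(labels1: np.ndarray, labels2: np.ndarray) -> float:
    """Chance-corrected pairwise agreement between two labelings."""
    from sklearn.metrics import adjusted_rand_score

    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    if labels1.shape != labels2.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels1, labels2))


def match_parcels(p1: Parcellation, p2: Parcellation):
    """One-to-one Hungarian matching of parcels maximizing total Dice.

    Cost is 1 - Dice per candidate pair; surplus parcels of the larger
    parcellation remain unmatched and are flagged.

    Returns
    -------
    pairs : list of (parcel_in_p1, parcel_in_p2) matched index pairs.
    dice : Dice coefficient per pair, sorted descending.
    unmatched : parcel ids of the larger parcellation left unmatched.
    """
    l1, l2 = p1.labels, p2.labels
    if l1.shape != l2.shape:
        raise ValueError("parcellations must cover the same vertex set")
    n1, n2 = p1.n_parcels, p2.n_parcels
    both = (l1 >= 0) & (l2 >= 0)
    cont = sp.coo_matrix(
        (np.ones(both.sum()), (l1[both], l2[both])), shape=(n1, n2)
    ).toarray()
    s1 = np.bincount(l1[l1 >= 0], minlength=n1).astype(float)
    s2 = np.bincount(l2[l2 >= 0], minlength=n2).astype(float)
    denom = s1[:, None] + s2[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        dice_mat = np.where(denom > 0, 2.0 * cont / denom, 0.0)
    rows, cols = linear_sum_assignment(1.0 - dice_mat)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    dice = np.sort(dice_mat[rows, cols])[::-1]
    if n1 >= n2:
        unmatched = sorted(set(range(n1)) - set(rows.tolist()))
    else:
        unmatched = sorted(set(range(n2)) - set(cols.tolist()))
    return pairs, dice, unmatched


def random_parcellation(mesh: SurfaceMesh, n_parcels: int, seed: int = 0,
                        valid: np.ndarray | None = None) -> Parcellation:
    """Region-growing random parcellation null model.

    ``n_parcels`` random seed vertices grow breadth-first in a
    round-robin over parcels, with seeded shuffling of the parcel order
    each round, until every valid vertex is claimed. Each parcel is
    non-empty and connected by construction.
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    V = mesh.n_vertices
    if valid is None:
        valid = np.ones(V, dtype=bool)
    candidates = np.flatnonzero(valid)
    if n_parcels > candidates.size:
        raise ValueError("more parcels than valid vertices")
    rng = np.random.default_rng(seed)
    adj = mesh.adjacency()
    indptr, indices = adj.indptr, adj.indices
    labels = np.full(V, -1, dtype=np.int32)
    seeds = rng.choice(candidates, size=n_parcels, replace=False)
    labels[seeds] = np.arange(n_parcels)
    frontiers = [[int(s)] for s in seeds]
    remaining = candidates.size - n_parcels
    while remaining > 0:
        grew = False
        for p in rng.permutation(n_parcels):
            new_frontier = []
            for v in frontiers[p]:
                for u in indices[indptr[v]:indptr[v + 1]]:
                    if valid[u] and labels[u] < 0:
                        labels[u] = p
                        new_frontier.append(int(u))
                        remaining -= 1
            if new_frontier:
                grew = True
            frontiers[p] = new_frontier
        if not grew:  # disconnected remainder: cannot be claimed
            warnings.warn("unreachable valid vertices left unlabeled", stacklevel=2)
            break
    relabeled, n = relabel_by_size(labels)
    return Parcellation(labels=relabeled, n_parcels=n)


def ratio_curve(
    parcellations: dict[int, Parcellation],
    mesh: SurfaceMesh,
    metric: str = "homogeneity",
    z_matrices: list[np.ndarray] | None = None,
    contrasts: np.ndarray | None = None,
    task_groups: dict[str, list[int]] | None = None,
    null_draws: int = 50,
    seed: int = 0,
) -> dict[int, float]:
    """Pipeline-vs-random metric ratio per parcel count k.

    For each k the metric of the supplied parcellation is divided by the
    mean metric over ``null_draws`` random region-growing parcellations
    of the same k (default 50 draws). Homogeneity scores are averaged
    across the supplied per-subject z matrices.
    """

    def score(parc: Parcellation) -> float:
        if metric == "homogeneity":
            if not z_matrices:
                raise ValueError("homogeneity ratio needs z matrices")
            return float(np.mean([homogeneity(z, parc).weighted_average
                                  for z in z_matrices]))
        if metric == "task_variance":
            if contrasts is None:
                raise ValueError("task-variance ratio needs contrast maps")
            C = np.atleast_2d(np.asarray(contrasts, float))
            if C.shape[0] == mesh.n_vertices:
                C = C.T
            per = [task_variance(C[j], parc).weighted_average for j in range(C.shape[0])]
            if task_groups:
                grouped = {t: [per[j] for j in js] for t, js in task_groups.items()}
                return aggregate_task_variance(grouped)
            return float(np.mean(per))
        raise ValueError(f"unknown metric {metric!r}")

    ratios: dict[int, float] = {}
    for k, parc in parcellations.items():
        valid = parc.labels >= 0
        null_scores = [
            score(random_parcellation(mesh, k, seed=seed + 1000 * k + d, valid=valid))
            for d in range(null_draws)
        ]
        ratios[k] = score(parc) / float(np.mean(null_scores))
    return ratios


def parcel_networks(parcel_timeseries: np.ndarray, n_networks: int,
                    global_signal_regression: bool = False,
                    seed: int = 0) -> np.ndarray:
    """Group parcels into networks by spectral clustering of parcel RSFC.

    Optionally regresses the global (mean across parcels) signal out of
    every parcel series first. The parcel-by-parcel Pearson correlation
    is kernelized to a positive affinity, and normalized-Laplacian
    spectral clustering (k-means on the leading eigenvectors) assigns
    each parcel to one of ``n_networks`` networks.
    """
    X = np.asarray(parcel_timeseries, dtype=float)
    n_parcels = X.shape[1]
    if n_networks > n_parcels:
        raise ValueError("more networks than parcels")
    if n_networks == n_parcels:
        return np.arange(n_parcels, dtype=np.int32)
    if global_signal_regression:
        g = X.mean(axis=1, keepdims=True)
        gg = float((g * g).sum())
        if gg > 0:
            X = X - g @ (g.T @ X) / gg
    C = np.corrcoef(X.T)
    C = np.nan_to_num(C, nan=0.0)
    W = gaussian_kernel(C, sigma=0.5)
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    deg[deg <= 0] = 1.0
    Dm = 1.0 / np.sqrt(deg)
    L = W * np.outer(Dm, Dm)
    evals, evecs = np.linalg.eigh(L)
    U = evecs[:, np.argsort(evals)[::-1][:n_networks]]
    rows = np.linalg.norm(U, axis=1)
    rows[rows == 0] = 1.0
    U = U / rows[:, None]
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_networks, n_init=20, random_state=int(seed)).fit(U)
    return km.labels_.astype(np.int32)


def degree_map(A: np.ndarray) -> np.ndarray:
    """Min-max-normalized non-negative degree of a similarity matrix.

    Negative entries are zeroed, degree is the off-diagonal row sum, and
    the result is scaled to [0, 1]. A constant-degree input returns all
    zeros with a warning.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("expected a square matrix")
    B = np.maximum(A, 0.0)
    deg = B.sum(axis=1) - np.diag(B)
    rng_ = deg.max() - deg.min()
    if rng_ <= 0:
        warnings.warn("constant degree map: returning zeros", stacklevel=2)
        return np.zeros_like(deg)
    return (deg - deg.min()) / rng_


@dataclass
class PairedComparison:
    t: float
    p: float
    d: float                 # Cohen's d of the paired differences
    degenerate: bool = False  # True when the differences have zero variance


def paired_comparison(values1: np.ndarray, values2: np.ndarray) -> PairedComparison:
    """Paired t-test plus Cohen's d = mean(diff) / sd(diff) (sample sd)."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.shape != v2.shape or v1.size < 2:
        raise ValueError("need two equal-length paired samples of size >= 2")
    diff = v1 - v2
    sd = diff.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences: effect size undefined", stacklevel=2)
        return PairedComparison(t=0.0, p=1.0, d=np.nan, degenerate=True)
    t, p = stats.ttest_rel(v1, v2)
    return PairedComparison(t=float(t), p=float(p), d=float(diff.mean() / sd))
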