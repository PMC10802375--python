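"""Unconstrained canonical-polyadic (CP) decomposition of the group tensor.

The synchronized group data form a third-order tensor X (vertex x time x
subject). A rank-R CP model

    X ~= sum_r  lambda_r  a_r o b_r o c_r

expresses it as R "networks": a_r is a spatial map over vertices, b_r a
shared time course, c_r per-subject participation, and lambda_r the
network magnitude. No orthogonality or independence is imposed, so
spatial maps may overlap and correlate — the property the downstream
graph construction relies on.

The solver is plain alternating least squares (ALS) with optional ridge
damping, deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroupTensor", "NetworkSet", "FeatureMatrix", "cp_decompose",
           "reconstruct", "feature_matrix"]


@dataclass
class GroupTensor:
    """|V| x T x S group data with bookkeeping.

    ``vertex_mask`` flags valid cortical vertices (e.g. excluding a
    medial wall); ``data`` must be finite on valid entries.
    """

    data: np.ndarray
    vertex_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("GroupTensor data must be 3-way (vertex, time, subject)")
        if self.vertex_mask is None:
            self.vertex_mask = np.ones(self.data.shape[0], dtype=bool)
        self.vertex_mask = np.asarray(self.vertex_mask, dtype=bool)
        if not np.all(np.isfinite(self.data[self.vertex_mask])):
            raise ValueError("non-finite entries in valid region of GroupTensor")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[2]


@dataclass
class NetworkSet:
    """CP factors: unit-norm a_r, b_r, c_r with magnitudes lambda_r.

    Magnitudes are sorted non-increasing; each spatial map's
    largest-magnitude entry is made positive (compensated in the time
    course) to remove sign indeterminacy.
    """

    magnitudes: np.ndarray          # (R,)
    spatial_maps: np.ndarray        # (V, R)
    time_courses: np.ndarray        # (T, R)
    subject_loadings: np.ndarray    # (S, R)
    rel_error: float | None = None
    error_trace: list[float] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return int(self.magnitudes.shape[0])


@dataclass
class FeatureMatrix:
    """|V| x R per-vertex network-participation features.

    Entry (i, j) is the participation level of vertex i in network j.
    """

    values: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _init_factors(X: np.ndarray, R: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Mode-wise leading singular vectors, seeded-Gaussian padded when R
    exceeds a mode dimension."""
    factors = []
    for mode in range(3):
        Xn = _unfold(X, mode)
        dim = Xn.shape[0]
        G = Xn @ Xn.T
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        U = evecs[:, order[: min(R, dim)]]
        if U.shape[1] < R:
            pad = rng.standard_normal((dim, R - U.shape[1]))
            pad /= np.maximum(np.linalg.norm(pad, axis=0), 1e-12)
            U = np.hstack([U, pad])
        factors.append(U)
    return factors


def cp_decompose(
    tensor: GroupTensor | np.ndarray,
    R: int,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    ridge: float = 0.0,
) -> NetworkSet:
    """Rank-R unconstrained CP fit by alternating least squares.

    Parameters
    ----------
    tensor : GroupTensor or 3-way array
    R : target rank (number of networks).
    max_iter, tol : ALS stops when the relative-error decrease per
        iteration falls below ``tol``.
    seed : seeds the Gaussian fallback initialization.
    ridge : optional Tikhonov damping of the normal equations.

    Returns
    -------
    NetworkSet with unit-norm factors, magnitudes sorted descending and
    the per-iteration relative reconstruction error trace.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if isinstance(tensor, GroupTensor):
        X = tensor.data
    else:
        X = np.asarray(tensor, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a 3-way tensor")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in tensor")

    norm_X = np.linalg.norm(X)
    if norm_X == 0.0:
        V, T, S = X.shape
        return NetworkSet(
            magnitudes=np.zeros(R),
            spatial_maps=np.zeros((V, R)),
            time_courses=np.zeros((T, R)),
            subject_loadings=np.zeros((S, R)),
            rel_error=0.0,
            error_trace=[0.0],
        )

    rng = np.random.default_rng(seed)
    A, B, C = _init_factors(X, R, rng)

    def mttkrp(mode: int) -> np.ndarray:
        if mode == 0:
            return np.einsum("its,tr,sr->ir", X, B, C, optimize=True)
        if mode == 1:
            return np.einsum("its,ir,sr->tr", X, A, C, optimize=True)
        return np.einsum("its,ir,tr->sr", X, A, B, optimize=True)

    eye = np.eye(R)
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        for mode in range(3):
            others = [f for m, f in enumerate((A, B, C)) if m != mode]
            G = np.multiply.reduce([f.T @ f for f in others]) + ridge * eye
            M = mttkrp(mode)
            try:
                F = np.linalg.solve(G, M.T).T
            except np.linalg.LinAlgError:
                F = M @ np.linalg.pinv(G)
            # each solve absorbs the full model scale; re-normalize and
            # carry it in lam
            norms = np.linalg.norm(F, axis=0)
            F = F / np.maximum(norms, 1e-300)
            lam = norms
            if mode == 0:
                A = F
            elif mode == 1:
                B = F
            else:
                C = F

        # relative error via the inner-product identity (no dense reconstruction)
        GA, GB, GC = A.T @ A, B.T @ B, C.T @ C
        inner = float(np.einsum("r,r->", lam, np.einsum("ir,ir->r", mttkrp(0), A)))
        model_sq = float(lam @ ((GA * GB * GC) @ lam))
        err_sq = max(norm_X**2 - 2.0 * inner + model_sq, 0.0)
        rel = float(np.sqrt(err_sq) / norm_X)
        trace.append(rel)
        if prev - rel < tol:
            break
        prev = rel

    # absorb magnitudes, sort, fix signs
    order = np.argsort(lam)[::-1]
    lam, A, B, C = lam[order], A[:, order], B[:, order], C[:, order]
    for r in range(R):
        i = int(np.argmax(np.abs(A[:, r])))
        if A[i, r] < 0:
            A[:, r] = -A[:, r]
            B[:, r] = -B[:, r]
        j = int(np.argmax(np.abs(C[:, r])))
        if C[j, r] < 0:
            C[:, r] = -C[:, r]
            B[:, r] = -B[:, r]
    return NetworkSet(
        magnitudes=lam,
        spatial_maps=A,
        time_courses=B,
        subject_loadings=C,
        rel_error=trace[-1] if trace else None,
        error_trace=trace,
    )


def reconstruct(networks: NetworkSet) -> np.ndarray:
    """Dense |V| x T x S reconstruction  sum_r lambda_r a_r o b_r o c_r."""
    return np.einsum(
        "r,ir,tr,sr->its",
        networks.magnitudes,
        networks.spatial_maps,
        networks.time_courses,
        networks.subject_loadings,
        optimize=True,
    )


def feature_matrix(networks: NetworkSet, scaling: str = "unit_norm") -> FeatureMatrix:
    """Stack spatial maps into the |V| x R per-vertex feature matrix.

    ``unit_norm`` keeps each column at norm 1; ``lambda_scaled`` weights
    columns by their network magnitude. Downstream vertex-pair
    correlations generally differ between the two, hence the flag.
    """
    if networks.rank < 2:
        raise ValueError("feature matrix needs rank >= 2")
    if scaling == "unit_norm":
        vals = networks.spatial_maps.copy()
    elif scaling == "lambda_scaled":
        vals = networks.spatial_maps * networks.magnitudes[np.newaxis, :]
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return FeatureMatrix(values=vals)
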