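"""Kronecker regularized least squares on a bipartite association matrix.

The model scores every (disease, microbe) pair at once.  A pairwise kernel
over pairs is the Kronecker product ``K = S_m (x) S_d`` of a microbe-microbe
and a disease-disease similarity; the Tikhonov-regularized least squares
solution is

    vec(F) = K (K + sigma I)^{-1} vec(Y)

with ``Y`` the 0/1 training matrix and ``vec`` column-major stacking.  The
``N x N`` kernel (``N = nd * nm``) is never materialized in the production
path: with eigendecompositions ``S_m = V_m L_m V_m^T`` and
``S_d = V_d L_d V_d^T``, the solution reduces to an elementwise filter factor
in the joint eigenbasis,

    F = V_d [ (l_d l_m^T) / (l_d l_m^T + sigma) * (V_d^T Y V_m) ] V_m^T,

costing two small eigendecompositions plus O(nd*nm) work.  One score matrix
is computed per similarity branch (Gaussian kernel and Hamming) and the two
are fused as ``F* = w F_G + (1 - w) F_H``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .data_model import AssociationDataset
from .similarity import SimilarityMatrix, gip_similarity, hip_similarity

__all__ = [
    "ModelParams",
    "ScoreMatrix",
    "EigenPair",
    "eig_decompose",
    "kronecker_similarity",
    "krls_solve_direct",
    "krls_solve_eigen",
    "fuse_scores",
    "predict",
    "predict_branches",
]

#: Largest pairwise-kernel size the direct (oracle) path will materialize.
KRON_SIZE_CAP = 4000


@dataclass(frozen=True)
class ModelParams:
    """Model hyperparameters.

    ``sigma_G`` and ``sigma_H`` regularize the Gaussian- and Hamming-branch
    solvers (default 30, the plateau value found by sensitivity analysis);
    ``w`` weights the Gaussian branch in the fused score (default 0.8);
    ``sigma_prime_m``/``sigma_prime_d`` are GIP bandwidth trade-offs
    (default 1); ``denom_tol`` guards the eigen-path denominators.
    """

    sigma_G: float = 30.0
    sigma_H: float = 30.0
    w: float = 0.8
    sigma_prime_m: float = 1.0
    sigma_prime_d: float = 1.0
    denom_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.sigma_G <= 0 or self.sigma_H <= 0:
            raise ValueError("regularization parameters must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("fusion weight w must lie in [0, 1]")
        if self.sigma_prime_m <= 0 or self.sigma_prime_d <= 0:
            raise ValueError("bandwidth trade-off parameters must be positive")
        if self.denom_tol <= 0:
            raise ValueError("denom_tol must be positive")

    def with_sigma(self, sigma: float) -> "ModelParams":
        """Both branch regularizers set to the same value (coupled sweep)."""
        return replace(self, sigma_G=sigma, sigma_H=sigma)


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued disease x microbe prediction scores for one branch."""

    values: np.ndarray = field(repr=False)
    branch: Literal["gaussian", "hamming", "fused"]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("score matrix must be 2-dimensional")
        if not np.isfinite(values).all():
            raise ValueError("score matrix contains non-finite entries")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class EigenPair:
    """Orthogonal eigenvectors and eigenvalues (descending) of a symmetric matrix."""

    vectors: np.ndarray
    eigenvalues: np.ndarray


def _sym_values(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("similarity input must be square")
    # wash out floating-point asymmetry before eigh
    return (values + values.T) / 2.0


def eig_decompose(S: SimilarityMatrix | np.ndarray) -> EigenPair:
    """Symmetric eigendecomposition with eigenvalues in descending order."""
    lam, V = np.linalg.eigh(_sym_values(S))
    order = np.argsort(lam)[::-1]
    return EigenPair(vectors=V[:, order], eigenvalues=lam[order])


def kronecker_similarity(
    S_m: SimilarityMatrix | np.ndarray,
    S_d: SimilarityMatrix | np.ndarray,
    size_cap: int = KRON_SIZE_CAP,
) -> np.ndarray:
    """Explicit pairwise kernel ``S_m (x) S_d`` (small instances only).

    Under column-major vectorization of nd x nm matrices this satisfies
    ``K @ vec(Y) == vec(S_d @ Y @ S_m.T)``.  Production predictions use the
    eigendecomposition path instead; this exists for oracle testing, hence
    the size cap.
    """
    Sm = _sym_values(S_m)
    Sd = _sym_values(S_d)
    N = Sm.shape[0] * Sd.shape[0]
    if N > size_cap:
        raise ValueError(
            f"pairwise kernel would be {N} x {N} (cap {size_cap}); "
            "use krls_solve_eigen instead"
        )
    return np.kron(Sm, Sd)


def krls_solve_direct(K: np.ndarray, Y: np.ndarray, sigma: float) -> ScoreMatrix:
    """Brute-force solve ``vec(F) = K (K + sigma I)^{-1} vec(Y)``.

    Oracle path: materializes the full pairwise kernel system.  ``Y`` is
    nd x nm; vectorization is column-major throughout.
    """
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    N = K.shape[0]
    if K.shape != (N, N) or Y.size != N:
        raise ValueError("kernel and training-matrix sizes are inconsistent")
    system = K + sigma * np.eye(N)
    cond = np.linalg.cond(system)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"(K + sigma I) is ill-conditioned (cond={cond:.3g}); increase sigma"
        )
    x = np.linalg.solve(system, Y.reshape(-1, order="F"))
    F = (K @ x).reshape(Y.shape, order="F")
    return ScoreMatrix(values=F, branch="fused")


def krls_solve_eigen(
    S_m: SimilarityMatrix | np.ndarray,
    S_d: SimilarityMatrix | np.ndarray,
    Y: np.ndarray,
    sigma: float,
    denom_tol: float = 1e-10,
    branch: Literal["gaussian", "hamming", "fused"] = "fused",
) -> ScoreMatrix:
    """Solve the Kronecker RLS system via per-axis eigendecompositions.

    Never forms an ``N x N`` matrix.  The filter factor
    ``l_d * l_m / (l_d * l_m + sigma)`` is applied elementwise in the joint
    eigenbasis.  Similarity inputs need not be positive semidefinite (the
    Hamming branch can be indefinite); each denominator must merely stay
    bounded away from zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    Y = np.asarray(Y, dtype=float)
    em = eig_decompose(S_m)
    ed = eig_decompose(S_d)
    if Y.shape != (ed.eigenvalues.size, em.eigenvalues.size):
        raise ValueError(
            f"training matrix shape {Y.shape} does not match similarity sizes "
            f"({ed.eigenvalues.size} diseases, {em.eigenvalues.size} microbes)"
        )
    products = np.outer(ed.eigenvalues, em.eigenvalues)
    denom = products + sigma
    bad = np.abs(denom) <= denom_tol
    if bad.any():
        p, q = np.argwhere(bad)[0]
        raise ValueError(
            f"eigenvalue product lambda_d[{p}] * lambda_m[{q}] = "
            f"{products[p, q]:.6g} cancels sigma = {sigma:.6g} to within "
            f"{denom_tol:g}; increase sigma"
        )
    Z = ed.vectors.T @ Y @ em.vectors
    X = (products / denom) * Z
    F = ed.vectors @ X @ em.vectors.T
    return ScoreMatrix(values=F, branch=branch)


def fuse_scores(F_G: ScoreMatrix, F_H: ScoreMatrix, w: float) -> ScoreMatrix:
    """Weighted fusion ``F* = w F_G + (1 - w) F_H``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("fusion weight w must lie in [0, 1]")
    if F_G.values.shape != F_H.values.shape:
        raise ValueError("score matrices have different shapes")
    return ScoreMatrix(values=w * F_G.values + (1.0 - w) * F_H.values, branch="fused")


def predict_branches(
    dataset: AssociationDataset, params: ModelParams = ModelParams()
) -> tuple[ScoreMatrix, ScoreMatrix, ScoreMatrix]:
    """Gaussian-branch, Hamming-branch and fused score matrices."""
    A = dataset.A
    S_G_m = gip_similarity(A, "microbe", params.sigma_prime_m, dataset.microbe_ids)
    S_G_d = gip_similarity(A, "disease", params.sigma_prime_d, dataset.disease_ids)
    S_H_m = hip_similarity(A, "microbe", dataset.microbe_ids)
    S_H_d = hip_similarity(A, "disease", dataset.disease_ids)
    F_G = krls_solve_eigen(S_G_m, S_G_d, A, params.sigma_G, params.denom_tol, "gaussian")
    F_H = krls_solve_eigen(S_H_m, S_H_d, A, params.sigma_H, params.denom_tol, "hamming")
    return F_G, F_H, fuse_scores(F_G, F_H, params.w)


def predict(dataset: AssociationDataset, params: ModelParams = ModelParams()) -> ScoreMatrix:
    """Fused prediction scores for every (disease, microbe) pair."""
    return predict_branches(dataset, params)[2]
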