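"""Interaction-profile similarities for microbes and diseases.

Both similarity measures treat an entity's row or column of the training
adjacency matrix — its *interaction profile* — as a binary feature vector:

* GIP (Gaussian interaction profile) kernel similarity:
  ``exp(-sigma * ||a_i - a_j||^2)`` with the bandwidth ``sigma`` set to a
  trade-off parameter ``sigma'`` divided by the mean squared profile norm, so
  the kernel adapts to the density of the network.
* HIP (Hamming interaction profile) similarity: one minus the fraction of
  profile positions at which two entities disagree.

On 0/1 vectors the squared Euclidean distance equals the Hamming mismatch
count, so both measures are computed on an exact integer mismatch matrix
before any floating-point transform; symmetry is therefore exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Literal, Sequence

import numpy as np

__all__ = [
    "Axis",
    "SimilarityMatrix",
    "BandwidthParams",
    "gip_bandwidth",
    "gip_similarity",
    "hip_similarity",
    "write_similarity",
]

Axis = Literal["microbe", "disease"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric entity-by-entity similarity with axis and kind tags."""

    values: np.ndarray = field(repr=False)
    axis: Axis
    kind: Literal["GIP", "HIP"]
    entity_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.array_equal(values, values.T):
            raise ValueError("similarity matrix must be exactly symmetric")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BandwidthParams:
    """GIP bandwidth: ``sigma = sigma' / mean squared profile norm``."""

    sigma_prime: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma_prime <= 0 or self.sigma <= 0:
            raise ValueError("bandwidth parameters must be positive")


def _check_binary(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or not np.isin(A, (0, 1)).all():
        raise ValueError("training matrix must be a 2-D 0/1 matrix")
    return A.astype(np.int64)


def _profiles(A: np.ndarray, axis: Axis) -> np.ndarray:
    """One interaction profile per row of the result.

    Microbe profiles are the columns of A (length nd); disease profiles are
    the rows (length nm).
    """
    if axis == "microbe":
        return A.T
    if axis == "disease":
        return A
    raise ValueError(f"axis must be 'microbe' or 'disease', got {axis!r}")


def _mismatch_counts(profiles: np.ndarray) -> np.ndarray:
    """Exact pairwise Hamming counts between binary profiles (integer matrix)."""
    gram = profiles @ profiles.T
    norms = np.diag(gram)
    return norms[:, None] + norms[None, :] - 2 * gram


def gip_bandwidth(A: np.ndarray, axis: Axis, sigma_prime: float = 1.0) -> BandwidthParams:
    """Adaptive GIP bandwidth for the given axis.

    For an all-zero training matrix the mean squared norm is zero; the
    bandwidth falls back to ``sigma_prime`` so that downstream kernels stay
    well defined (all distances are zero anyway, giving an all-ones kernel).
    """
    if sigma_prime <= 0:
        raise ValueError("sigma_prime must be positive")
    profiles = _profiles(_check_binary(A), axis)
    mean_sq_norm = float(np.mean(np.sum(profiles * profiles, axis=1)))
    sigma = sigma_prime / mean_sq_norm if mean_sq_norm > 0 else sigma_prime
    return BandwidthParams(sigma_prime=sigma_prime, sigma=sigma)


def gip_similarity(
    A: np.ndarray,
    axis: Axis,
    sigma_prime: float = 1.0,
    entity_ids: Sequence[str] = (),
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity along one axis."""
    profiles = _profiles(_check_binary(A), axis)
    bw = gip_bandwidth(A, axis, sigma_prime)
    counts = _mismatch_counts(profiles)
    values = np.exp(-bw.sigma * counts)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, axis=axis, kind="GIP", entity_ids=entity_ids)


def hip_similarity(
    A: np.ndarray,
    axis: Axis,
    entity_ids: Sequence[str] = (),
) -> SimilarityMatrix:
    """Hamming interaction profile similarity along one axis."""
    profiles = _profiles(_check_binary(A), axis)
    length = profiles.shape[1]
    counts = _mismatch_counts(profiles)
    values = 1.0 - counts / length
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, axis=axis, kind="HIP", entity_ids=entity_ids)


def write_similarity(sim: SimilarityMatrix, stream: IO[str], delimiter: str = ",") -> None:
    """Write a labeled dense CSV of a similarity matrix (for inspection)."""
    ids = sim.entity_ids or tuple(str(i) for i in range(sim.n))
    stream.write(delimiter.join(["", *ids]) + "\n")
    for i, label in enumerate(ids):
        cells = (format(v, ".12g") for v in sim.values[i])
        stream.write(delimiter.join([label, *cells]) + "\n")
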