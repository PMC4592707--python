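"""Principal component analysis of a Cα trajectory.

The covariance matrix of the spatial fluctuation,
M_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩, is assembled from the 3N-dimensional
Cα coordinate vectors of all P+1 frames (population average, 1/(P+1)).
Frames are by default rigidly superposed onto a reference (the final,
native frame) first, so rigid-body motion does not masquerade as internal
fluctuation; ``alignment_mode="none"`` gives the literal unaligned
covariance.  Diagonalizing M yields 3N eigenvalues/eigenvectors; the top
few components typically dominate a folding pathway, and per-residue
eigenvector magnitudes localize the dominant motions along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import superpose
from .structures import Conformation, Path

__all__ = [
    "CovarianceMatrix", "PCAResult", "compute_covariance", "eigendecompose",
    "variance_fraction", "project", "residue_contributions",
]


@dataclass
class CovarianceMatrix:
    """3N×3N spatial-fluctuation covariance over path frames."""

    matrix: np.ndarray
    mean_vector: np.ndarray
    n_frames: int
    alignment_mode: str                 # "none" | "superpose"
    reference: np.ndarray | None = None  # (N_Cα, 3) used for superposition

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = 0.5 * (m + m.T)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, non-negative
    eigenvectors: np.ndarray       # (3N, 3N), columns orthonormal
    mean_vector: np.ndarray
    alignment_mode: str
    reference: np.ndarray | None

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot == 0:
            raise ZeroDivisionError("zero total variance")
        return self.eigenvalues / tot

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)


def _aligned_ca_vectors(path, alignment_mode: str,
                        reference: np.ndarray | None):
    if isinstance(path, Path):
        ca_idx = path.topology.calpha_indices
        frames = path.coords[:, ca_idx, :]
    else:  # a bare sequence of Conformations (e.g. a 2-frame pair)
        frames = np.stack([
            f.positions[f.topology.calpha_indices] for f in path])
    if alignment_mode == "superpose":
        ref = frames[-1] if reference is None else np.asarray(reference, float)
        frames = np.stack([superpose(f, ref) for f in frames])
    elif alignment_mode != "none":
        raise ValueError("alignment_mode must be 'none' or 'superpose'")
    else:
        ref = None
    return frames.reshape(len(frames), -1), ref


def compute_covariance(path: Path, alignment_mode: str = "superpose",
                       reference: Conformation | None = None) -> CovarianceMatrix:
    """Assemble the Cα fluctuation covariance matrix over all frames.

    ``reference`` (a Conformation whose Cα positions anchor the
    superposition) defaults to the final frame, i.e. the native endpoint of
    a folding path.
    """
    n_frames = path.n_frames if isinstance(path, Path) else len(path)
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    ref_coords = None
    if reference is not None:
        ref_coords = reference.positions[reference.topology.calpha_indices]
    X, ref = _aligned_ca_vectors(path, alignment_mode, ref_coords)
    mean = X.mean(axis=0)
    D = X - mean
    M = D.T @ D / len(X)               # population normalization, 1/(P+1)
    return CovarianceMatrix(M, mean, len(X), alignment_mode, ref)


def eigendecompose(cov: CovarianceMatrix) -> PCAResult:
    """Eigenpairs of M, descending; tiny negative eigenvalues clamped to 0.

    Eigenvector signs are fixed so each column's largest-magnitude entry is
    positive.
    """
    vals, vecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    clamp = 1e-8 * max(np.trace(cov.matrix), 0.0)
    vals = np.where(vals < clamp, np.maximum(vals, 0.0), vals)
    vals[np.abs(vals) < clamp] = np.abs(vals[np.abs(vals) < clamp])
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return PCAResult(np.maximum(vals, 0.0), vecs, cov.mean_vector,
                     cov.alignment_mode, cov.reference)


def variance_fraction(result: PCAResult, k: int) -> float:
    """Fraction of total variance captured by the top ``k`` components."""
    n = len(result.eigenvalues)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    tot = result.eigenvalues.sum()
    if tot == 0:
        raise ZeroDivisionError("zero total variance")
    return float(result.eigenvalues[:k].sum() / tot)


def project(path: Path, result: PCAResult, components=(0, 1, 2)) -> np.ndarray:
    """Per-frame coordinates of the path on selected components.

    Frames are centered with the stored mean and aligned exactly as the
    covariance was (same mode and reference).
    """
    comp = np.asarray(components, int)
    if comp.min() < 0 or comp.max() >= result.eigenvectors.shape[1]:
        raise IndexError("component index out of range")
    X, _ = _aligned_ca_vectors(path, result.alignment_mode, result.reference)
    if X.shape[1] != len(result.mean_vector):
        raise ValueError("path incompatible with PCA result")
    return (X - result.mean_vector) @ result.eigenvectors[:, comp]


def residue_contributions(result: PCAResult, component: int = 0) -> np.ndarray:
    """Per-residue magnitude of one eigenvector.

    Entry r is the Euclidean norm of the residue's (x, y, z) triplet within
    the unit eigenvector; the squared contributions sum to 1.
    """
    if not 0 <= component < result.eigenvectors.shape[1]:
        raise IndexError("component out of range")
    v = result.eigenvectors[:, component].reshape(-1, 3)
    return np.linalg.norm(v, axis=1)
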