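"""Generalised Procrustes Analysis (GPA) and tangent-space projection.

GPA removes location (centering), size (scaling every configuration to
unit centroid size) and orientation (rotation-only least-squares fit to
an iteratively refined consensus).  Reflections are deliberately never
absorbed by the fit: in symmetry analysis they are explicit data
operations, and letting the superimposition flip configurations would
destroy the asymmetric component of variation.

Aligned configurations are then projected into the linear tangent space
at the consensus, where standard multivariate statistics apply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Dataset

__all__ = [
    "centroid_size",
    "optimal_rotation",
    "ProcrustesResult",
    "gpa",
    "tangent_project",
    "procrustes_distance",
    "ProcrustesAlignment",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||source @ R - target||_F (Kabsch).

    Reflections are excluded: if the best orthogonal map would flip the
    configuration, the best proper rotation is returned instead.
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.ones(h.shape[0])
    corr[-1] = d
    return (u * corr) @ vt


@dataclass
class ProcrustesResult:
    """Output of a Procrustes superimposition.

    ``aligned`` configurations are centred, unit-size and rotated onto the
    consensus; ``tangent`` holds flattened tangent-space coordinates once
    :func:`tangent_project` has run.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    tangent: np.ndarray | None = None


def _as_array(data) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.coords_array()
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected (n, p, d) coordinates, got shape {arr.shape}")
    return arr


def _principal_axes_align(consensus: np.ndarray, aligned: np.ndarray):
    """Rotate the consensus onto its principal axes and co-rotate all
    configurations; sign fixed so landmark 1 has non-negative x."""
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    rot = vecs[:, ::-1]  # descending axes
    if np.linalg.det(rot) < 0:
        rot[:, -1] = -rot[:, -1]
    new_consensus = consensus @ rot
    if new_consensus[0, 0] < 0:
        flip = -np.eye(rot.shape[0])
        flip[-1, -1] = 1.0 if rot.shape[0] % 2 == 0 else -1.0
        # in 2D a 180 degree rotation; keeps det +1
        flip = np.diag([-1.0, -1.0]) if rot.shape[0] == 2 else flip
        rot = rot @ flip
        new_consensus = consensus @ rot
    return new_consensus, aligned @ rot, rot


def gpa(
    data,
    align_principal_axes: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Iterative generalised Procrustes superimposition.

    Parameters
    ----------
    data : Dataset or (n, p, d) array
        At least two configurations with shared landmark scheme.
    align_principal_axes : bool
        Rotate the final consensus to its principal axes (the conventional
        display orientation) and co-rotate the sample.
    tol : float
        Convergence threshold on the root-mean-square change of the
        consensus between iterations.
    max_iter : int
        Iteration cap; non-convergence returns ``converged=False`` with a
        warning rather than raising.
    """
    coords = _as_array(data)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two configurations")

    sizes = np.array([centroid_size(c) for c in coords])
    if np.any(sizes <= 0):
        bad = int(np.argmin(sizes))
        raise ValueError(f"configuration {bad} has zero centroid size (degenerate)")

    centred = coords - coords.mean(axis=1, keepdims=True)
    scaled = centred / sizes[:, None, None]

    consensus = scaled[0].copy()
    consensus /= centroid_size(consensus)
    aligned = scaled.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ optimal_rotation(scaled[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning
        )
    # final pass against the converged consensus
    for i in range(n):
        aligned[i] = scaled[i] @ optimal_rotation(scaled[i], consensus)

    if align_principal_axes:
        consensus, aligned, _ = _principal_axes_align(consensus, aligned)

    return ProcrustesResult(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


def tangent_project(result: ProcrustesResult) -> ProcrustesResult:
    """Project aligned configurations into the tangent space at the consensus.

    The projection is orthogonal to the consensus direction: with the
    consensus scaled to unit centroid size its flattened vector c has unit
    norm, and each aligned configuration x maps to x - (x . c) c.
    """
    n = result.aligned.shape[0]
    c = result.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    flat = result.aligned.reshape(n, -1)
    result.tangent = flat - np.outer(flat @ c, c)
    return result


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations
    (location, size and rotation removed; no reflection)."""
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    a = a / centroid_size(a)
    b = b / centroid_size(b)
    a = a @ optimal_rotation(a, b)
    return float(np.linalg.norm(a - b))


class ProcrustesAlignment:
    """Generalised Procrustes superimposition as a scikit-learn style transformer.

    ``fit`` runs GPA on a sample of configurations; ``transform`` aligns
    configurations (the training sample or new ones) to the fitted
    consensus and returns tangent-space coordinates as an (n, p*d) matrix,
    so the transformer composes with ordinary multivariate pipelines.

    Parameters
    ----------
    align_principal_axes : bool, default True
        Orient the consensus along its principal axes after convergence.
    tol : float, default 1e-10
        Consensus convergence threshold.
    max_iter : int, default 100
        Maximum GPA iterations.

    Attributes
    ----------
    consensus_ : (p, d) ndarray
        Unit-centroid-size mean shape.
    aligned_ : (n, p, d) ndarray
        Superimposed training configurations.
    tangent_ : (n, p*d) ndarray
        Tangent coordinates of the training sample.
    centroid_sizes_ : (n,) ndarray
        Centroid size of each input configuration (before scaling).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, align_principal_axes: bool = True, tol: float = 1e-10,
                 max_iter: int = 100):
        self.align_principal_axes = align_principal_axes
        self.tol = tol
        self.max_iter = max_iter

    # minimal get/set_params so the class plugs into sklearn model selection
    def get_params(self, deep: bool = True) -> dict:
        return {
            "align_principal_axes": self.align_principal_axes,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "ProcrustesAlignment":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "ProcrustesAlignment":
        result = gpa(
            X,
            align_principal_axes=self.align_principal_axes,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        tangent_project(result)
        self.result_ = result
        self.consensus_ = result.consensus
        self.aligned_ = result.aligned
        self.tangent_ = result.tangent
        self.centroid_sizes_ = result.centroid_sizes
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "consensus_"):
            raise AttributeError("ProcrustesAlignment is not fitted yet")
        coords = _as_array(X)
        n = coords.shape[0]
        centred = coords - coords.mean(axis=1, keepdims=True)
        sizes = np.array([centroid_size(c) for c in centred])
        scaled = centred / sizes[:, None, None]
        aligned = np.empty_like(scaled)
        for i in range(n):
            aligned[i] = scaled[i] @ optimal_rotation(scaled[i], self.consensus_)
        c = self.consensus_.reshape(-1)
        c = c / np.linalg.norm(c)
        flat = aligned.reshape(n, -1)
        return flat - np.outer(flat @ c, c)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).tangent_
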