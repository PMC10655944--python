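"""Generalized Procrustes analysis for 2D landmark configurations.

Superimposition removes the similarity-transform nuisance (translation, scale,
orientation) from raw landmark coordinates, leaving pure shape: each
configuration is centred, scaled to unit centroid size, and rotated into
least-squares agreement with an iteratively re-estimated consensus.  Residuals
from the consensus, projected onto the tangent plane at the consensus, are the
shape variables consumed by every downstream multivariate analysis.

Size is carried separately as centroid size — the square root of the summed
squared distances of the landmarks to their centroid — computed on the raw
configurations before normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_tps import LandmarkConfiguration


class DegenerateShapeError(ValueError):
    """All landmarks coincide; the shape carries no information."""


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size CS = sqrt(sum_i ||p_i - centroid||^2).

    Invariant to translation and rotation; scales linearly under uniform
    scaling.  Returns 0.0 for a fully degenerate (single-point) configuration.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else \
        np.asarray(config, dtype=float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred ** 2)))


def center(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def to_preshape(coords: np.ndarray) -> np.ndarray:
    """Centre and scale to unit centroid size."""
    centred = center(coords)
    cs = np.sqrt(np.sum(centred ** 2))
    if cs == 0.0:
        raise DegenerateShapeError("degenerate shape: all landmarks coincide")
    return centred / cs

def optimal_rotation(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimising ||config @ R - reference||_F.

    Reflections are excluded (det R = +1): left and right crania must never be
    mirror-matched.  Shapes are k x 2 with landmarks in rows.
    """
    m = config.T @ reference
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def align_pair(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate a centred, unit-size shape onto a reference (no reflection)."""
    config = np.asarray(config, dtype=float)
    if not np.any(config != config.mean(axis=0)):
        raise DegenerateShapeError("degenerate shape: all landmarks coincide")
    return config @ optimal_rotation(config, np.asarray(reference, float))


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Partial Procrustes distance: min over rotations of ||A - B·R||.

    Both inputs are centred and rescaled to unit centroid size first, so the
    function accepts raw configurations too.  This distance (2·sin(ρ/2) for
    Procrustes arc ρ) is a metric: symmetric, zero iff the shapes coincide up
    to similarity, and satisfying the triangle inequality.
    """
    a = np.asarray(shape_a, dtype=float)
    b = np.asarray(shape_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    a = to_preshape(a)
    b = to_preshape(b)
    return float(np.linalg.norm(align_pair(b, a) - a))


@dataclass
class GPAResult:
    """Output of a generalized Procrustes superimposition.

    Attributes
    ----------
    consensus : (k, 2) ndarray
        Mean shape, centred at the origin with unit centroid size.
    aligned : (n, k, 2) ndarray
        Superimposed configurations (centred, unit size, rotated).
    tangent : (n, 2k) ndarray
        Tangent-space shape coordinates (orthogonal projection at the
        consensus); rows sum to zero-mean columns.
    centroid_sizes : (n,) ndarray
        Centroid sizes of the raw configurations, before normalisation.
    ids : tuple of str
        Specimen ids in row order.
    iterations : int
    converged : bool
    sum_of_squares_trace : list of float
        Total squared distance to the consensus after each iteration
        (non-increasing).
    """

    consensus: np.ndarray
    aligned: np.ndarray
    tangent: np.ndarray
    centroid_sizes: np.ndarray
    ids: tuple[str, ...]
    iterations: int
    converged: bool
    sum_of_squares_trace: list[float]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def _principal_axis_standardise(consensus: np.ndarray,
                                aligned: np.ndarray) -> tuple[np.ndarray,
                                                              np.ndarray]:
    # Rotate the whole superimposition so the consensus's principal axes lie
    # on the coordinate axes; makes the result independent of the initial
    # reference choice (up to the residual sign ambiguity, fixed below).
    cov = consensus.T @ consensus
    eigval, eigvec = np.linalg.eigh(cov)
    rot = eigvec[:, ::-1]            # major axis first
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]
    consensus = consensus @ rot
    aligned = aligned @ rot
    # The remaining ambiguity is a 180-degree rotation (a single-axis flip
    # would be a reflection, which is never applied to shapes).
    col = consensus[:, 0]
    if col[np.argmax(np.abs(col))] < 0:
        consensus = -consensus
        aligned = -aligned
    return consensus, aligned


def gpa(configs, tol: float = 1e-10, max_iter: int = 1000) -> GPAResult:
    """Generalized Procrustes analysis of two or more configurations.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated onto the current consensus; the consensus is the
    renormalised mean of the aligned set.  Iteration stops when the root mean
    square change of the consensus falls below ``tol``.

    ``configs`` may be a sequence of :class:`LandmarkConfiguration` or an
    (n, k, 2) array.  With configurations, processing order is id-sorted and
    the output is rotation-standardised by the consensus principal axes, so
    the result does not depend on input order.
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        ids = tuple(str(i) for i in range(arr.shape[0]))
    else:
        configs = sorted(configs, key=lambda c: c.specimen_id)
        ids = tuple(c.specimen_id for c in configs)
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
        arr = np.stack([c.coords for c in configs])
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    if tol <= 0:
        raise ValueError("tol must be positive")

    centroid_sizes = np.array([centroid_size(x) for x in arr])
    pre = np.stack([to_preshape(x) for x in arr])

    consensus = pre[0].copy()
    trace: list[float] = []
    converged = False
    iterations = 0
    aligned = pre
    for iterations in range(1, max_iter + 1):
        aligned = np.stack([align_pair(x, consensus) for x in pre])
        mean = aligned.mean(axis=0)
        new_consensus = to_preshape(mean)
        trace.append(float(np.sum((aligned - new_consensus) ** 2)))
        delta = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning
        )
    # Final pass: align to the converged consensus, then recompute it as the
    # renormalised mean of that alignment so the tangent scores centre exactly.
    aligned = np.stack([align_pair(x, consensus) for x in pre])
    consensus = to_preshape(aligned.mean(axis=0))
    consensus, aligned = _principal_axis_standardise(consensus, aligned)

    c = consensus.reshape(-1)
    flat = aligned.reshape(n, -1)
    tangent = flat - np.outer(flat @ c, c)   # (I - cc') x_i
    return GPAResult(
        consensus=consensus,
        aligned=aligned,
        tangent=tangent,
        centroid_sizes=centroid_sizes,
        ids=ids,
        iterations=iterations,
        converged=converged,
        sum_of_squares_trace=trace,
    )
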