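"""Chiral, geometry-complete local frames and scalarization.

For a directed edge (i, j) of a CoM-centered point cloud the frame is

    a = (x_i − x_j) / ‖x_i − x_j‖
    b = (x_i × x_j) / ‖x_i × x_j‖
    c = a × b

The triple spans 3D space (geometry completeness), rotates with the
input, and flips handedness under reflection: projections onto ``b`` and
``c`` change sign for a mirrored input, which is what lets the denoiser
distinguish enantiomers.  Degenerate geometries (coincident atoms, or
x_i ∥ x_j so the cross product vanishes — always the case for a centered
two-atom molecule) yield a zero frame with a degeneracy flag so the
scalarized features are zeros, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LocalFrame:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    degenerate: bool = False

    def as_matrix(self) -> np.ndarray:
        """Rows are the frame axes (3, 3)."""
        return np.stack([self.a, self.b, self.c])


def build_frames(xi: np.ndarray, xj: np.ndarray,
                 eps_guard: float = 1e-8) -> LocalFrame:
    """Local frame of one directed edge; inputs must be CoM-centered."""
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise ValueError("non-finite coordinates")
    d = xi - xj
    nd = np.linalg.norm(d)
    cr = np.cross(xi, xj)
    ncr = np.linalg.norm(cr)
    if nd < eps_guard or ncr < eps_guard:
        z = np.zeros(3)
        a = d / nd if nd >= eps_guard else z
        return LocalFrame(a=a, b=z.copy(), c=z.copy(), degenerate=True)
    a = d / nd
    b = cr / ncr
    c = np.cross(a, b)
    return LocalFrame(a=a, b=b, c=c)


def frames_for_edges(coords: np.ndarray, edges: np.ndarray,
                     eps_guard: float = 1e-8):
    """Vectorized frames for all directed edges.

    Returns ``F`` of shape (E, 3, 3) with rows (a, b, c) per edge and a
    boolean degeneracy mask; degenerate rows of b and c are zeroed.
    """
    xi = coords[edges[:, 0]]
    xj = coords[edges[:, 1]]
    d = xi - xj
    nd = np.linalg.norm(d, axis=1)
    cr = np.cross(xi, xj)
    ncr = np.linalg.norm(cr, axis=1)
    bad_a = nd < eps_guard
    bad_b = ncr < eps_guard
    a = np.where(bad_a[:, None], 0.0, d / np.where(bad_a, 1.0, nd)[:, None])
    b = np.where(bad_b[:, None], 0.0, cr / np.where(bad_b, 1.0, ncr)[:, None])
    c = np.cross(a, b)
    F = np.stack([a, b, c], axis=1)
    return F, (bad_a | bad_b)


def scalarize(vectors: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Project k vectors onto the frame axes → 3k rotation-invariant reals."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    return (vectors @ frame.as_matrix().T).reshape(-1)


def vectorize_positions(zx: np.ndarray) -> np.ndarray:
    """Initial equivariant node vector channels from noisy coordinates.

    Each node gets its position-from-CoM vector (per-edge displacement
    vectors are carried by the graph's edge channels).  Input must be
    centered.
    """
    zx = np.asarray(zx, dtype=np.float64)
    if np.abs(zx.mean(axis=0)).max() > 1e-8:
        raise ValueError("coordinates must be CoM-centered")
    return zx[:, None, :].copy()
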