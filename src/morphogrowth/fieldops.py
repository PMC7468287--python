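"""Low-level vector-field numerics shared across modules.

Everything here works in physical millimetres on the package's standard
grid convention (``position = origin + index * spacing``).  Interpolation
is trilinear via :func:`scipy.ndimage.map_coordinates`; displacement
fields are extended by their edge values outside the lattice so that
compositions near the boundary stay finite and smooth.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "sample_scalar",
    "sample_vectors",
    "compose_displacements",
    "exp_velocity",
    "invert_displacement",
    "jacobian_det_array",
]


def _to_index(points: np.ndarray, spacing, origin) -> np.ndarray:
    """Physical (..., 3) points -> fractional index coordinates (3, N)."""
    idx = (points.reshape(-1, 3) - np.asarray(origin)) / np.asarray(spacing)
    return idx.T


def sample_scalar(values, spacing, origin, points, order=1, cval=0.0, mode="constant"):
    """Sample a scalar lattice at arbitrary physical points (trilinear by
    default).

    Note on boundary modes: plain ``constant`` snaps to the fill value
    immediately past the last lattice point (discontinuous exactly at
    lattice alignment), while ``grid-constant`` blends the edge cell
    toward the fill value (continuous, but it manufactures intensity
    ramps along the volume faces that leak spurious forces into
    registration).  Optimisation code must therefore either keep its
    sample points strictly inside the domain (the affine metric trims a
    border) or tolerate the boundary discontinuity.
    """
    coords = _to_index(np.asarray(points, dtype=float), spacing, origin)
    out = map_coordinates(np.asarray(values, dtype=float), coords, order=order,
                          mode=mode, cval=cval)
    return out.reshape(np.asarray(points).shape[:-1])


def sample_vectors(vectors, spacing, origin, points):
    """Sample a (nx, ny, nz, 3) vector lattice at physical points.

    Edge-extended (``mode='nearest'``) so repeated composition does not
    drag in artificial zeros from outside the domain.
    """
    pts = np.asarray(points, dtype=float)
    coords = _to_index(pts, spacing, origin)
    out = np.empty((coords.shape[1], 3))
    for c in range(3):
        out[:, c] = map_coordinates(vectors[..., c], coords, order=1, mode="nearest")
    return out.reshape(pts.shape)


def compose_displacements(u_outer, u_inner, spacing, origin, points=None):
    """Displacement of the composition ``(id + u_outer) o (id + u_inner)``.

    ``result(x) = u_inner(x) + u_outer(x + u_inner(x))`` on the lattice.
    """
    if points is None:
        axes = [origin[d] + spacing[d] * np.arange(u_inner.shape[d]) for d in range(3)]
        points = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    inner_pts = points + u_inner
    return u_inner + sample_vectors(u_outer, spacing, origin, inner_pts)


def exp_velocity(velocity, spacing, origin, min_squarings: int = 6):
    """Exponentiate a stationary velocity field by scaling and squaring.

    The number of squarings is at least ``min_squarings`` and large enough
    that the initial scaled step is below a quarter of the smallest voxel
    size, which keeps every self-composition well inside the trilinear
    interpolation regime and the result diffeomorphic for smooth input.
    """
    v = np.asarray(velocity, dtype=float)
    vmax = float(np.sqrt((v**2).sum(axis=-1)).max())
    n = int(min_squarings)
    if vmax > 0:
        needed = int(np.ceil(np.log2(max(vmax / (0.25 * float(np.min(spacing))), 1.0))))
        n = max(n, needed)
    u = v / (2.0**n)
    axes = [origin[d] + spacing[d] * np.arange(v.shape[d]) for d in range(3)]
    points = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    for _ in range(n):
        u = compose_displacements(u, u, spacing, origin, points=points)
    return u


def invert_displacement(vectors, spacing, origin, n_iter: int = 30, tol: float = 1e-3):
    """Approximate inverse displacement by fixed-point iteration.

    Solves ``u_inv(x) = -u(x + u_inv(x))`` so that the composition
    ``(id + u) o (id + u_inv)`` is close to the identity.
    """
    axes = [origin[d] + spacing[d] * np.arange(vectors.shape[d]) for d in range(3)]
    points = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    u_inv = np.zeros_like(vectors)
    for _ in range(n_iter):
        new = -sample_vectors(vectors, spacing, origin, points + u_inv)
        delta = float(np.abs(new - u_inv).max())
        u_inv = new
        if delta < tol:
            break
    return u_inv


def jacobian_det_array(vectors, spacing):
    """det(I + du/dx) per voxel, derivatives by central finite differences
    in physical mm (one-sided at the boundary)."""
    vec = np.asarray(vectors, dtype=float)
    if any(s < 3 for s in vec.shape[:3]):
        from .errors import GridError

        raise GridError(f"need >= 3 voxels per axis for finite differences, got {vec.shape[:3]}")
    jac = np.empty(vec.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(vec[..., i], *spacing, axis=(0, 1, 2))
        for j in range(3):
            jac[..., i, j] = grads[j]
    jac += np.eye(3)
    return np.linalg.det(jac)
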