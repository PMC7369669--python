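"""Piecewise-linear (P1) finite-element assembly on triangle meshes.

Vectorized COO assembly of the standard Galerkin matrices used by both the
Stokes pre-solve and the oxygen transport solver:

* consistent mass and stiffness matrices,
* convection matrix for a nodal vector field in non-divergence form
  ``(v . grad u, w)``,
* Robin boundary mass ``int_Gamma c u w ds`` and boundary loads
  ``int_Gamma c u_b w ds`` with per-edge coefficients,

All interior integrals use quadrature exact for quadratics (analytic P1
formulas for mass/stiffness, the three edge-midpoint rule for convection);
boundary integrals use the exact 1D P1 formulas.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import Mesh

__all__ = [
    "tri_gradients",
    "mass_matrix",
    "stiffness_matrix",
    "convection_matrix",
    "directional_matrices",
    "boundary_mass_matrix",
    "boundary_load",
    "v_inner_matrix",
]


def tri_gradients(mesh: Mesh):
    """Areas (M,) and constant shape-function gradients (M, 3, 2)."""
    if "grads" in mesh._cache:
        return mesh._cache["areas"], mesh._cache["grads"]
    p = mesh.vertices[mesh.triangles]  # (M,3,2)
    areas = mesh.triangle_areas()
    # grad N_i = perp(edge opposite i) / (2A)
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    perp = np.stack([e0, e1, e2], axis=1)[:, :, ::-1] * np.array([-1.0, 1.0])
    grads = perp / (2.0 * areas)[:, None, None]
    mesh._cache["grads"] = grads
    return areas, grads


def _assemble(mesh: Mesh, elem: np.ndarray) -> sp.csr_matrix:
    """Assemble (M,3,3) element matrices into a CSR matrix."""
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    n = mesh.n_vertices
    return sp.coo_matrix((elem.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def mass_matrix(mesh: Mesh) -> sp.csr_matrix:
    areas = mesh.triangle_areas()
    base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    elem = areas[:, None, None] * base
    return _assemble(mesh, elem)


def stiffness_matrix(mesh: Mesh) -> sp.csr_matrix:
    areas, grads = tri_gradients(mesh)
    elem = areas[:, None, None] * np.einsum("mid,mjd->mij", grads, grads)
    return _assemble(mesh, elem)


def convection_matrix(mesh: Mesh, velocity: np.ndarray) -> sp.csr_matrix:
    """``C[i,j] = int (v . grad N_j) N_i dx`` for a P1 nodal field ``v``.

    Three edge-midpoint quadrature (exact: the integrand is quadratic).
    """
    velocity = np.asarray(velocity, dtype=float)
    if velocity.shape != (mesh.n_vertices, 2):
        raise ValueError("velocity must be a nodal (N, 2) array")
    areas, grads = tri_gradients(mesh)
    vt = velocity[mesh.triangles]  # (M,3,2)
    # midpoints of edges (01, 12, 20); N_i values there
    vq = 0.5 * (vt + np.roll(vt, -1, axis=1))  # (M,3,2) velocity at midpoints
    nq = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])  # (q,i)
    # s[m,q,j] = v(x_q) . grad N_j
    s = np.einsum("mqd,mjd->mqj", vq, grads)
    elem = (areas[:, None, None] / 3.0) * np.einsum("qi,mqj->mij", nq, s)
    return _assemble(mesh, elem)


def directional_matrices(mesh: Mesh):
    """``Cx[i,j] = int N_i dN_j/dx dx`` and the y analogue (exact)."""
    areas, grads = tri_gradients(mesh)
    out = []
    for d in (0, 1):
        # int N_i dx = A/3 for each i; dN_j/dd constant
        elem = (areas[:, None, None] / 3.0) * grads[:, None, :, d]
        out.append(_assemble(mesh, elem * np.ones((1, 3, 1))))
    return out[0], out[1]


def _edge_coef(mesh: Mesh, coef) -> np.ndarray:
    """Per-boundary-edge coefficient from a scalar, per-class dict, or array."""
    b = len(mesh.boundary_edges)
    if np.isscalar(coef):
        return np.full(b, float(coef))
    if isinstance(coef, dict):
        from .geometry import TAG_BY_CLASS
        out = np.zeros(b)
        for cls, val in coef.items():
            out[mesh.boundary_tags == TAG_BY_CLASS[cls]] = val
        return out
    coef = np.asarray(coef, dtype=float)
    if coef.shape != (b,):
        raise ValueError("per-edge coefficient has wrong length")
    return coef


def boundary_mass_matrix(mesh: Mesh, coef) -> sp.csr_matrix:
    """``int_Gamma c u w ds`` with ``c`` constant per boundary edge."""
    c = _edge_coef(mesh, coef)
    lens = mesh.boundary_lengths()
    w = c * lens
    e = mesh.boundary_edges
    base = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
    elem = w[:, None, None] * base
    rows = np.repeat(e, 2, axis=1).ravel()
    cols = np.tile(e, (1, 2)).ravel()
    n = mesh.n_vertices
    return sp.coo_matrix((elem.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def boundary_load(mesh: Mesh, coef, ambient) -> np.ndarray:
    """``F[i] = int_Gamma c u_b N_i ds``.

    ``ambient`` may be a scalar, a per-class dict of scalars, a per-class
    dict of callables ``f(x, y)``, or a nodal array; it is sampled at edge
    endpoints and integrated with the exact linear rule.
    """
    c = _edge_coef(mesh, coef)
    e = mesh.boundary_edges
    pts = mesh.vertices[e]  # (B,2,2)
    if callable(ambient):
        ub = ambient(pts[..., 0], pts[..., 1])
    elif isinstance(ambient, dict) and any(callable(v) for v in ambient.values()):
        from .geometry import TAG_BY_CLASS
        ub = np.zeros(e.shape)
        for cls, val in ambient.items():
            m = mesh.boundary_tags == TAG_BY_CLASS[cls]
            ub[m] = (val(pts[m, :, 0], pts[m, :, 1]) if callable(val)
                     else float(val))
    elif isinstance(ambient, dict):
        ub = _edge_coef(mesh, ambient)[:, None] * np.ones((1, 2))
    elif np.isscalar(ambient):
        ub = np.full(e.shape, float(ambient))
    else:
        ub = np.asarray(ambient, dtype=float)[e]
    lens = mesh.boundary_lengths()
    w = c * lens
    # int c (ub0 N0 + ub1 N1) N_i ds, exact for linear ub
    f0 = w * (ub[:, 0] / 3.0 + ub[:, 1] / 6.0)
    f1 = w * (ub[:, 0] / 6.0 + ub[:, 1] / 3.0)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, e[:, 0], f0)
    np.add.at(out, e[:, 1], f1)
    return out


def v_inner_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Discrete H^1 inner-product matrix ``(u, w) + (grad u, grad w)``."""
    return mass_matrix(mesh) + stiffness_matrix(mesh)
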