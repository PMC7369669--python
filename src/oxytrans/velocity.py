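"""Stokes pre-solve for the convective velocity field.

The transport model convects blood oxygen with a prescribed, continuous
velocity field.  Here that field is produced by a steady Stokes flow on the
perforated square: the outer edges carry a uniform drift (default
(0, 0.6) mm/s), inlet rims inject fluid at 3.4 mm/s and outlet rims drain at
1.7 mm/s, both normal to the rim.

With equal rim perimeters these Dirichlet data have a nonzero net boundary
flux, so the incompressible problem has no solution; a pressure-penalty
(slightly compressible) formulation ``div v + penalty * p = 0`` absorbs the
imbalance.  Discretization is equal-order P1/P1 velocity-pressure with
Brezzi-Pitkaranta pressure stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .geometry import Mesh, TAG_EDGE, TAG_INLET, TAG_OUTLET

__all__ = ["VelocityField", "solve_stokes", "speed_fraction", "SolverError"]


class SolverError(RuntimeError):
    pass


@dataclass
class VelocityField:
    """Nodal velocity vectors (mm/s) on the mesh's vertices."""

    mesh: Mesh
    values: np.ndarray  # (N, 2)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_vertices, 2):
            raise ValueError("velocity values must be (n_vertices, 2)")

    @property
    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=1)

    @classmethod
    def constant(cls, mesh: Mesh, vector) -> "VelocityField":
        v = np.tile(np.asarray(vector, dtype=float), (mesh.n_vertices, 1))
        return cls(mesh, v, metadata={"kind": "constant", "vector": list(vector)})

    @classmethod
    def zero(cls, mesh: Mesh) -> "VelocityField":
        return cls.constant(mesh, (0.0, 0.0))

    @classmethod
    def from_vtu(cls, mesh: Mesh, path, name: str = "velocity"
                 ) -> "VelocityField":
        """Load a nodal vector field written by :func:`oxytrans.io.write_vtu`,
        letting users bypass the Stokes stage with their own field."""
        from .io import read_vtu_point_data
        data = read_vtu_point_data(path)
        if name not in data:
            raise ValueError(f"{path} has no point field {name!r}")
        if (data["points"].shape[0] != mesh.n_vertices
                or not np.allclose(data["points"], mesh.vertices)):
            raise ValueError(f"{path}: points do not match the mesh")
        return cls(mesh, data[name], metadata={"kind": "file",
                                               "path": str(path)})


def _boundary_node_sets(mesh: Mesh):
    """Nodes of each boundary class; hole nodes mapped to their hole center."""
    sets = {}
    for tag in (TAG_EDGE, TAG_INLET, TAG_OUTLET):
        e = mesh.boundary_edges[mesh.boundary_tags == tag]
        sets[tag] = np.unique(e)
    return sets


def solve_stokes(m: Mesh, edge_velocity=(0.0, 0.6), inlet_speed: float = 3.4,
                 outlet_speed: float = 1.7, penalty: float = 1e-6,
                 stabilization: float = 0.05) -> VelocityField:
    """Solve the penalized Stokes system on the tagged mesh.

    Momentum ``-lap(v) + grad p = 0``; mass ``div v + penalty * p = 0``.
    Dirichlet data: ``v = edge_velocity`` on the outer square,
    ``v = -inlet_speed * n`` on inlet rims and ``v = +outlet_speed * n`` on
    outlet rims, with ``n`` the outward normal of the computational domain
    (pointing into the hole), so inlets inject and outlets drain.
    """
    if inlet_speed < 0 or outlet_speed < 0:
        raise ValueError("hole speeds must be >= 0")
    if penalty < 0 or stabilization < 0:
        raise ValueError("penalty and stabilization must be >= 0")
    n = m.n_vertices
    K = fem.stiffness_matrix(m)
    M = fem.mass_matrix(m)
    Cx, Cy = fem.directional_matrices(m)

    # Brezzi-Pitkaranta: sum_T c_stab * h_T^2 (grad p, grad q)_T
    areas, grads = fem.tri_gradients(m)
    hT2 = 2.0 * areas
    elem = (stabilization * hT2 * areas)[:, None, None] * np.einsum(
        "mid,mjd->mij", grads, grads)
    S = fem._assemble(m, elem)

    Z = sp.csr_matrix((n, n))
    A = sp.bmat([
        [K, Z, -Cx.T],
        [Z, K, -Cy.T],
        [-Cx, -Cy, -(penalty * M + S)],
    ], format="csr")
    rhs = np.zeros(3 * n)

    # Dirichlet velocity values
    vals = np.full((n, 2), np.nan)
    sets = _boundary_node_sets(m)
    vals[sets[TAG_EDGE]] = np.asarray(edge_velocity, dtype=float)
    if m.domain is not None:
        centers = np.array([[h.x, h.y] for h in m.domain.holes]) \
            if m.domain.holes else np.zeros((0, 2))
        kinds = [h.kind for h in m.domain.holes]
        for tag, sign, speed in ((TAG_INLET, -1.0, inlet_speed),
                                 (TAG_OUTLET, +1.0, outlet_speed)):
            nodes = sets[tag]
            if len(nodes) == 0:
                continue
            pts = m.vertices[nodes]
            d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
            own = d.argmin(axis=1)
            nrm = centers[own] - pts  # outward normal: toward hole center
            nrm /= np.linalg.norm(nrm, axis=1)[:, None]
            for k, node in enumerate(nodes):
                if kinds[own[k]] not in ("inlet", "outlet"):
                    raise SolverError("unclassified hole")
            vals[nodes] = sign * speed * nrm
    elif (len(sets[TAG_INLET]) or len(sets[TAG_OUTLET])):
        raise SolverError("mesh has hole tags but no domain metadata")

    fixed = ~np.isnan(vals[:, 0])
    known = np.concatenate([fixed, fixed, np.zeros(n, dtype=bool)])
    xk = np.zeros(3 * n)
    xk[:n][fixed] = vals[fixed, 0]
    xk[n:2 * n][fixed] = vals[fixed, 1]

    free = ~known
    rhs_red = rhs[free] - A[:, known][free] @ xk[known]
    A_red = A[free][:, free].tocsc()
    try:
        sol_free = spla.spsolve(A_red, rhs_red)
    except Exception as exc:  # pragma: no cover
        raise SolverError(
            "Stokes solve failed; with incompatible boundary fluxes try a "
            "larger pressure penalty") from exc
    if not np.all(np.isfinite(sol_free)):
        raise SolverError(
            "singular Stokes system (incompatible flux data with penalty=0?); "
            "raise the pressure penalty")
    x = xk.copy()
    x[free] = sol_free
    values = np.column_stack([x[:n], x[n:2 * n]])
    meta = {
        "elements": "P1/P1 + Brezzi-Pitkaranta",
        "penalty": penalty,
        "stabilization": stabilization,
        "bc": {"edge_velocity": list(np.asarray(edge_velocity, float)),
               "inlet_speed": inlet_speed, "outlet_speed": outlet_speed},
        "pressure_range": [float(x[2 * n:].min()), float(x[2 * n:].max())],
    }
    return VelocityField(mesh=m, values=values, metadata=meta)


def speed_fraction(v: VelocityField, lo: float, hi: float) -> float:
    """Area fraction of the domain where ``lo <= |v| <= hi`` (mm/s).

    Element-midpoint quadrature: the field is interpolated linearly to each
    triangle centroid.
    """
    if not lo < hi:
        raise ValueError("speed_fraction requires lo < hi")
    areas = v.mesh.triangle_areas()
    vc = v.values[v.mesh.triangles].mean(axis=1)
    s = np.linalg.norm(vc, axis=1)
    mask = (s >= lo) & (s <= hi)
    return float(areas[mask].sum() / areas.sum())
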