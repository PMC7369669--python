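"""Quantitative post-processing and runtime verification of the solver.

Two kinds of diagnostics live here:

* descriptive: stabilization times of the blood and tissue fields, total
  oxygen content, and the physiological back-of-envelope estimates (mean
  inlet-outlet separation, diffusion time);
* verificative: the a-priori energy estimate and the uniqueness (Gronwall
  contraction) estimate of the continuous model, turned into per-step
  inequality checks on the discrete solution.  The constants involved
  (coercivity constants ``k1``, ``k2`` of the elliptic operators, the energy
  constants ``C1``, ``C2`` and the contraction rate ``C3``) are computed
  from the assembled matrices, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

__all__ = [
    "SimulationResult",
    "AprioriConstants",
    "stabilization_time",
    "coercivity_constants",
    "dual_norm",
    "apriori_constants",
    "energy_bound_check",
    "gronwall_difference_check",
    "mean_inlet_separation",
    "diffusion_time",
    "total_oxygen",
]


@dataclass
class SimulationResult:
    """Time series of states plus per-step diagnostic records."""

    mesh: object
    times: np.ndarray
    states: list
    records: list
    ops: object = None
    params: object = None
    bc: object = None
    velocity: object = None
    table: object = None
    config: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.records) != len(self.states):
            raise ValueError("record count must equal state count")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if dts.min() <= 0:
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-8):
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 \
            else 0.0

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def summary(self, eps: float = 0.01) -> dict:
        out = {
            "t_final": float(self.times[-1]),
            "dt": self.dt,
            "n_steps": len(self.times) - 1,
            "stabilization_time_phi": stabilization_time(self, "phi", eps),
            "stabilization_time_theta": stabilization_time(self, "theta", eps),
            "stabilization_eps": eps,
            "stabilization_criterion":
                "L2 step increment per unit time, relative to final-state "
                "L2 norm, below eps from t* onward",
            "final_picard_residual": self.records[-1]["picard_residual"],
            "min_theta_over_run": min(r["min_theta"] for r in self.records),
            "min_phi_over_run": min(r["min_phi"] for r in self.records),
        }
        if self.config is not None:
            out["config"] = self.config.to_dict()
        return out


@dataclass(frozen=True)
class AprioriConstants:
    """Constants of the energy and contraction estimates.

    ``k1``, ``k2``: coercivity constants of the elliptic operators in the
    discrete H1 norm; ``C1`` (mM^2 mm^2) collects initial energy and
    time-integrated dual norms of the Robin loads; ``C2`` (1/s) the energy
    growth rate; ``C3`` (1/s) the contraction rate of the uniqueness bound.
    """

    k1: float
    k2: float
    C1: float
    C2: float
    C3: float


def stabilization_time(r: SimulationResult, fld: str, eps: float = 0.01):
    """Smallest stored time after which the field stops changing.

    Criterion: for every later step,
    ``||u(t+dt) - u(t)||_L2 / (dt * ||u(T)||_L2) <= eps`` (units 1/s).
    Returns ``inf`` if the tail never settles, 0.0 for a constant series.
    """
    if fld not in ("phi", "theta"):
        raise ValueError("field must be 'phi' or 'theta'")
    if len(r.states) < 2:
        raise ValueError("need at least two states")
    M = r.ops.M
    dt = r.dt
    u = [getattr(s, fld) for s in r.states]
    un = u[-1]
    ref = float(np.sqrt(un @ (M @ un)))
    if ref == 0:
        ref = 1.0
    rates = np.array([
        np.sqrt((u[i + 1] - u[i]) @ (M @ (u[i + 1] - u[i]))) / (dt * ref)
        for i in range(len(u) - 1)])
    bad = np.nonzero(rates > eps)[0]
    if len(bad) == 0:
        return 0.0
    if bad[-1] == len(rates) - 1:
        return float("inf")
    return float(r.times[bad[-1] + 1])


def coercivity_constants(ops, m=None):
    """Coercivity constants ``k1``, ``k2``: smallest generalized eigenvalues
    of ``A1`` and ``A2`` against the discrete H1 matrix ``Mv = M + K``."""
    out = []
    for A in (ops.A1, ops.A2):
        try:
            # tiny negative shift keeps the shift-inverted matrix invertible
            # even in the degenerate no-flux case (A singular, k = 0)
            vals = spla.eigsh(A.tocsc(), k=1, M=ops.Mv.tocsc(), sigma=-1e-10,
                              which="LM", return_eigenvectors=False)
        except spla.ArpackNoConvergence as exc:  # pragma: no cover
            raise RuntimeError("coercivity eigensolver failed") from exc
        out.append(max(float(vals[0]), 0.0))
    return tuple(out)


def dual_norm(load: np.ndarray, ops) -> float:
    """Dual (H1)' norm of a linear functional given in vector form.

    Riesz representation: solve ``Mv z = load`` and return
    ``sqrt(load . z) = ||z||_V``.
    """
    load = np.asarray(load, dtype=float)
    z = spla.spsolve(ops.Mv.tocsc(), load)
    return float(np.sqrt(max(load @ z, 0.0)))


def apriori_constants(p, bc, ops, v, phi0, theta0, T) -> AprioriConstants:
    """Assemble the constants of the energy and contraction estimates.

    ``C1 = ||phi0||^2 + ||theta0||^2 + T*((2/k1)||f1||_*^2 + (1/k2)||f2||_*^2)``
    (the loads are time-constant here, so the time integral is T times the
    value), ``C2 = (2/k1)||v||_inf^2 + a(1+kappa)``,
    ``C3 = (1/(4 k1))||v||_inf^2 + a/2``.  The velocity sup norm is the max
    nodal speed (P1 fields attain extrema at nodes).
    """
    k1, k2 = coercivity_constants(ops)
    M = ops.M
    phi0 = np.asarray(phi0, float) * np.ones(M.shape[0]) \
        if np.isscalar(phi0) else np.asarray(phi0, float)
    theta0 = np.asarray(theta0, float) * np.ones(M.shape[0]) \
        if np.isscalar(theta0) else np.asarray(theta0, float)
    vmax = 0.0 if v is None else float(np.linalg.norm(v.values, axis=1).max())
    # vanishing loads / velocity contribute zero even when a coercivity
    # constant degenerates to zero (closed, no-flux configuration)
    df1 = dual_norm(ops.f1, ops) ** 2
    df2 = dual_norm(ops.f2, ops) ** 2
    C1 = (float(phi0 @ (M @ phi0)) + float(theta0 @ (M @ theta0))
          + T * ((2.0 / k1) * df1 if df1 > 0 else 0.0)
          + T * ((1.0 / k2) * df2 if df2 > 0 else 0.0))
    C2 = ((2.0 / k1) * vmax ** 2 if vmax > 0 else 0.0) \
        + p.a * (1.0 + p.kappa)
    C3 = ((1.0 / (4.0 * k1)) * vmax ** 2 if vmax > 0 else 0.0) + p.a / 2.0
    return AprioriConstants(k1=k1, k2=k2, C1=C1, C2=C2, C3=C3)


def energy_bound_check(r: SimulationResult, c: AprioriConstants) -> np.ndarray:
    """Per-step margins of the discrete energy inequality.

    At each stored time ``t``::

        ||phi(t)||^2 + ||theta(t)||^2
          + int_0^t (k1 ||phi||_V^2 + k2 ||theta||_V^2) ds
        <= C1 + C2 int_0^t (||phi||^2 + ||theta||^2) ds

    Time integrals use the trapezoid rule; margins (left minus right) must
    all be <= 0.
    """
    rec = r.records_frame()
    l2sq = rec["l2_phi"].to_numpy() ** 2 + rec["l2_theta"].to_numpy() ** 2
    vsq = (c.k1 * rec["v_phi"].to_numpy() ** 2
           + c.k2 * rec["v_theta"].to_numpy() ** 2)
    t = r.times
    int_v = _cumtrapz(vsq, t)
    int_l2 = _cumtrapz(l2sq, t)
    lhs = l2sq + int_v
    rhs = c.C1 + c.C2 * int_l2
    return lhs - rhs


def gronwall_difference_check(rA: SimulationResult, rB: SimulationResult,
                              c: AprioriConstants) -> np.ndarray:
    """Margins of the uniqueness (contraction) estimate for two runs.

    The runs must share mesh and configuration except for initial data.
    Checks ``||dphi(t)||^2 + ||dtheta(t)||^2 <= D0 * exp(2 (C3 + kappa a / 2) t)``
    with ``D0`` the initial squared difference; returns per-step margins
    (left minus right, <= 0 when the bound holds).
    """
    if rA.mesh is not rB.mesh and rA.mesh.n_vertices != rB.mesh.n_vertices:
        raise ValueError("runs live on different meshes")
    if len(rA.times) != len(rB.times) or not np.allclose(rA.times, rB.times):
        raise ValueError("runs have different time grids")
    M = rA.ops.M
    p = rA.params
    dsq = np.array([
        (a.phi - b.phi) @ (M @ (a.phi - b.phi))
        + (a.theta - b.theta) @ (M @ (a.theta - b.theta))
        for a, b in zip(rA.states, rB.states)])
    rate = 2.0 * (c.C3 + p.kappa * p.a / 2.0)
    if dsq[0] == 0.0:
        return dsq.copy()  # identical initial data: the bound is zero
    with np.errstate(over="ignore"):  # huge rate -> bound saturates at inf
        bound = dsq[0] * np.exp(rate * rA.times)
    return dsq - bound


def mean_inlet_separation(N: float = 76.8e6, m: float = 1200.0,
                          rho: float = 1.04) -> float:
    """Mean inlet-outlet separation ``(m / (rho N))**(1/3)`` in mm.

    ``N``: number of arteriolar inlets / venular outlets in the organ,
    ``m``: organ mass in g, ``rho``: density in g/cm^3.  Each junction is
    assigned a cube of tissue of volume ``m/(rho N)``; its side is the
    separation estimate (converted cm -> mm).
    """
    if N <= 0 or m <= 0 or rho <= 0:
        raise ValueError("all arguments must be > 0")
    return 10.0 * (m / (rho * N)) ** (1.0 / 3.0)


def diffusion_time(L: float = 0.02, D: float = 0.0024,
                   c: float = 1.0) -> float:
    """Diffusive travel time ``L**2 / (c D)`` in s over distance L (mm).

    The dimensionless constant ``c`` encodes the convention for the mean
    first-passage geometry (1 for the plain scaling estimate).
    """
    return L ** 2 / (c * D)


def total_oxygen(s, mesh_or_ops, sigma: float) -> float:
    """Volume-fraction-weighted oxygen content ``int sigma phi + (1-sigma) theta``
    (mM mm^2) by mass-matrix quadrature."""
    ops = mesh_or_ops
    if hasattr(ops, "M"):
        M = ops.M
    else:
        from . import fem
        M = fem.mass_matrix(ops)
    one = np.ones_like(s.phi)
    return float(one @ (M @ (sigma * s.phi + (1.0 - sigma) * s.theta)))


def _cumtrapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    if len(t) > 1:
        out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))
    return out
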