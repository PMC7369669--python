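"""Independent reference computations validating the transport solver.

Two oracles, both deliberately bypassing the discretization under test:

* :func:`ode_reduction` — the spatially homogeneous limit of the model
  (drop all gradients): ``phi' = a (theta - g(phi))``,
  ``theta' = -mu(theta) - kappa a (theta - g(phi))``, integrated with a
  high-accuracy adaptive implicit scheme where ``g`` is evaluated by
  bracketed root solving on every call — no spline table involved.

* :func:`mms_run` — a method-of-manufactured-solutions harness.  The
  *plasma* field ``psi_e(x, y, t)`` is manufactured symbolically and the
  blood field defined as ``phi_e = f(psi_e)``, so ``g(phi_e) = psi_e``
  exactly and all sources, Robin ambient data and initial states come from
  sympy differentiation in closed form.  The harness runs the production
  solver on a refinement ladder and reports L2 errors, from which the
  expected first-order-in-time / second-order-in-space convergence can be
  fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy as sym
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import kinetics, transport
from .geometry import build_domain, triangulate
from .kinetics import ModelParameters
from .velocity import VelocityField

__all__ = ["ODETrajectory", "ode_reduction", "mms_run", "fit_rate"]


@dataclass
class ODETrajectory:
    times: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    rtol: float
    atol: float


def _g_root(phi: float, p: ModelParameters) -> float:
    """Inverse Hill by per-call bracketed root solve (odd extension)."""
    if phi == 0.0:
        return 0.0
    s, x = np.sign(phi), abs(phi)
    return s * brentq(lambda v: kinetics.hill_forward(v, p) - x, 0.0, x,
                      xtol=1e-14, rtol=8.9e-16)


def ode_reduction(p: ModelParameters, phi0: float, theta0: float, T: float,
                  n_out: int = 201, rtol: float = 1e-10,
                  atol: float = 1e-12) -> ODETrajectory:
    """Integrate the spatially uniform (closed, well-mixed) reduction."""
    if T <= 0:
        raise ValueError("T must be > 0")

    def rhs(_t, y):
        phi, theta = y
        ex = p.a * (theta - _g_root(phi, p))
        return [ex, -kinetics.mm_rate(theta, p) - p.kappa * ex]

    t_eval = np.linspace(0.0, T, n_out)
    sol = solve_ivp(rhs, (0.0, T), [phi0, theta0], method="Radau",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integrator failed: {sol.message}")
    return ODETrajectory(times=sol.t, phi=sol.y[0], theta=sol.y[1],
                         rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# manufactured solutions

_X, _Y, _T = sym.symbols("x y t", real=True)


def _canonical(expr):
    """Rebind any free symbols named x, y, t to the module's symbols, so
    callers may build expressions with their own ``sympy.symbols``."""
    table = {"x": _X, "y": _Y, "t": _T}
    sub = {s: table[s.name] for s in expr.free_symbols if s.name in table}
    unknown = [s for s in expr.free_symbols if s.name not in table]
    if unknown:
        raise ValueError(f"manufactured field has unknown symbols {unknown}")
    return expr.subs(sub)


def _side_of_edge(mid, side, tol):
    if abs(mid[0]) < tol:
        return "xlo"
    if abs(mid[0] - side) < tol:
        return "xhi"
    if abs(mid[1]) < tol:
        return "ylo"
    return "yhi"


_NORMALS = {"xlo": (-1, 0), "xhi": (1, 0), "ylo": (0, -1), "yhi": (0, 1)}


def _robin_ambient(expr, diffusivity, robin_coef):
    """Per-side sympy expressions of the Robin ambient value
    ``u_b = u + (D/c) dn(u)``."""
    out = {}
    for sd, (nx, ny) in _NORMALS.items():
        dn = nx * sym.diff(expr, _X) + ny * sym.diff(expr, _Y)
        out[sd] = expr + diffusivity / robin_coef * dn
    return out


def mms_run(psi_exact, theta_exact, p: ModelParameters, *,
            side: float = 1.0, velocity=(0.3, 0.2),
            levels=((8, 0.02), (16, 0.005), (32, 0.00125)),
            T: float = 0.08, gamma: float = 1.0, delta: float = 1.0,
            n_picard: int = 8) -> pd.DataFrame:
    """Run the solver against a manufactured solution on a plain square.

    ``psi_exact`` and ``theta_exact`` are sympy expressions in ``x, y, t``
    (``psi_exact`` must stay positive so that ``phi_e = f(psi_e)`` lies on
    the principal Hill branch).  ``levels`` is a ladder of
    ``(n_edge_segments, dt)`` pairs; the returned frame has one row per
    level with columns ``h``, ``dt``, ``err_phi``, ``err_theta``.
    """
    psi_e = _canonical(sym.sympify(psi_exact))
    theta_e = _canonical(sym.sympify(theta_exact))
    phi_e = psi_e + p.b * psi_e ** p.r / (psi_e ** p.r + p.c)
    vx, vy = float(velocity[0]), float(velocity[1])

    def lap(u):
        return sym.diff(u, _X, 2) + sym.diff(u, _Y, 2)

    mu_e = p.mu0 * theta_e / (theta_e + p.theta50)
    exch = p.a * (theta_e - psi_e)
    s_phi = (sym.diff(phi_e, _T) - p.alpha * lap(phi_e)
             + vx * sym.diff(phi_e, _X) + vy * sym.diff(phi_e, _Y) - exch)
    s_theta = (sym.diff(theta_e, _T) - p.beta * lap(theta_e)
               + p.kappa * exch + mu_e)

    lam = lambda e: sym.lambdify((_X, _Y, _T), e, "numpy")
    f_phi, f_theta = lam(phi_e), lam(theta_e)
    f_sphi, f_stheta = lam(s_phi), lam(s_theta)
    amb_phi = {k: lam(v) for k, v in
               _robin_ambient(phi_e, p.alpha, gamma).items()}
    amb_theta = {k: lam(v) for k, v in
                 _robin_ambient(theta_e, p.beta, delta).items()}

    tbl = kinetics.build_inverse_hill(p)
    rows = []
    for n_seg, dt in levels:
        mesh = triangulate(build_domain(side, 0, 0), n_seg, 8)
        vel = VelocityField.constant(mesh, (vx, vy))
        bc = transport.BoundaryData(
            gamma={c: gamma for c in transport.CLASSES},
            delta={c: delta for c in transport.CLASSES},
            phi_b={c: 0.0 for c in transport.CLASSES},
            theta_b={c: 0.0 for c in transport.CLASSES})
        ops = transport.assemble(mesh, p, bc, vel, tbl)

        sides = [_side_of_edge(mid, side, 1e-9 * side)
                 for mid in mesh.vertices[mesh.boundary_edges].mean(axis=1)]

        def loads(t):
            f1 = _mms_boundary_load(mesh, sides, gamma, amb_phi, t)
            f2 = _mms_boundary_load(mesh, sides, delta, amb_theta, t)
            return f1, f2

        xn, yn = mesh.vertices[:, 0], mesh.vertices[:, 1]
        state = transport.StateFields(
            time=0.0, phi=np.broadcast_to(f_phi(xn, yn, 0.0), xn.shape).copy(),
            theta=np.broadcast_to(f_theta(xn, yn, 0.0), xn.shape).copy(),
            table=tbl)
        n_steps = int(round(T / dt))
        for k in range(n_steps):
            t_new = (k + 1) * dt
            ops.f1, ops.f2 = loads(t_new)
            state = transport.advance(
                state, ops, tbl, p, dt, n_picard,
                sources=(np.broadcast_to(f_sphi(xn, yn, t_new),
                                         xn.shape).copy(),
                         np.broadcast_to(f_stheta(xn, yn, t_new),
                                         xn.shape).copy()))
        M = ops.M
        ephi = state.phi - f_phi(xn, yn, state.time)
        etheta = state.theta - f_theta(xn, yn, state.time)
        rows.append({"n": n_seg, "h": side / n_seg, "dt": dt,
                     "err_phi": float(np.sqrt(ephi @ (M @ ephi))),
                     "err_theta": float(np.sqrt(etheta @ (M @ etheta)))})
    return pd.DataFrame(rows)


def _mms_boundary_load(mesh, sides, coef, ambient_by_side, t):
    e = mesh.boundary_edges
    pts = mesh.vertices[e]
    ub = np.empty(e.shape)
    for i, sd in enumerate(sides):
        fn = ambient_by_side[sd]
        ub[i] = fn(pts[i, :, 0], pts[i, :, 1], t)
    lens = mesh.boundary_lengths()
    w = coef * lens
    f0 = w * (ub[:, 0] / 3.0 + ub[:, 1] / 6.0)
    f1 = w * (ub[:, 0] / 6.0 + ub[:, 1] / 3.0)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, e[:, 0], f0)
    np.add.at(out, e[:, 1], f1)
    return out


def fit_rate(hs, errs) -> float:
    """Least-squares slope of log(err) against log(h)."""
    hs = np.asarray(hs, float)
    errs = np.asarray(errs, float)
    return float(np.polyfit(np.log(hs), np.log(errs), 1)[0])
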