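"""Forward mechanical model: 2D incompressible viscous flow with substrate
friction, driven by regularized forces and sinks.

The neuroectoderm is modelled as an infinite two-dimensional incompressible
viscous fluid (viscosity µ, normalized to 1) experiencing linear friction
against the overlying enveloping layer (EVL).  The momentum balance is the
Brinkman (screened Stokes) equation

    µ ∇²u − γ² u = ∇p − f,        ∇·u = s,

where ``f`` is a superposition of point forces smeared over finite extents
by an isotropic Gaussian kernel of standard deviation ``extent`` (total
weight 1), and ``s`` is the (negative) source density of Gaussian-regularized
sinks representing out-of-plane internalisation.  The friction term screens
the logarithmic divergence of the 2D Stokeslet (the Stokes paradox), so the
flow decays at infinity for any γ² > 0.

Closed forms
------------
For a point force ``F`` the solution is the screened Stokeslet

    u_i = (F_j / 2πµ) [ A(γr) δ_ij + B(γr) r̂_i r̂_j ],
    A(s) = K₀(s) + K₁(s)/s − 1/s²,
    B(s) = 2/s² − 2K₁(s)/s − K₀(s),

with K₀, K₁ modified Bessel functions.  The Gaussian-regularized force
response is obtained from the stream-function scalar φ with
(∇² − γ²) φ = −Π, ∇²Π = g: the smoothed-log (potential) part of φ is known
in closed form and the exponentially screened remainder is evaluated by
Hankel-transform quadrature, tabulated on a dimensionless (γr, γa) grid.

A Gaussian-regularized sink is radial potential flow, unaffected by the
friction term (its momentum residual is a pure gradient absorbed by the
pressure):

    u_r(r) = −(Q / 2πr) (1 − exp(−r² / 2a²)).
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import brentq
from scipy.special import j0, j1, k0, k1

from .fields import GridSpec, VelocityField
from .singularities import (ForceSingularity, SingularityConfig,
                            SinkSingularity)

__all__ = [
    "force_flow", "sink_flow", "evaluate_model", "pde_oracle",
    "screened_stokeslet_AB", "sink_peak_speed",
]


# --------------------------------------------------------------------------
# point (unregularized) screened Stokeslet
# --------------------------------------------------------------------------

def screened_stokeslet_AB(s):
    """Radial coefficient functions of the point screened Stokeslet.

    ``u_i = (F_j/2πµ)[A δ_ij + B r̂_i r̂_j]`` with ``s = γ r``.  Used for
    far-field evaluation and as the Stokes-limit reference in tests.
    """
    s = np.asarray(s, dtype=float)
    A = k0(s) + k1(s) / s - 1.0 / s ** 2
    B = 2.0 / s ** 2 - 2.0 * k1(s) / s - k0(s)
    return A, B


# --------------------------------------------------------------------------
# dimensionless kernel table for the Gaussian-regularized force
# --------------------------------------------------------------------------

_S_MIN, _S_MAX, _N_S = 1e-4, 400.0, 280
_EPS_MIN, _EPS_MAX, _N_EPS = 0.06, 30.0, 40


def _far_P1P2(s, eps):
    """Hybrid closed form valid beyond the quadrature window.

    The potential (smoothed-log) part is exact; the screened part uses the
    point Bessel form, whose smearing correction is negligible there.
    """
    E = np.exp(-0.5 * (s / eps) ** 2)
    P1 = (1.0 - E) / (2 * np.pi * s) - k1(s) / (2 * np.pi)
    P2 = (-(1.0 - E) / s ** 2 + E / eps ** 2
          + k0(s) + k1(s) / s) / (2 * np.pi)
    return P1, P2


def _quad_P1P2(s, eps):
    """P1 = γφ', P2 = φ'' for the regularized force, by split quadrature.

    Exact smoothed-log part plus Gauss–Legendre quadrature of the screened
    Hankel integrals (smooth, Gaussian-cut integrands).
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    kappa_max = max(5.0 / eps, 6.0)
    osc = kappa_max * s.max() / (2 * np.pi)
    n_nodes = int(min(5000, max(800, 8 * osc)))
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    kap = 0.5 * kappa_max * (nodes + 1.0)
    wts = wts * 0.5 * kappa_max
    gh = np.exp(-0.5 * (kap * eps) ** 2)
    base1 = gh * kap ** 2 / (kap ** 2 + 1.0)
    base2 = gh * kap ** 3 / (kap ** 2 + 1.0)
    ks = np.outer(s, kap)
    J1 = j1(ks)
    J0 = j0(ks)
    with np.errstate(invalid="ignore"):
        J1_over = np.where(ks > 0, J1 / np.where(ks > 0, ks, 1.0), 0.5)
    E = np.exp(-0.5 * (s / eps) ** 2)
    P1 = (1.0 - E) / (2 * np.pi * s) - (J1 * base1) @ wts / (2 * np.pi)
    P2 = (-(1.0 - E) / (2 * np.pi * s ** 2) + E / (2 * np.pi * eps ** 2)
          - ((J0 - J1_over) * base2) @ wts / (2 * np.pi))
    return P1, P2


@lru_cache(maxsize=1)
def _kernel_table():
    """Bivariate splines of P1, P2 over (ln s, ln ε); built once per process."""
    s_grid = np.geomspace(_S_MIN, _S_MAX, _N_S)
    eps_grid = np.geomspace(_EPS_MIN, _EPS_MAX, _N_EPS)
    P1 = np.empty((_N_S, _N_EPS))
    P2 = np.empty((_N_S, _N_EPS))
    for j, eps in enumerate(eps_grid):
        s_q = min(max(12.0, 8.0 * eps), _S_MAX)
        near = s_grid <= s_q
        P1[near, j], P2[near, j] = _quad_P1P2(s_grid[near], eps)
        if np.any(~near):
            P1[~near, j], P2[~near, j] = _far_P1P2(s_grid[~near], eps)
    spl1 = RectBivariateSpline(np.log(s_grid), np.log(eps_grid), P1)
    spl2 = RectBivariateSpline(np.log(s_grid), np.log(eps_grid), P2)
    return spl1, spl2, s_grid, eps_grid


def _reg_force_H(r, extent, gamma2):
    """H1, H2 with u = F H1 + (F·r̂) H2 r̂ for the regularized force."""
    gam = np.sqrt(gamma2)
    s = gam * np.asarray(r, dtype=float)
    eps = float(np.clip(gam * extent, _EPS_MIN, _EPS_MAX))
    spl1, spl2, s_grid, _ = _kernel_table()
    s_c = np.clip(s, _S_MIN, _S_MAX)
    ls = np.log(s_c)
    le = np.log(eps)
    P1 = spl1.ev(ls, le)
    P2 = spl2.ev(ls, le)
    # below the table: P2 is flat, P1 linear in s
    small = s < _S_MIN
    if np.any(small):
        P1[small] *= s[small] / _S_MIN
    # beyond the table: hybrid closed form
    big = s > _S_MAX
    if np.any(big):
        P1[big], P2[big] = _far_P1P2(s[big], eps)
    H1 = P2
    with np.errstate(invalid="ignore", divide="ignore"):
        H2 = np.where(s > 0, P1 / np.where(s > 0, s, 1.0) - P2, 0.0)
    return H1, H2


# --------------------------------------------------------------------------
# public flow evaluators
# --------------------------------------------------------------------------

def force_flow(force: ForceSingularity, gamma2: float,
               points: np.ndarray) -> np.ndarray:
    """Velocity at ``points`` (N, 2) due to one regularized force.

    Requires γ² > 0; the unscreened 2D Stokeslet has no bounded solution
    (Stokes paradox).  For Stokes-limit behaviour compare velocity
    *differences* of :func:`screened_stokeslet_AB` at small γ².
    """
    if gamma2 <= 0:
        raise ValueError(
            "gamma2 must be > 0 (Stokes paradox); for the gamma2 -> 0 limit "
            "use velocity differences of screened_stokeslet_AB")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if force.magnitude == 0:
        return np.zeros_like(points)
    d = points - force.position
    r = np.hypot(d[:, 0], d[:, 1])
    H1, H2 = _reg_force_H(r, force.extent, gamma2)
    with np.errstate(invalid="ignore"):
        rhat = np.where(r[:, None] > 0, d / np.where(r[:, None] > 0,
                                                     r[:, None], 1.0), 0.0)
    F = force.vector
    Fdot = rhat @ F
    u = (F[None, :] * H1[:, None] + (H2 * Fdot)[:, None] * rhat)
    return u


def sink_flow(sink: SinkSingularity, gamma2: float,
              points: np.ndarray) -> np.ndarray:
    """Velocity at ``points`` (N, 2) due to one regularized sink.

    Radial potential inflow; independent of γ² (the friction force on a
    potential flow is a gradient, absorbed by the pressure).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if sink.strength == 0:
        return np.zeros_like(points)
    d = points - sink.position
    r = np.hypot(d[:, 0], d[:, 1])
    a = sink.extent
    with np.errstate(invalid="ignore", divide="ignore"):
        # u_r / r, finite at r = 0 (limit −Q/(4π a²))
        ur_over_r = np.where(
            r > 1e-12,
            -sink.strength * (1.0 - np.exp(-0.5 * (r / a) ** 2))
            / (2 * np.pi * np.where(r > 1e-12, r, 1.0) ** 2),
            -sink.strength / (4 * np.pi * a ** 2))
    return ur_over_r[:, None] * d


@lru_cache(maxsize=1)
def _sink_peak_t() -> float:
    # maximize (1 - e^-t)/sqrt(t): root of 2 t e^-t = 1 - e^-t
    return brentq(lambda t: 2 * t * np.exp(-t) - (1 - np.exp(-t)), 0.1, 5.0)


def sink_peak_speed(sink: SinkSingularity) -> float:
    """Peak radial inflow speed of the regularized sink (u_sink).

    Attained at r ≈ 1.585·extent for the Gaussian kernel.
    """
    t = _sink_peak_t()
    r_star = sink.extent * np.sqrt(2 * t)
    return float(sink.strength * (1 - np.exp(-t)) / (2 * np.pi * r_star))


def velocity_at(config: SingularityConfig, points: np.ndarray) -> np.ndarray:
    """Superposed model velocity at arbitrary points (N, 2) -> (N, 2)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    u = np.zeros_like(points)
    g2 = config.gamma2 / config.viscosity
    for f in config.forces:
        u += force_flow(f, g2, points) / config.viscosity
    for s in config.sinks:
        u += sink_flow(s, g2, points)
    return u


def evaluate_model(config: SingularityConfig, grid: GridSpec,
                   time: float = float("nan")) -> VelocityField:
    """Evaluate the superposed singularity flow on a grid.

    Linear in all force magnitudes and sink strengths.  Singularities
    outside the grid trigger a warning, not an error.
    """
    for sing in (*config.forces, *config.sinks):
        px, py = sing.position
        if not (grid.x[0] <= px <= grid.x[-1] and
                grid.y[0] <= py <= grid.y[-1]):
            warnings.warn(
                f"singularity at ({px:.1f}, {py:.1f}) lies outside the grid",
                stacklevel=2)
    pts = grid.points()
    uv = velocity_at(config, pts)
    ny, nx = grid.shape
    return VelocityField(grid, uv[:, 0].reshape(ny, nx),
                         uv[:, 1].reshape(ny, nx), time=time)


# --------------------------------------------------------------------------
# independent finite-difference oracle (used in tests)
# --------------------------------------------------------------------------

def _poisson_dirichlet(rhs, h, bc, helmholtz=0.0):
    """Solve (∇² − c)φ = rhs on a square grid with Dirichlet boundary ``bc``.

    ``rhs`` and ``bc`` are full (n, n) arrays; only the boundary ring of
    ``bc`` is used.  5-point stencil, sparse direct solve.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    n = rhs.shape[0]
    m = n - 2
    main = -4.0 * np.ones(m)
    T = sp.diags([np.ones(m - 1), main, np.ones(m - 1)], [-1, 0, 1])
    I = sp.identity(m)
    L = (sp.kron(I, T) + sp.kron(sp.diags([np.ones(m - 1)], [1])
                                 + sp.diags([np.ones(m - 1)], [-1]), I))
    A = L / h ** 2 - helmholtz * sp.identity(m * m)
    b = rhs[1:-1, 1:-1].copy()
    # fold Dirichlet values into the RHS
    b[0, :] -= bc[0, 1:-1] / h ** 2
    b[-1, :] -= bc[-1, 1:-1] / h ** 2
    b[:, 0] -= bc[1:-1, 0] / h ** 2
    b[:, -1] -= bc[1:-1, -1] / h ** 2
    sol = spla.spsolve(A.tocsr(), b.ravel())
    out = bc.copy()
    out[1:-1, 1:-1] = sol.reshape(m, m)
    return out


def pde_oracle(config: SingularityConfig, domain: tuple[float, float],
               resolution: int = 192) -> VelocityField:
    """Direct numerical solution of the friction-Stokes system.

    Stream-function/vorticity formulation for the solenoidal (force-driven)
    part with far-field dipole boundary values, plus a potential solve for
    the sink part with monopole (net-flux) boundary values.  Independent of
    the closed-form/quadrature evaluators; intended for verification.

    Parameters
    ----------
    domain : (x_half_width, (y_min, y_max)) is not supported; pass
        ``(half_width_x, half_width_y)`` of a rectangle centred on the mean
        singularity position.  The grid is square ``resolution²``.
    """
    if resolution < 16:
        raise ValueError("resolution too small for the oracle")
    g2 = config.gamma2 / config.viscosity
    if g2 <= 0:
        raise ValueError("pde_oracle requires gamma2 > 0")
    all_pos = [s.position for s in (*config.forces, *config.sinks)]
    center = np.mean(all_pos, axis=0) if all_pos else np.zeros(2)
    hx, hy = domain
    if not np.isclose(hx, hy):
        raise ValueError("oracle domain must be square")
    n = resolution
    x = np.linspace(center[0] - hx, center[0] + hx, n)
    y = np.linspace(center[1] - hy, center[1] + hy, n)
    h = x[1] - x[0]
    X, Y = np.meshgrid(x, y)

    u = np.zeros((n, n))
    v = np.zeros((n, n))

    # --- solenoidal part: (∇²−γ²)ω = −curl f ; ∇²ψ = −ω -------------------
    if config.forces:
        curl_f = np.zeros((n, n))
        psi_bc = np.zeros((n, n))
        for f in config.forces:
            dx = X - f.position[0]
            dy = Y - f.position[1]
            a2 = f.extent ** 2
            g = np.exp(-(dx ** 2 + dy ** 2) / (2 * a2)) / (2 * np.pi * a2)
            Fx, Fy = f.vector / config.viscosity
            # curl of F g(r): Fy ∂g/∂x − Fx ∂g/∂y with ∂g/∂x = −x g / a²
            curl_f += (-Fy * dx + Fx * dy) * g / a2
            r2 = dx ** 2 + dy ** 2
            r2 = np.where(r2 > 1e-12, r2, 1e-12)
            psi_bc += (Fx * dy - Fy * dx) / (2 * np.pi * g2 * r2)
        omega = _poisson_dirichlet(-curl_f, h, np.zeros((n, n)),
                                   helmholtz=g2)
        psi = _poisson_dirichlet(-omega, h, psi_bc)
        u += np.gradient(psi, h, axis=0)          # ψ_y  (rows = y)
        v += -np.gradient(psi, h, axis=1)         # −ψ_x

    # --- potential part: ∇²φ = s, u += ∇φ ---------------------------------
    if config.sinks:
        s_src = np.zeros((n, n))
        total = 0.0
        centroid = np.zeros(2)
        for s in config.sinks:
            dx = X - s.position[0]
            dy = Y - s.position[1]
            a2 = s.extent ** 2
            g = np.exp(-(dx ** 2 + dy ** 2) / (2 * a2)) / (2 * np.pi * a2)
            s_src += -s.strength * g
            total += -s.strength
            centroid += s.strength * s.position
        centroid /= sum(s.strength for s in config.sinks) or 1.0
        rb = np.hypot(X - centroid[0], Y - centroid[1])
        phi_bc = (total / (2 * np.pi)) * np.log(np.where(rb > 1e-12, rb, 1.0))
        phi = _poisson_dirichlet(s_src, h, phi_bc)
        u += np.gradient(phi, h, axis=1)
        v += np.gradient(phi, h, axis=0)

    return VelocityField(GridSpec(x, y), u, v)
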