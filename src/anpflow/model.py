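"""Inverse mechanical model: fit regularized singularities to observed flows.

`SingularityFlowModel` is built from an observed :class:`VelocityField` and
a model specification (number of forces and sinks, parameter bounds); its
:meth:`fit` runs seeded multi-start bounded local optimization and returns
a :class:`SingularityFitResults` carrying the best-fitting
:class:`SingularityConfig`, its fit score, and near-tied alternate optima.
`fit_series` applies the fit per timepoint and assembles the normalized
sink-velocity (u_sink) and friction (γ²) trajectories.

The fit score is the relative root-mean-square residual

    score = ‖u_model − U_obs‖₂ / ‖U_obs‖₂

over masked grid points.  Because the flow is linear in the force vectors
and sink strengths, those enter as a linear least-squares subproblem solved
exactly at every evaluation (variable projection); the nonlinear search
runs only over positions, extents and the friction coefficient.  Sink
strengths are constrained non-negative; forces are parameterized by free
(Fx, Fy) components, so magnitudes are non-negative by construction.
Singularity positions are constrained to the midline (x = 0) by default,
matching the axial placement of the forces and the sink; off-axis fitting
is available via ``axis_constrained=False`` for sensitivity analysis.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .brinkman import force_flow, sink_flow, sink_peak_speed, velocity_at
from .fields import GridSpec, VelocityField
from .singularities import (ForceSingularity, SingularityConfig,
                            SinkSingularity)

__all__ = ["FitBounds", "SingularityFlowModel", "SingularityFitResults",
           "FitSeries", "fit_series", "objective"]


def objective(config: SingularityConfig, observed: VelocityField) -> float:
    """Relative RMS residual of a model config against an observed field."""
    m = observed.mask
    if not np.any(m):
        raise ValueError("observed field is entirely masked")
    pts = observed.grid.points()[m.ravel()]
    uv = velocity_at(config, pts)
    obs = np.column_stack([observed.u[m], observed.v[m]])
    denom = np.linalg.norm(obs)
    resid = np.linalg.norm(uv - obs)
    if denom == 0:
        return 0.0 if resid == 0 else float("inf")
    return float(resid / denom)


@dataclass(frozen=True)
class FitBounds:
    """Box bounds of the nonlinear fit parameters."""

    position_d: tuple[float, float] = (0.0, 250.0)   # µm along the axis
    extent: tuple[float, float] = (8.0, 60.0)        # µm
    log10_gamma2: tuple[float, float] = (-4.0, -1.0)  # log10(1/µm²)
    position_x: tuple[float, float] = (-100.0, 100.0)  # only if off-axis

    @classmethod
    def from_field(cls, fld: VelocityField) -> "FitBounds":
        return cls(position_d=(float(fld.y[0]), float(fld.y[-1])),
                   position_x=(float(fld.x[0]), float(fld.x[-1])))


class SingularityFlowModel:
    """Mechanical flow model to be fitted to one observed velocity field.

    Parameters
    ----------
    observed : the experimental (or synthetic) flow field U.
    n_forces, n_sinks : number of regularized forces and sinks.
    bounds : parameter box; defaults to the field's AP extent.
    axis_constrained : keep singularities on the midline x = 0 (default).
    """

    def __init__(self, observed: VelocityField, n_forces: int = 2,
                 n_sinks: int = 1, bounds: FitBounds | None = None,
                 axis_constrained: bool = True):
        if not np.any(observed.mask):
            raise ValueError("observed field is entirely masked")
        self.observed = observed
        self.n_forces = int(n_forces)
        self.n_sinks = int(n_sinks)
        self.bounds = bounds or FitBounds.from_field(observed)
        self.axis_constrained = bool(axis_constrained)
        m = observed.mask
        self._pts = observed.grid.points()[m.ravel()]
        self._b = np.concatenate([observed.u[m], observed.v[m]])
        self._bnorm = float(np.linalg.norm(self._b))

    # -- parameter vector layout ------------------------------------------
    # per force: (d, extent[, x]); per sink: (d, extent[, x]); then log10 γ².
    @property
    def _per_sing(self) -> int:
        return 2 if self.axis_constrained else 3

    @property
    def n_nonlinear(self) -> int:
        return self._per_sing * (self.n_forces + self.n_sinks) + 1

    def _theta_bounds(self) -> np.ndarray:
        b = []
        for _ in range(self.n_forces + self.n_sinks):
            b.append(self.bounds.position_d)
            b.append(self.bounds.extent)
            if not self.axis_constrained:
                b.append(self.bounds.position_x)
        b.append(self.bounds.log10_gamma2)
        return np.asarray(b, dtype=float)

    def _unpack(self, theta):
        ps = self._per_sing
        singes = []
        for i in range(self.n_forces + self.n_sinks):
            d = theta[ps * i]
            ext = theta[ps * i + 1]
            x0 = theta[ps * i + 2] if ps == 3 else 0.0
            singes.append((d, ext, x0))
        g2 = 10.0 ** theta[-1]
        return singes[:self.n_forces], singes[self.n_forces:], g2

    def _design(self, theta) -> np.ndarray:
        """Unit-response basis: 2 columns per force (Fx, Fy), 1 per sink."""
        from .brinkman import _reg_force_H

        forces, sinks, g2 = self._unpack(theta)
        n_pts = self._pts.shape[0]
        cols = []
        for d, ext, x0 in forces:
            dx = self._pts[:, 0] - x0
            dy = self._pts[:, 1] - d
            r = np.hypot(dx, dy)
            H1, H2 = _reg_force_H(r, ext, g2)
            with np.errstate(invalid="ignore"):
                safe = np.where(r > 0, r, 1.0)
                xh = np.where(r > 0, dx / safe, 0.0)
                yh = np.where(r > 0, dy / safe, 0.0)
            # unit +x force and unit +y force responses
            cols.append(np.concatenate([H1 + H2 * xh * xh, H2 * xh * yh]))
            cols.append(np.concatenate([H2 * xh * yh, H1 + H2 * yh * yh]))
        for d, ext, x0 in sinks:
            s = SinkSingularity(d, 1.0, ext, x0)
            uv = sink_flow(s, g2, self._pts)
            cols.append(np.concatenate([uv[:, 0], uv[:, 1]]))
        return np.column_stack(cols) if cols else np.zeros((2 * n_pts, 0))

    def _solve_linear(self, A):
        """Least squares with non-negative sink strengths."""
        nf = 2 * self.n_forces
        active = np.ones(A.shape[1], dtype=bool)
        for _ in range(self.n_sinks + 1):
            coef = np.zeros(A.shape[1])
            if active.any():
                sol, *_ = np.linalg.lstsq(A[:, active], self._b, rcond=None)
                coef[active] = sol
            neg = (coef[nf:] < 0)
            if not neg.any():
                return coef
            active[nf:] &= ~neg
        return coef

    def _score_theta(self, theta):
        A = self._design(theta)
        coef = self._solve_linear(A)
        resid = np.linalg.norm(A @ coef - self._b)
        score = resid / self._bnorm if self._bnorm > 0 else float(resid > 0)
        return score, coef

    def _config_from(self, theta, coef) -> SingularityConfig:
        forces_np, sinks_np, g2 = self._unpack(theta)
        forces = []
        for i, (d, ext, x0) in enumerate(forces_np):
            fx, fy = coef[2 * i], coef[2 * i + 1]
            mag = float(np.hypot(fx, fy))
            direction = float(np.arctan2(fx, fy)) if mag > 0 else 0.0
            forces.append(ForceSingularity(d, direction, mag, ext, x0))
        sinks = []
        for i, (d, ext, x0) in enumerate(sinks_np):
            q = float(coef[2 * self.n_forces + i])
            sinks.append(SinkSingularity(d, max(q, 0.0), ext, x0))
        # canonical order: sort by axial position for comparability
        forces.sort(key=lambda f: f.position_d)
        sinks.sort(key=lambda s: s.position_d)
        return SingularityConfig(tuple(forces), tuple(sinks), g2)

    def fit(self, n_starts: int = 20, seed: int | None = None,
            warm_start: SingularityConfig | None = None,
            maxiter: int = 200, dedup_frac: float = 0.1,
            tie_frac: float = 0.2) -> "SingularityFitResults":
        """Multi-start bounded local optimization of the nonlinear params.

        Starts are a seeded Latin hypercube over the bounds (plus the
        warm start, if given); local optima are deduplicated at 10% of the
        bound range and near-ties kept as alternates.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        t0 = _time.perf_counter()
        tb = self._theta_bounds()
        lo, hi = tb[:, 0], tb[:, 1]
        span = hi - lo

        sampler = qmc.LatinHypercube(d=self.n_nonlinear, seed=seed)
        starts = [lo + span * row for row in sampler.random(n_starts)]
        if warm_start is not None:
            starts.insert(0, self._theta_from_config(warm_start))

        def fun(z):
            return self._score_theta(lo + span * np.clip(z, 0, 1))[0]

        optima = []
        failures = []
        for s in starts:
            z0 = (np.asarray(s) - lo) / span
            try:
                res = minimize(fun, np.clip(z0, 0, 1), method="L-BFGS-B",
                               bounds=[(0.0, 1.0)] * self.n_nonlinear,
                               options={"maxiter": maxiter})
                optima.append((float(res.fun), lo + span * res.x))
            except Exception as exc:  # pragma: no cover - diagnostics path
                failures.append(repr(exc))
        if not optima:
            raise RuntimeError("all optimization starts failed: "
                               + "; ".join(failures))
        optima.sort(key=lambda t: t[0])

        # deduplicate in normalized parameter space
        distinct: list[tuple[float, np.ndarray]] = []
        for sc, th in optima:
            z = (th - lo) / span
            if all(np.linalg.norm(z - (t - lo) / span) > dedup_frac
                   for _, t in distinct):
                distinct.append((sc, th))
        best_score, best_theta = distinct[0]
        _, best_coef = self._score_theta(best_theta)
        best_cfg = self._config_from(best_theta, best_coef)
        alternates = []
        for sc, th in distinct[1:]:
            if sc <= best_score * (1 + tie_frac) + 1e-12:
                _, cf = self._score_theta(th)
                alternates.append((self._config_from(th, cf), float(sc)))
        return SingularityFitResults(
            model=self, config=best_cfg, score=float(best_score),
            alternates=alternates, n_starts=len(starts),
            time=self.observed.time,
            elapsed=_time.perf_counter() - t0)

    def _theta_from_config(self, cfg: SingularityConfig) -> np.ndarray:
        theta = []
        for f in list(cfg.forces)[:self.n_forces]:
            theta += [f.position_d, f.extent]
            if not self.axis_constrained:
                theta.append(f.position_x)
        for s in list(cfg.sinks)[:self.n_sinks]:
            theta += [s.position_d, s.extent]
            if not self.axis_constrained:
                theta.append(s.position_x)
        theta.append(np.log10(max(cfg.gamma2, 1e-12)))
        tb = self._theta_bounds()
        return np.clip(np.asarray(theta), tb[:, 0], tb[:, 1])


@dataclass
class SingularityFitResults:
    """Best-fit singularity configuration for one timepoint."""

    model: SingularityFlowModel
    config: SingularityConfig
    score: float                      # relative RMS residual
    alternates: list[tuple[SingularityConfig, float]]
    n_starts: int
    time: float = float("nan")        # hpf
    elapsed: float = float("nan")     # wall seconds

    @property
    def u_sink(self) -> float:
        """Peak inflow speed of the fitted sink (0 if no sink)."""
        if not self.config.sinks:
            return 0.0
        return max(sink_peak_speed(s) for s in self.config.sinks)

    @property
    def gamma2(self) -> float:
        return self.config.gamma2

    def predict(self, grid: GridSpec | None = None) -> VelocityField:
        from .brinkman import evaluate_model
        return evaluate_model(self.config,
                              grid or self.model.observed.grid,
                              time=self.time)

    def summary(self) -> str:
        lines = [
            "Singularity flow model fit",
            "=" * 62,
            f"timepoint (hpf):      {self.time}",
            f"fit score (rel RMS):  {self.score:.4f}",
            f"friction gamma^2:     {self.config.gamma2:.4e} 1/um^2",
            f"starts / alternates:  {self.n_starts} / {len(self.alternates)}",
            "-" * 62,
            f"{'kind':<8}{'d [um]':>10}{'extent':>10}{'magnitude':>12}"
            f"{'direction':>12}",
        ]
        for f in self.config.forces:
            lines.append(f"{'force':<8}{f.position_d:>10.1f}"
                         f"{f.extent:>10.1f}{f.magnitude:>12.3f}"
                         f"{np.degrees(f.direction):>11.1f}\N{DEGREE SIGN}")
        for s in self.config.sinks:
            lines.append(f"{'sink':<8}{s.position_d:>10.1f}"
                         f"{s.extent:>10.1f}{s.strength:>12.3f}"
                         f"{'—':>12}")
        if self.config.sinks:
            lines.append("-" * 62)
            lines.append(f"u_sink (peak inflow): {self.u_sink:.4f} um/min")
        return "\n".join(lines)


@dataclass
class FitSeries:
    """Per-timepoint fits and the normalized fitted trajectories."""

    results: list[SingularityFitResults]

    def __post_init__(self):
        t = self.times
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.results])

    @property
    def u_sink(self) -> np.ndarray:
        return np.array([r.u_sink for r in self.results])

    @property
    def u_sink_norm(self) -> np.ndarray:
        u = self.u_sink
        peak = u.max()
        return u / peak if peak > 0 else u

    @property
    def gamma2(self) -> np.ndarray:
        return np.array([r.gamma2 for r in self.results])

    @property
    def gamma2_norm(self) -> np.ndarray:
        g = self.gamma2
        peak = g.max()
        return g / peak if peak > 0 else g

    @property
    def positions_d(self) -> dict[str, np.ndarray]:
        """Axial positions (distance d from the anterior limit) over time."""
        out: dict[str, np.ndarray] = {}
        nf = max(len(r.config.forces) for r in self.results)
        ns = max(len(r.config.sinks) for r in self.results)
        for i in range(nf):
            out[f"force_{i}"] = np.array(
                [r.config.forces[i].position_d if i < len(r.config.forces)
                 else np.nan for r in self.results])
        for i in range(ns):
            out[f"sink_{i}"] = np.array(
                [r.config.sinks[i].position_d if i < len(r.config.sinks)
                 else np.nan for r in self.results])
        return out

    @property
    def direction_signs(self) -> np.ndarray:
        """Sign of the AP force component per (position-sorted) force.

        +1 = posterior-directed, −1 = anterior-directed, 0 = negligible.
        Shape (n_times, n_forces).
        """
        nf = max(len(r.config.forces) for r in self.results)
        out = np.zeros((len(self.results), nf), dtype=int)
        for j, r in enumerate(self.results):
            mags = [f.magnitude for f in r.config.forces]
            floor = 0.05 * max(mags) if mags else 0.0
            for i, f in enumerate(r.config.forces):
                fy = f.magnitude * np.cos(f.direction)
                out[j, i] = int(np.sign(fy)) if abs(fy) > floor else 0
        return out

    def plot_trajectories(self, axes=None):
        """Normalized u_sink and γ² against time, with positions d."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(6, 8))
        t = self.times
        for name, d in self.positions_d.items():
            style = "o-" if name.startswith("force") else "s--"
            axes[0].plot(t, d, style, label=name)
        axes[0].set_ylabel("d from anterior limit (µm)")
        axes[0].invert_yaxis()
        axes[0].legend(fontsize="small")
        axes[1].plot(t, self.u_sink_norm, "o-")
        axes[1].set_ylabel("u_sink (norm., AU)")
        axes[2].plot(t, self.gamma2_norm, "o-")
        axes[2].set_ylabel("γ² (norm., AU)")
        axes[2].set_xlabel("time (hpf)")
        return axes

    def transition_index(self) -> int | None:
        """First timepoint whose force-direction pattern differs from the
        initial pattern and persists to the end of the series."""
        signs = self.direction_signs
        first = tuple(signs[0])
        for j in range(1, len(signs)):
            pat = tuple(signs[j])
            if pat != first and all(tuple(s) == pat for s in signs[j:]):
                return j
        return None


def fit_series(fields: list[VelocityField], n_forces: int = 2,
               n_sinks: int = 1, bounds: FitBounds | None = None,
               n_starts: int = 12, seed: int | None = None,
               warm_start: bool = True, maxiter: int = 200) -> FitSeries:
    """Independent per-timepoint fits over a flow-field time series.

    Each timepoint gets its own multi-start fit; optionally the previous
    best config is added as a warm start.
    """
    if len(fields) < 2:
        raise ValueError("fit_series needs at least 2 timepoints")
    results = []
    prev_cfg = None
    rng = np.random.default_rng(seed)
    for fld in fields:
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        m = SingularityFlowModel(fld, n_forces=n_forces, n_sinks=n_sinks,
                                 bounds=bounds)
        res = m.fit(n_starts=n_starts, seed=sub_seed,
                    warm_start=prev_cfg if warm_start else None,
                    maxiter=maxiter)
        results.append(res)
        prev_cfg = res.config
    return FitSeries(results)
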