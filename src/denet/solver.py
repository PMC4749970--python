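"""Dynamic elastic-net estimator.

Estimates the hidden input ``w(t)`` (the model error) by minimising

    J(w) = sum_i || y(t_i) - y_hat(t_i) ||^2_{W_i}
           + lambda1 * sum_k  int |w_k(t)| dt
           + lambda2 * sum_k  int w_k(t)^2 dt

subject to the observer dynamics  dx_hat/dt = f(x_hat, u, p, t) + w(t),
y_hat = h(x_hat).  The combined L1+L2 functional penalty mirrors the
elastic-net of regression: the L1 part drives whole components of ``w`` to
zero (localising the error to few target states), the L2 part keeps the
estimate smooth and bounded — a pure L1 penalty is not usable here because
the optimal-control solution becomes unbounded or bang-bang.

Numerics: direct control parameterization.  ``w`` is a piecewise-linear (or
piecewise-constant) function on a control grid; the nonsmooth L1 term is
made smooth by the exact split w = w+ - w-, w+/- >= 0.  The observer ODE is
integrated with fixed-step RK4 on a refinement of the control grid, and the
gradient of the *discrete* objective is computed exactly by reverse-mode
differentiation of the RK4 recursion (a discrete adjoint), so quasi-Newton
iterations converge to tight tolerances.  Bound-constrained problems are
solved with L-BFGS-B; optional endpoint-fit constraints switch to SLSQP.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    ConfigurationError,
    KnownInput,
    MeasurementSet,
    OdeModel,
    SimulationResult,
)

__all__ = [
    "RegularizationConfig",
    "ControlGrid",
    "HiddenInputTrajectory",
    "ObjectiveBreakdown",
    "DenSolution",
    "weighted_sse",
    "penalty",
    "solve_den",
    "select_lambdas",
    "PathFailureError",
]


class PathFailureError(RuntimeError):
    """Every fit along a regularisation path failed."""


# ---------------------------------------------------------------------------
# Configuration and trajectory containers
# ---------------------------------------------------------------------------

_POLICIES = ("fixed-to-nominal", "free-with-delta0-constraint")


@dataclass(frozen=True)
class RegularizationConfig:
    """Elastic-net weights and optional endpoint-fit tolerances.

    lambda1 weights the integrated absolute value (sparsity), lambda2 the
    integrated square (smoothness/boundedness) of each hidden-input
    component.  ``delta0``/``deltaN`` are preset tolerances on the weighted
    output misfit at the first / last sample time; in practice they can be
    read off the measurement error bars.  ``initial_state_policy`` decides
    whether the observer starts at the nominal initial state or treats it as
    a free variable constrained by delta0.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    delta0: float | None = None
    deltaN: float | None = None
    initial_state_policy: str = "fixed-to-nominal"

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConfigurationError("lambda1 and lambda2 must be nonnegative")
        if self.initial_state_policy not in _POLICIES:
            raise ConfigurationError(f"initial_state_policy must be one of {_POLICIES}")
        if self.initial_state_policy == "free-with-delta0-constraint" and self.delta0 is None:
            raise ConfigurationError("free initial state requires delta0")


_BASES = ("piecewise-linear", "piecewise-constant")


@dataclass(frozen=True)
class ControlGrid:
    """Discretization grid for the hidden input."""

    knots: np.ndarray
    basis: str = "piecewise-linear"

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2 or not np.all(np.diff(knots) > 0):
            raise ConfigurationError("knots must be strictly increasing, length >= 2")
        if self.basis not in _BASES:
            raise ConfigurationError(f"basis must be one of {_BASES}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_intervals(self) -> int:
        return self.knots.size - 1

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @classmethod
    def uniform(cls, t0: float, t1: float, n_intervals: int = 100,
                basis: str = "piecewise-linear") -> "ControlGrid":
        return cls(np.linspace(t0, t1, n_intervals + 1), basis=basis)

    @classmethod
    def for_data(cls, data: MeasurementSet, n_intervals: int = 100,
                 basis: str = "piecewise-linear") -> "ControlGrid":
        """Uniform grid spanning the measurement horizon [t_1, t_N]."""
        return cls.uniform(data.sample_times[0], data.sample_times[-1], n_intervals, basis)

    def locate(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Interval index j and local coordinate theta in [0, 1] for times t."""
        t = np.clip(np.asarray(t, float), self.knots[0], self.knots[-1])
        j = np.clip(np.searchsorted(self.knots, t, side="right") - 1, 0, self.n_intervals - 1)
        h = self.knots[j + 1] - self.knots[j]
        theta = (t - self.knots[j]) / h
        return j, theta


@dataclass
class HiddenInputTrajectory:
    """Hidden-input estimate/truth on a control grid, one column per state.

    ``zero_mask`` marks components constrained to exactly zero at every knot
    (either by thresholding or by an exclusion experiment).
    """

    grid: ControlGrid
    values: np.ndarray  # (n_knots, n_states)
    zero_mask: np.ndarray | None = None  # (n_states,) bool

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[0] != self.grid.n_knots:
            raise ConfigurationError("values must have one row per grid knot")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("hidden-input values must be finite")
        if self.zero_mask is None:
            self.zero_mask = np.zeros(self.values.shape[1], dtype=bool)
        else:
            self.zero_mask = np.asarray(self.zero_mask, bool)
            if np.any(np.abs(self.values[:, self.zero_mask]) > 0):
                raise ConfigurationError("masked components must be exactly zero")

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def __call__(self, t):
        j, theta = self.grid.locate(t)
        if self.grid.basis == "piecewise-constant":
            return self.values[j]
        th = np.asarray(theta)[..., None]
        return (1.0 - th) * self.values[j] + th * self.values[j + 1]

    @classmethod
    def zeros(cls, grid: ControlGrid, n_states: int) -> "HiddenInputTrajectory":
        return cls(grid, np.zeros((grid.n_knots, n_states)))

    @classmethod
    def from_callable(cls, grid: ControlGrid, fun, n_states: int) -> "HiddenInputTrajectory":
        vals = np.vstack([np.broadcast_to(np.asarray(fun(t), float), (n_states,)) for t in grid.knots])
        return cls(grid, vals)


@dataclass
class ObjectiveBreakdown:
    """Value of the error functional split into its three terms."""

    total: float
    fit_term: float
    l1_term: float
    l2_term: float
    solver_status: str  # optimal | max-iter | infeasible

    def __post_init__(self):
        parts = self.fit_term + self.l1_term + self.l2_term
        if min(self.fit_term, self.l1_term, self.l2_term) < -1e-12:
            raise ConfigurationError("objective terms must be nonnegative")
        if abs(self.total - parts) > 1e-9 * max(1.0, abs(self.total)):
            raise ConfigurationError("total must equal fit + l1 + l2")


@dataclass
class DenSolution:
    """Result of a dynamic elastic-net fit."""

    state_estimate: SimulationResult  # x_hat(t), y_hat(t) on the fine grid
    hidden_input: HiddenInputTrajectory
    objective: ObjectiveBreakdown
    config: RegularizationConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def fitted_at(self):
        """(sample_times, fitted outputs at sample times) recorded at solve time."""
        return self.diagnostics.get("sample_times"), self.diagnostics.get("fitted_outputs")


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------


def weighted_sse(observations: MeasurementSet, fitted_outputs: np.ndarray) -> float:
    """Weighted sum of squared output residuals, sum_i r_i^T W_i r_i."""
    fitted = np.atleast_2d(np.asarray(fitted_outputs, float))
    if fitted.shape != observations.observations.shape:
        raise ConfigurationError(
            f"fitted outputs shape {fitted.shape} does not match "
            f"observations {observations.observations.shape}"
        )
    r = observations.observations - fitted
    return float(np.einsum("ij,ijk,ik->", r, observations.weights, r))


def _segment_l1(a: np.ndarray, b: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Exact integral of |linear interpolant| on segments with endpoint values a, b."""
    same = a * b >= 0
    out = np.where(
        same,
        0.5 * h * (np.abs(a) + np.abs(b)),
        0.5 * h * (a * a + b * b) / np.maximum(np.abs(a) + np.abs(b), 1e-300),
    )
    return out


def penalty(w: HiddenInputTrajectory, cfg: RegularizationConfig) -> tuple[float, float]:
    """Elastic-net penalty terms (lambda1 * int |w|, lambda2 * int w^2).

    Quadrature is exact for the control basis: segment-wise closed forms for
    the piecewise-linear interpolant (including sign-crossing segments) and
    rectangle sums for the piecewise-constant one.
    """
    V = w.values
    h = np.diff(w.grid.knots)[:, None]
    if w.grid.basis == "piecewise-constant":
        l1 = np.sum(h * np.abs(V[:-1]))
        l2 = np.sum(h * V[:-1] ** 2)
    else:
        a, b = V[:-1], V[1:]
        l1 = np.sum(_segment_l1(a, b, h))
        l2 = np.sum(h / 3.0 * (a * a + a * b + b * b))
    return cfg.lambda1 * float(l1), cfg.lambda2 * float(l2)


# ---------------------------------------------------------------------------
# Discretized problem
# ---------------------------------------------------------------------------


class _Transcription:
    """Fixed-step RK4 transcription of the observer problem with an exact
    discrete adjoint for the gradient."""

    def __init__(self, model: OdeModel, input: KnownInput | None,
                 data: MeasurementSet, cfg: RegularizationConfig,
                 grid: ControlGrid, zero_mask: np.ndarray, substeps: int):
        self.model = model
        self.data = data
        self.cfg = cfg
        self.grid = grid
        self.mask = zero_mask
        self.active = np.flatnonzero(~zero_mask)
        self.n = model.n_states
        self.na = self.active.size
        self.K = grid.n_knots
        self.p = model.param_values
        t0, t1 = grid.knots[0], grid.knots[-1]
        if data.sample_times[0] < t0 - 1e-12 or data.sample_times[-1] > t1 + 1e-12:
            raise ConfigurationError("sample times must lie within the control grid span")
        self.u = input if input is not None else KnownInput.zero(model.n_inputs, (t0, t1))

        # fine integration grid: each control interval subdivided, plus every
        # sample time as an exact node
        fine = [np.linspace(grid.knots[j], grid.knots[j + 1], substeps + 1)
                for j in range(grid.n_intervals)]
        fine = np.unique(np.concatenate(fine + [data.sample_times]))
        self.ft = fine
        self.M = fine.size - 1
        # sample-time -> fine-node index
        self.sample_node = np.searchsorted(fine, data.sample_times)
        if not np.allclose(fine[self.sample_node], data.sample_times, atol=1e-9):
            raise ConfigurationError("sample times could not be matched to grid nodes")
        self.is_sample = {int(n_): i for i, n_ in enumerate(self.sample_node)}

        # stage times per step: t_a, t_mid, t_b
        ta, tb = fine[:-1], fine[1:]
        self.hstep = tb - ta
        tm = 0.5 * (ta + tb)
        self.stage_t = (ta, tm, tb)
        self.stage_u = tuple(np.atleast_2d(self.u(t)) for t in self.stage_t)
        # control-basis weights at stage times
        self.stage_w = tuple(grid.locate(t) for t in self.stage_t)
        self._pwc = grid.basis == "piecewise-constant"

        # trapezoid weights of the knots (L1 quadrature of the split form)
        h = np.diff(grid.knots)
        if self._pwc:
            tw = np.zeros(self.K)
            tw[:-1] = h
        else:
            tw = np.zeros(self.K)
            tw[:-1] += 0.5 * h
            tw[1:] += 0.5 * h
        self.trapw = tw

    # -- w evaluation at a stage of a step --------------------------------

    def _wstage(self, V: np.ndarray, stage: int, step: int) -> np.ndarray:
        j, th = self.stage_w[stage]
        j, th = j[step], th[step]
        if self._pwc:
            return V[j]
        return (1.0 - th) * V[j] + th * V[j + 1]

    def _addw(self, Vbar: np.ndarray, stage: int, step: int, v: np.ndarray):
        j, th = self.stage_w[stage]
        j, th = j[step], th[step]
        if self._pwc:
            Vbar[j] += v
        else:
            Vbar[j] += (1.0 - th) * v
            Vbar[j + 1] += th * v

    # -- packing ----------------------------------------------------------

    def pack(self, Vp, Vm, x0=None):
        parts = [Vp[:, self.active].ravel(), Vm[:, self.active].ravel()]
        if x0 is not None:
            parts.append(x0)
        return np.concatenate(parts)

    def unpack(self, z):
        K, na, n = self.K, self.na, self.n
        Vp = np.zeros((K, n))
        Vm = np.zeros((K, n))
        Vp[:, self.active] = z[: K * na].reshape(K, na)
        Vm[:, self.active] = z[K * na: 2 * K * na].reshape(K, na)
        x0 = z[2 * K * na:] if z.size > 2 * K * na else None
        return Vp, Vm, x0

    # -- forward integration ----------------------------------------------

    def forward(self, V: np.ndarray, x0: np.ndarray) -> np.ndarray:
        m = self.model
        xs = np.empty((self.M + 1, self.n))
        xs[0] = x0
        f = m.rate_function
        p = self.p
        ua, um, ub = self.stage_u
        ta, tm, tb = self.stage_t
        for i in range(self.M):
            h = self.hstep[i]
            x = xs[i]
            wa = self._wstage(V, 0, i)
            wm = self._wstage(V, 1, i)
            wb = self._wstage(V, 2, i)
            k1 = np.asarray(f(x, ua[i], p, ta[i]), float) + wa
            k2 = np.asarray(f(x + 0.5 * h * k1, um[i], p, tm[i]), float) + wm
            k3 = np.asarray(f(x + 0.5 * h * k2, um[i], p, tm[i]), float) + wm
            k4 = np.asarray(f(x + h * k3, ub[i], p, tb[i]), float) + wb
            xs[i + 1] = x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(xs)):
            raise FloatingPointError("forward transcription produced non-finite states")
        return xs

    # -- objective + gradient ---------------------------------------------

    def fit_and_residuals(self, xs):
        d = self.data
        res = []
        fit = 0.0
        for i, node in enumerate(self.sample_node):
            yhat = self.model.h(xs[node])
            r = d.observations[i] - yhat
            fit += float(r @ d.weights[i] @ r)
            res.append(r)
        return fit, res

    def objective(self, z, need_grad=True, x0_nominal=None):
        cfg = self.cfg
        Vp, Vm, x0 = self.unpack(z)
        x0_eff = x0 if x0 is not None else x0_nominal
        V = Vp - Vm
        xs = self.forward(V, x0_eff)
        fit, res = self.fit_and_residuals(xs)

        # penalties on the split controls (smooth):
        l1 = cfg.lambda1 * float(np.sum(self.trapw[:, None] * (Vp + Vm)))
        h = np.diff(self.grid.knots)[:, None]
        if self._pwc:
            l2 = cfg.lambda2 * float(np.sum(h * V[:-1] ** 2))
        else:
            a, b = V[:-1], V[1:]
            l2 = cfg.lambda2 * float(np.sum(h / 3.0 * (a * a + a * b + b * b)))
        total = fit + l1 + l2
        if not need_grad:
            return total, (fit, l1, l2), xs

        Vbar = self._fit_adjoint(xs, res, V)
        lam0 = Vbar.pop("lam0")
        Gv = Vbar["V"]

        # penalty gradients w.r.t. V (then split onto V+/V-)
        Gpen = np.zeros_like(V)
        if self._pwc:
            Gpen[:-1] += 2.0 * cfg.lambda2 * h * V[:-1]
        else:
            a, b = V[:-1], V[1:]
            Gpen[:-1] += cfg.lambda2 * h / 3.0 * (2 * a + b)
            Gpen[1:] += cfg.lambda2 * h / 3.0 * (a + 2 * b)
        gl1 = cfg.lambda1 * self.trapw[:, None]
        Gp = (Gv + Gpen) + gl1
        Gm = -(Gv + Gpen) + gl1
        parts = [Gp[:, self.active].ravel(), Gm[:, self.active].ravel()]
        if x0 is not None:
            parts.append(lam0)
        return total, (fit, l1, l2), xs, np.concatenate(parts)

    def _fit_adjoint(self, xs, res, V, terminal_only: int | None = None):
        """Reverse sweep of the RK4 recursion.

        Returns d(fit)/dV and d(fit)/dx0.  With ``terminal_only`` set to a
        sample index, differentiates only that sample's squared residual
        (used for endpoint-constraint Jacobians).
        """
        m = self.model
        d = self.data
        p = self.p
        jac = m.jac if m.rate_jac_x is None else (
            lambda x, u, t: np.atleast_2d(np.asarray(m.rate_jac_x(x, u, p, t), float)))
        ua, um, ub = self.stage_u
        ta, tm, tb = self.stage_t
        lam = np.zeros(self.n)
        Vbar = np.zeros_like(V)

        def sample_jump(node_idx, lam):
            if node_idx in self.is_sample:
                i = self.is_sample[node_idx]
                if terminal_only is not None and i != terminal_only:
                    return lam
                H = m.h_jac(xs[node_idx])
                lam = lam - 2.0 * H.T @ (d.weights[i] @ res[i])
            return lam

        for i in range(self.M - 1, -1, -1):
            lam = sample_jump(i + 1, lam)
            h = self.hstep[i]
            x = xs[i]
            wa = self._wstage(V, 0, i)
            wm = self._wstage(V, 1, i)
            k1 = np.asarray(m.rate_function(x, ua[i], p, ta[i]), float) + wa
            k2 = np.asarray(m.rate_function(x + 0.5 * h * k1, um[i], p, tm[i]), float) + wm
            k3 = np.asarray(m.rate_function(x + 0.5 * h * k2, um[i], p, tm[i]), float) + wm
            A1 = jac(x, ua[i], ta[i])
            A2 = jac(x + 0.5 * h * k1, um[i], tm[i])
            A3 = jac(x + 0.5 * h * k2, um[i], tm[i])
            A4 = jac(x + h * k3, ub[i], tb[i])

            kb1 = h / 6.0 * lam
            kb2 = h / 3.0 * lam
            kb3 = h / 3.0 * lam
            kb4 = h / 6.0 * lam
            g4 = A4.T @ kb4
            kb3 = kb3 + h * g4
            self._addw(Vbar, 2, i, kb4)
            g3 = A3.T @ kb3
            kb2 = kb2 + 0.5 * h * g3
            self._addw(Vbar, 1, i, kb3)
            g2 = A2.T @ kb2
            kb1 = kb1 + 0.5 * h * g2
            self._addw(Vbar, 1, i, kb2)
            g1 = A1.T @ kb1
            self._addw(Vbar, 0, i, kb1)
            lam = lam + g1 + g2 + g3 + g4
        lam = sample_jump(0, lam)
        return {"V": Vbar, "lam0": lam}


# ---------------------------------------------------------------------------
# Main solve
# ---------------------------------------------------------------------------


def solve_den(
    model: OdeModel,
    input: KnownInput | None,
    data: MeasurementSet,
    cfg: RegularizationConfig,
    grid: ControlGrid | None = None,
    zero_mask: np.ndarray | Sequence[int] | None = None,
    seed: int = 0,
    substeps: int = 3,
    maxiter: int = 600,
    gtol: float = 1e-7,
    n_starts: int = 1,
    start_scale: float = 0.1,
    w_init: HiddenInputTrajectory | None = None,
) -> DenSolution:
    """Fit the dynamic elastic-net and return the estimated hidden input.

    ``zero_mask`` may be a boolean vector over states or a sequence of state
    indices; masked components are pinned to exactly zero.  The solve is
    deterministic given identical inputs and ``seed`` (the seed only matters
    when ``n_starts > 1`` enables random restarts).
    """
    if data.n_outputs != model.n_outputs:
        raise ConfigurationError("measurement outputs do not match the model")
    if grid is None:
        grid = ControlGrid.for_data(data)
    mask = np.zeros(model.n_states, dtype=bool)
    if zero_mask is not None:
        zm = np.asarray(zero_mask)
        if zm.dtype == bool:
            mask = zm.copy()
        else:
            mask[np.asarray(zm, int)] = True
    tr = _Transcription(model, input, data, cfg, grid, mask, substeps)

    free_x0 = cfg.initial_state_policy == "free-with-delta0-constraint"
    x0_nom = model.initial_state.copy()
    K, na = tr.K, tr.na

    def make_z0(rng=None):
        Vp = np.zeros((K, model.n_states))
        Vm = np.zeros((K, model.n_states))
        if w_init is not None:
            W0 = np.asarray(w_init(grid.knots), float).reshape(K, model.n_states)
            W0[:, mask] = 0.0
            Vp = np.maximum(W0, 0.0)
            Vm = np.maximum(-W0, 0.0)
        if rng is not None:
            Vp[:, tr.active] += np.abs(rng.normal(0, start_scale, (K, na)))
            Vm[:, tr.active] += np.abs(rng.normal(0, start_scale, (K, na)))
        return tr.pack(Vp, Vm, x0_nom.copy() if free_x0 else None)

    nvar = 2 * K * na + (model.n_states if free_x0 else 0)
    bounds = [(0.0, None)] * (2 * K * na) + [(None, None)] * (nvar - 2 * K * na)

    def fun(z):
        try:
            out = tr.objective(z, need_grad=True, x0_nominal=x0_nom)
        except FloatingPointError:
            # diverging trial point: return a huge value so the line search backtracks
            return 1e20, np.zeros_like(z)
        return out[0], out[3]

    constraints = []
    use_slsqp = free_x0 or cfg.deltaN is not None
    if free_x0:
        W0m = data.weights[0]
        y0 = data.observations[0]

        def c0(z):
            _, _, x0 = tr.unpack(z)
            r = y0 - model.h(x0)
            return cfg.delta0 ** 2 - float(r @ W0m @ r)

        def c0_jac(z):
            _, _, x0 = tr.unpack(z)
            r = y0 - model.h(x0)
            g = np.zeros_like(z)
            g[2 * K * na:] = 2.0 * model.h_jac(x0).T @ (W0m @ r)
            return g

        constraints.append({"type": "ineq", "fun": c0, "jac": c0_jac})
    if cfg.deltaN is not None:
        iN = data.n_samples - 1

        def cN(z):
            Vp, Vm, x0 = tr.unpack(z)
            xs = tr.forward(Vp - Vm, x0 if x0 is not None else x0_nom)
            _, res = tr.fit_and_residuals(xs)
            rN = res[iN]
            return cfg.deltaN ** 2 - float(rN @ data.weights[iN] @ rN)

        def cN_jac(z):
            Vp, Vm, x0 = tr.unpack(z)
            V = Vp - Vm
            xs = tr.forward(V, x0 if x0 is not None else x0_nom)
            _, res = tr.fit_and_residuals(xs)
            adj = tr._fit_adjoint(xs, res, V, terminal_only=iN)
            Gv = adj["V"]
            parts = [-Gv[:, tr.active].ravel(), Gv[:, tr.active].ravel()]
            if x0 is not None:
                parts.append(-adj["lam0"])
            return np.concatenate(parts)

        constraints.append({"type": "ineq", "fun": cN, "jac": cN_jac})

    rng = np.random.default_rng(seed)
    best = None
    if nvar == 0:
        # every component masked: the solution is w == 0 by construction
        z0 = np.zeros(0)
        f0, g0 = fun(z0)
        from scipy.optimize import OptimizeResult
        best = OptimizeResult(x=z0, fun=f0, jac=g0, success=True, nit=0,
                              message="all components masked")
    for start in range(max(1, n_starts) if best is None else 0):
        z0 = make_z0(None if start == 0 else rng)
        if use_slsqp:
            res = minimize(fun, z0, jac=True, method="SLSQP", bounds=bounds,
                           constraints=constraints,
                           options={"maxiter": maxiter, "ftol": 1e-12})
        else:
            res = minimize(fun, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                                    "ftol": 1e-14, "gtol": gtol, "maxcor": 25})
        if best is None or res.fun < best.fun:
            best = res
    res = best

    status = "optimal" if res.success else "max-iter"
    msg = str(getattr(res, "message", ""))
    if "incompatible" in msg.lower() or "infeasible" in msg.lower() or getattr(res, "status", 0) == 4:
        status = "infeasible"
    if constraints and any(c["fun"](res.x) < -1e-6 for c in constraints):
        status = "infeasible"

    Vp, Vm, x0 = tr.unpack(res.x)
    x0_eff = x0 if x0 is not None else x0_nom
    total, (fit, l1, l2), xs = tr.objective(res.x, need_grad=False, x0_nominal=x0_nom)
    V = Vp - Vm
    V[:, mask] = 0.0
    w_hat = HiddenInputTrajectory(grid, V, zero_mask=mask)
    outputs = np.vstack([model.h(xs[i]) for i in range(xs.shape[0])])
    est = SimulationResult(times=tr.ft.copy(), states=xs, outputs=outputs)
    fitted = outputs[tr.sample_node]

    constraint_rec = {}
    if free_x0:
        constraint_rec["delta0_residual"] = float(constraints[0]["fun"](res.x))
    if cfg.deltaN is not None:
        constraint_rec["deltaN_residual"] = float(constraints[-1]["fun"](res.x))

    obj = ObjectiveBreakdown(total=total, fit_term=fit, l1_term=l1, l2_term=l2,
                             solver_status=status)
    diag = {
        "n_iter": int(getattr(res, "nit", -1)),
        "message": msg,
        "grad_inf_norm": (float(np.max(np.abs(res.jac)))
                          if getattr(res, "jac", None) is not None and np.size(res.jac)
                          else None),
        "constraints": constraint_rec,
        "sample_times": data.sample_times.copy(),
        "fitted_outputs": fitted,
        "x0": x0_eff.copy(),
        "substeps": substeps,
        "seed": seed,
    }
    return DenSolution(state_estimate=est, hidden_input=w_hat, objective=obj,
                       config=cfg, diagnostics=diag)


# ---------------------------------------------------------------------------
# Regularisation-path selection
# ---------------------------------------------------------------------------


def select_lambdas(
    model: OdeModel,
    input: KnownInput | None,
    data: MeasurementSet,
    grid: ControlGrid,
    lambda1_grid: Sequence[float],
    lambda2_grid: Sequence[float],
    fit_factor: float = 1.1,
    base_cfg: RegularizationConfig | None = None,
    **solve_opts,
) -> tuple[float, float, pd.DataFrame]:
    """Fit a (lambda1, lambda2) grid and pick the knee point.

    The chosen point is the sparsest acceptable one: the largest lambda1
    (ties broken by the largest lambda2) whose fit term is within
    ``fit_factor`` of the best fit found along the path, balancing the
    smoothness of the estimate against the accuracy of the fit.
    """
    l1s = sorted(set(float(v) for v in lambda1_grid))
    l2s = sorted(set(float(v) for v in lambda2_grid))
    if not l1s or not l2s or min(l1s) < 0 or min(l2s) < 0:
        raise ConfigurationError("lambda grids must be nonempty and nonnegative")
    rows = []
    for l2 in l2s:
        for l1 in l1s:
            cfg = dataclasses.replace(base_cfg or RegularizationConfig(),
                                      lambda1=l1, lambda2=l2)
            try:
                sol = solve_den(model, input, data, cfg, grid, **solve_opts)
                V = sol.hidden_input
                unit = RegularizationConfig(lambda1=1.0, lambda2=1.0)
                l1n, l2n = penalty(V, unit)
                rows.append({"lambda1": l1, "lambda2": l2,
                             "fit_term": sol.objective.fit_term,
                             "l1_norm": l1n, "l2_norm": l2n,
                             "status": sol.objective.solver_status})
            except Exception as exc:  # noqa: BLE001 - recorded, not raised
                rows.append({"lambda1": l1, "lambda2": l2, "fit_term": np.nan,
                             "l1_norm": np.nan, "l2_norm": np.nan,
                             "status": f"failed: {exc}"})
    report = pd.DataFrame(rows)
    ok = report[np.isfinite(report["fit_term"])]
    if ok.empty:
        raise PathFailureError("all regularisation-path fits failed")
    fmin = ok["fit_term"].min()
    good = ok[ok["fit_term"] <= fit_factor * max(fmin, 1e-300)]
    if good.empty:
        good = ok
    pick = good.sort_values(["lambda1", "lambda2"]).iloc[-1]
    return float(pick["lambda1"]), float(pick["lambda2"]), report
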