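"""Nominal ODE models, known inputs and simulation.

A *nominal model* is the modeller's current draft of a dynamical system,

    dx/dt = f(x, u, p, t),   y = h(x),

with state ``x`` (n_states), known external input ``u``, parameters ``p``
and an output map ``h`` describing which combinations of states are
experimentally accessible.  The true system is assumed to differ from the
nominal one by an additive, time-varying *hidden input* ``w(t)`` on the
state derivatives,

    dx/dt = f(x, u, p, t) + w(t),

which lumps together unmodelled exogenous influences and missing or
misspecified interactions.  This module provides the model container, the
built-in example models (JAK-STAT signalling, a synthetic UV-B-like
surrogate network, small network motifs) and an adaptive-step simulator
that optionally injects a hidden input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "ConfigurationError",
    "IntegrationError",
    "KnownInput",
    "OdeModel",
    "SimulationResult",
    "MeasurementSet",
    "simulate",
    "jak_stat_model",
    "uvb_model",
    "motif_models",
    "model_from_config",
    "linearize",
]


class ConfigurationError(ValueError):
    """Inconsistent dimensions, labels or settings."""


class IntegrationError(RuntimeError):
    """The initial-value solver failed; ``last_time`` is the furthest time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


# ---------------------------------------------------------------------------
# Known external inputs
# ---------------------------------------------------------------------------

_INTERPOLATIONS = ("piecewise-linear", "piecewise-constant", "zero-order-hold")


@dataclass(frozen=True)
class KnownInput:
    """Tabulated external input u(t) with a fixed interpolation rule.

    Outside the tabulated range the boundary value is held constant.
    ``piecewise-constant`` and ``zero-order-hold`` both hold the value of the
    most recent tabulated time point.
    """

    times: np.ndarray
    values: np.ndarray  # (n_times, n_inputs)
    interpolation: str = "piecewise-linear"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[0] != times.size:
            values = values.T
        if values.shape[0] != times.size:
            raise ConfigurationError(
                f"input table has {values.shape[0]} rows for {times.size} times"
            )
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ConfigurationError("input times must be strictly increasing")
        if self.interpolation not in _INTERPOLATIONS:
            raise ConfigurationError(
                f"unknown interpolation {self.interpolation!r}; choose from {_INTERPOLATIONS}"
            )
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("input values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_inputs(self) -> int:
        return self.values.shape[1]

    @classmethod
    def zero(cls, n_inputs: int = 1, t_span: tuple[float, float] = (0.0, 1.0)) -> "KnownInput":
        return cls(np.asarray(t_span, float), np.zeros((2, n_inputs)))

    @classmethod
    def constant(cls, value, t_span: tuple[float, float] = (0.0, 1.0)) -> "KnownInput":
        v = np.atleast_1d(np.asarray(value, float))
        return cls(np.asarray(t_span, float), np.tile(v, (2, 1)))

    def __call__(self, t) -> np.ndarray:
        t = np.clip(t, self.times[0], self.times[-1])
        if self.interpolation == "piecewise-linear":
            return np.stack(
                [np.interp(t, self.times, self.values[:, j]) for j in range(self.n_inputs)],
                axis=-1,
            )
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, self.times.size - 1)
        return self.values[idx]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class OdeModel:
    """A nominal ODE model ``dx/dt = f(x, u, p, t)`` with output map ``y = h(x)``.

    ``rate_function(x, u, params, t)`` and ``output_function(x)`` are plain
    callables; models built with :meth:`from_expressions` additionally carry
    analytic Jacobians (used by the estimator's adjoint) and the symbolic
    right-hand sides (used by the SBML layer and by symbolic invariant checks).
    """

    n_states: int
    n_outputs: int
    rate_function: Callable
    output_function: Callable
    initial_state: np.ndarray
    parameters: dict
    state_labels: tuple
    output_labels: tuple
    n_inputs: int = 1
    rate_jac_x: Callable | None = None  # d f / d x, shape (n_states, n_states)
    output_jac: Callable | None = None  # d h / d x, shape (n_outputs, n_states)
    name: str = "model"
    # symbolic metadata (None for models defined by raw callables)
    sym_states: tuple | None = None
    sym_inputs: tuple | None = None
    sym_rates: tuple | None = None
    sym_outputs: tuple | None = None

    def __post_init__(self):
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.initial_state.size != self.n_states:
            raise ConfigurationError(
                f"initial_state has length {self.initial_state.size}, expected {self.n_states}"
            )
        if len(self.state_labels) != self.n_states:
            raise ConfigurationError("state_labels length must equal n_states")
        if len(self.output_labels) != self.n_outputs:
            raise ConfigurationError("output_labels length must equal n_outputs")
        self.state_labels = tuple(self.state_labels)
        self.output_labels = tuple(self.output_labels)

    # -- construction from symbolic expressions ---------------------------

    @classmethod
    def from_expressions(
        cls,
        states: Sequence[str],
        rates: Sequence,
        outputs: Sequence,
        parameters: Mapping[str, float],
        initial_state: Sequence[float],
        inputs: Sequence[str] = ("u",),
        output_labels: Sequence[str] | None = None,
        name: str = "model",
    ) -> "OdeModel":
        """Build a model from rate/output expressions given as strings or sympy.

        The expressions may involve the state names, the input names, the
        parameter names and the time symbol ``t``.  Analytic Jacobians are
        derived symbolically and lambdified with numpy.
        """
        param_names = list(parameters)
        t = sp.Symbol("t")
        xs = sp.symbols(list(states))
        us = sp.symbols(list(inputs))
        ps = sp.symbols(param_names)
        xs = (xs,) if isinstance(xs, sp.Symbol) else tuple(xs)
        us = (us,) if isinstance(us, sp.Symbol) else tuple(us)
        ps = (ps,) if isinstance(ps, sp.Symbol) else tuple(ps)
        ns = {str(s): s for s in (*xs, *us, *ps, t)}
        f_exprs = [sp.sympify(r, locals=ns) for r in rates]
        h_exprs = [sp.sympify(o, locals=ns) for o in outputs]
        if len(f_exprs) != len(xs):
            raise ConfigurationError("one rate expression required per state")

        fmat = sp.Matrix(f_exprs)
        hmat = sp.Matrix(h_exprs)
        jac_f = fmat.jacobian(xs)
        jac_h = hmat.jacobian(xs)
        args = (xs, us, ps, t)
        f_fun = sp.lambdify(args, f_exprs, modules="numpy")
        jf_fun = sp.lambdify(args, jac_f, modules="numpy")
        h_fun = sp.lambdify((xs, ps), h_exprs, modules="numpy")
        jh_fun = sp.lambdify((xs, ps), jac_h, modules="numpy")

        n, m = len(xs), len(h_exprs)
        p0 = np.array([float(parameters[k]) for k in param_names])

        def rate_function(x, u, p, tt, _f=f_fun):
            return np.asarray(_f(x, np.atleast_1d(u), p, tt), dtype=float)

        def rate_jac_x(x, u, p, tt, _j=jf_fun):
            return np.asarray(_j(x, np.atleast_1d(u), p, tt), dtype=float)

        # the output map takes the state only; parameter values (e.g. output
        # scale factors) are baked in here — with_parameters() rebuilds them
        def output_function(x, _h=h_fun, _p=p0):
            return np.asarray(_h(x, _p), dtype=float)

        def output_jac(x, _j=jh_fun, _p=p0):
            return np.asarray(_j(x, _p), dtype=float)

        return cls(
            n_states=n,
            n_outputs=m,
            rate_function=rate_function,
            output_function=output_function,
            initial_state=np.asarray(initial_state, float),
            parameters=dict(parameters),
            state_labels=tuple(states),
            output_labels=tuple(output_labels) if output_labels else tuple(f"y{i+1}" for i in range(m)),
            n_inputs=len(us),
            rate_jac_x=rate_jac_x,
            output_jac=output_jac,
            name=name,
            sym_states=xs,
            sym_inputs=us,
            sym_rates=tuple(f_exprs),
            sym_outputs=tuple(h_exprs),
        )

    # -- convenience ------------------------------------------------------

    @property
    def param_values(self) -> np.ndarray:
        return np.array(list(self.parameters.values()), dtype=float)

    def with_parameters(self, new: Mapping[str, float]) -> "OdeModel":
        """Copy of the model with some parameter values replaced."""
        params = dict(self.parameters)
        unknown = set(new) - set(params)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        params.update(new)
        if self.sym_rates is not None:
            # rebuild so parameter values baked into the output map refresh
            return OdeModel.from_expressions(
                states=[str(s) for s in self.sym_states],
                rates=list(self.sym_rates),
                outputs=list(self.sym_outputs),
                parameters=params,
                initial_state=self.initial_state,
                inputs=[str(s) for s in self.sym_inputs],
                output_labels=self.output_labels,
                name=self.name,
            )
        return replace(self, parameters=params)

    def f(self, x, u, t) -> np.ndarray:
        return self.rate_function(np.asarray(x, float), u, self.param_values, t)

    def jac(self, x, u, t) -> np.ndarray:
        if self.rate_jac_x is not None:
            return self.rate_jac_x(np.asarray(x, float), u, self.param_values, t)
        # fall back to forward differences
        x = np.asarray(x, float)
        f0 = self.f(x, u, t)
        J = np.empty((self.n_states, self.n_states))
        for j in range(self.n_states):
            step = 1e-7 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += step
            J[:, j] = (self.f(xp, u, t) - f0) / step
        return J

    def h(self, x) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.output_function(np.asarray(x, float)), float))

    def h_jac(self, x) -> np.ndarray:
        if self.output_jac is not None:
            return np.atleast_2d(np.asarray(self.output_jac(np.asarray(x, float)), float))
        x = np.asarray(x, float)
        h0 = self.h(x)
        J = np.empty((self.n_outputs, self.n_states))
        for j in range(self.n_states):
            step = 1e-7 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += step
            J[:, j] = (self.h(xp) - h0) / step
        return J


def linearize(model: OdeModel, x: np.ndarray, u, t: float = 0.0):
    """Return (A, C): the state Jacobian and output Jacobian at (x, u, t)."""
    return model.jac(x, u, t), model.h_jac(x)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Trajectory of a simulated model: states and outputs on a time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    outputs: np.ndarray  # (n_times, n_outputs)

    def state_at(self, t: float) -> np.ndarray:
        return np.array([np.interp(t, self.times, self.states[:, k]) for k in range(self.states.shape[1])])


def simulate(
    model: OdeModel,
    input: KnownInput | None,
    t_grid: Sequence[float],
    hidden_input: Callable | None = None,
    x0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the model on ``t_grid`` with adaptive error control.

    ``hidden_input``, if given, is a callable ``w(t) -> (n_states,)`` added to
    the right-hand side, turning the nominal model into the (assumed) true
    system.  ``input=None`` means u == 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ConfigurationError("t_grid must be an increasing 1-d sequence")
    u = input if input is not None else KnownInput.zero(model.n_inputs, (t_grid[0], t_grid[-1]))
    if u.n_inputs != model.n_inputs:
        raise ConfigurationError(
            f"input has {u.n_inputs} channels, model expects {model.n_inputs}"
        )
    x0 = model.initial_state if x0 is None else np.asarray(x0, float)
    if x0.size != model.n_states:
        raise ConfigurationError("x0 length must equal n_states")
    p = model.param_values

    if hidden_input is None:
        def rhs(t, x):
            return model.rate_function(x, u(t), p, t)
    else:
        def rhs(t, x):
            w = np.asarray(hidden_input(t), float)
            return model.rate_function(x, u(t), p, t) + w
        w0 = np.asarray(hidden_input(t_grid[0]), float)
        if w0.size != model.n_states:
            raise ConfigurationError("hidden_input must return one value per state")

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != t_grid.size:
        last = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        raise IntegrationError(f"integration failed at t={last:g}: {sol.message}", last_time=last)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise IntegrationError("integration produced non-finite states")
    outputs = np.vstack([model.h(states[i]) for i in range(states.shape[0])])
    return SimulationResult(times=t_grid, states=states, outputs=outputs)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------


@dataclass
class MeasurementSet:
    """Sampled noisy outputs y(t_i) with per-sample weighting matrices.

    ``weights[i]`` is the symmetric positive-semidefinite matrix W_i entering
    the weighted square norm of the fit term.  When per-point standard
    deviations are available, the default weighting is diag(1/sd^2), which
    puts outputs of different magnitude on a common scale.
    """

    sample_times: np.ndarray
    observations: np.ndarray  # (N, n_outputs)
    weights: np.ndarray | None = None  # (N, n_outputs, n_outputs)
    sds: np.ndarray | None = None  # (N, n_outputs)

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, float)
        self.observations = np.atleast_2d(np.asarray(self.observations, float))
        N, m = self.observations.shape
        if self.sample_times.size != N:
            raise ConfigurationError("one observation row per sample time required")
        if N < 2:
            raise ConfigurationError("at least two sample times required")
        if not np.all(np.diff(self.sample_times) > 0):
            raise ConfigurationError("sample times must be strictly increasing")
        if self.sds is not None:
            self.sds = np.atleast_2d(np.asarray(self.sds, float))
            if self.sds.shape != (N, m):
                raise ConfigurationError("sds must match the shape of observations")
        if self.weights is None:
            if self.sds is not None:
                W = np.zeros((N, m, m))
                for i in range(N):
                    W[i] = np.diag(1.0 / np.maximum(self.sds[i], 1e-12) ** 2)
                self.weights = W
            else:
                self.weights = np.tile(np.eye(m), (N, 1, 1))
        else:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape == (m, m):
                self.weights = np.tile(self.weights, (N, 1, 1))
            if self.weights.shape != (N, m, m):
                raise ConfigurationError("weights must be (N, n_outputs, n_outputs)")
            for i in range(N):
                if not np.allclose(self.weights[i], self.weights[i].T, atol=1e-12):
                    raise ConfigurationError(f"weight matrix at sample {i} is not symmetric")

    @property
    def n_outputs(self) -> int:
        return self.observations.shape[1]

    @property
    def n_samples(self) -> int:
        return self.observations.shape[0]


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------


def jak_stat_model() -> OdeModel:
    """Nominal JAK-STAT signalling model (4 states, EPO-receptor driven).

    States: cytoplasmic STAT5 (x1), phosphorylated monomeric STAT5 (x2),
    phosphorylated dimeric STAT5 (x3), nuclear dimeric STAT5 (x4).  The known
    input u(t) is the phosphorylated EPO-receptor time course.  Outputs are
    the measured quantities: phosphorylated cytoplasmic STAT5, s1*(x2 + 2 x3),
    and total cytoplasmic STAT5, s2*(x1 + x2 + 2 x3).  Nuclear dimers
    dissociate and return to the cytoplasm instantaneously at rate k4 (the
    delay of that relocation is exactly the kind of unmodelled dynamics a
    hidden-input fit should expose as errors on x1 and x4).  The
    monomer-equivalent total x1 + x2 + 2 x3 + 2 x4 is conserved.

    Rate constants follow the published parameterization of the source model
    (Swameye et al. 2003); output scale factors are set to 1.
    """
    return OdeModel.from_expressions(
        states=["x1", "x2", "x3", "x4"],
        rates=[
            "-k1*x1*u + 2*k4*x4",
            "k1*x1*u - k2*x2**2",
            "-k3*x3 + k2*x2**2/2",
            "k3*x3 - k4*x4",
        ],
        outputs=["s1*(x2 + 2*x3)", "s2*(x1 + x2 + 2*x3)"],
        parameters={"k1": 0.021, "k2": 2.46, "k3": 0.1066, "k4": 0.10658,
                    "s1": 1.0, "s2": 1.0},
        initial_state=[1.0, 0.0, 0.0, 0.0],
        inputs=["u"],
        output_labels=["pSTAT5_cyt", "totalSTAT5_cyt"],
        name="jak_stat",
    )


def uvb_model() -> OdeModel:
    """Synthetic surrogate of a plant UV-B photoreceptor signalling network.

    SYNTHETIC STAND-IN: the curated published model (BioModels
    BIOMD0000000545) could not be bundled, so this is a purpose-built
    surrogate sharing its coarse anatomy — 11 states coupled by 10 reactions,
    a UV-dose-like known input driving a photoreceptor dimer/monomer cycle,
    a downstream signalling cascade, and a 5-component output map whose
    components are linear combinations of 7 distinct state variables
    (x2, x4, x5, x6, x7, x8, x9).  States x10 and x11 are terminal
    products that do not feed back into any output-relevant state, so hidden
    inputs targeting them have no output effect.  Results on this model
    characterise the estimator, not the published network.

    Reactions (mass action):
      v1 = k1*u*x1  (dimer photoconversion, x1 -> 2 x2)
      v2 = k2*x2^2  (re-dimerisation, 2 x2 -> x1)
      v3 = k3*x2*x3 (monomer-effector binding, x2 + x3 -> x4)
      v4 = k4*x4    (complex dissociation)
      v5 = k5*x4    (complex-driven synthesis of x5)
      v6 = k6*x5    (x5 -> x6)
      v7 = k7*x6    (x6 -> x7)
      v8 = k8*x7    (x7 -> x8)
      v9 = k9*x8    (x8 -> x9 + x10, branch)
      v10 = k10*x9  (x9 -> x11)
    """
    v = {
        "v1": "k1*u*x1",
        "v2": "k2*x2**2",
        "v3": "k3*x2*x3",
        "v4": "k4*x4",
        "v5": "k5*x4",
        "v6": "k6*x5",
        "v7": "k7*x6",
        "v8": "k8*x7",
        "v9": "k9*x8",
        "v10": "k10*x9",
    }
    rates = [
        f"-({v['v1']}) + ({v['v2']})",                                   # x1
        f"2*({v['v1']}) - 2*({v['v2']}) - ({v['v3']}) + ({v['v4']})",    # x2
        f"-({v['v3']}) + ({v['v4']})",                                   # x3
        f"({v['v3']}) - ({v['v4']})",                                    # x4
        f"({v['v5']}) - ({v['v6']})",                                    # x5
        f"({v['v6']}) - ({v['v7']})",                                    # x6
        f"({v['v7']}) - ({v['v8']})",                                    # x7
        f"({v['v8']}) - ({v['v9']})",                                    # x8
        f"({v['v9']}) - ({v['v10']})",                                   # x9
        f"({v['v9']})",                                                  # x10
        f"({v['v10']})",                                                 # x11
    ]
    outputs = [
        "x2 + 2*x4",        # photoreceptor monomer + signalling complex
        "x5",
        "x6 + 0.5*x7",
        "x8",
        "0.8*x9",
    ]
    params = {
        "k1": 0.6, "k2": 0.3, "k3": 0.8, "k4": 0.4, "k5": 0.7,
        "k6": 0.35, "k7": 0.45, "k8": 0.4, "k9": 0.5, "k10": 0.3,
    }
    return OdeModel.from_expressions(
        states=[f"x{i}" for i in range(1, 12)],
        rates=rates,
        outputs=outputs,
        parameters=params,
        initial_state=[2.0, 0.1, 1.5, 0.0, 0.2, 0.1, 0.1, 0.05, 0.05, 0.0, 0.0],
        inputs=["u"],
        output_labels=["y_receptor", "y_x5", "y_x6x7", "y_x8", "y_x9"],
        name="uvb_surrogate",
    )


def motif_models() -> dict[str, OdeModel]:
    """Small linear network motifs used as ground-truth test beds.

    All motifs use mass-action (first-order) rates, a single known input
    channel and a single measured output:

    - ``chain3``:      u -> x1 -> x2 -> x3
    - ``feedforward``: u -> x1, x1 -> x2, x1 and x2 both feed x3
    - ``feedback``:    chain with negative feedback x3 -| x1
    - ``symmetric``:   x1 and x2 decay identically and feed x3 with equal
      rates; outputs (x1 + x2, x3).  Hidden inputs to x1 and x2 are
      output-indistinguishable by construction (a deliberately unobservable
      error pair): the outputs pin their sum but not the split.

    The first three observe every state (scaled), which makes a hidden input
    on any single node observable in the localisation sense: no other node
    can fake its output signature.  With fewer outputs than states, an error
    on a sparsely-observed node can be mimicked — often more cheaply in the
    penalty — by inputs to nodes nearer the output; the ``symmetric`` motif
    makes that ambiguity exact.
    """
    motifs = {}
    motifs["chain3"] = OdeModel.from_expressions(
        states=["x1", "x2", "x3"],
        rates=["u - a1*x1", "a1*x1 - a2*x2", "a2*x2 - a3*x3"],
        outputs=["x1", "x2", "x3"],
        parameters={"a1": 1.0, "a2": 0.8, "a3": 0.5},
        initial_state=[0.0, 0.0, 0.0],
        name="chain3",
    )
    motifs["feedforward"] = OdeModel.from_expressions(
        states=["x1", "x2", "x3"],
        rates=["u - a*x1", "b*x1 - c*x2", "d*x1 + e*x2 - g*x3"],
        outputs=["x1", "0.8*x2", "1.2*x3"],
        parameters={"a": 1.0, "b": 0.7, "c": 0.9, "d": 0.4, "e": 0.8, "g": 0.6},
        initial_state=[0.0, 0.0, 0.0],
        name="feedforward",
    )
    motifs["feedback"] = OdeModel.from_expressions(
        states=["x1", "x2", "x3"],
        rates=["u - a*x1 - f*x3", "b*x1 - c*x2", "d*x2 - e*x3"],
        outputs=["x1", "x2", "x3"],
        parameters={"a": 0.8, "b": 1.0, "c": 0.7, "d": 0.9, "e": 0.5, "f": 0.4},
        initial_state=[0.0, 0.0, 0.0],
        name="feedback",
    )
    motifs["symmetric"] = OdeModel.from_expressions(
        states=["x1", "x2", "x3"],
        rates=["u - a*x1", "-a*x2", "b*x1 + b*x2 - c*x3"],
        outputs=["x1 + x2", "x3"],
        parameters={"a": 0.9, "b": 0.8, "c": 0.6},
        initial_state=[0.0, 0.0, 0.0],
        name="symmetric",
    )
    return motifs


def model_from_config(cfg: Mapping) -> OdeModel:
    """Build a model from a declarative mapping (states, rates, outputs,
    parameters, initial_state, optional inputs/output_labels/name)."""
    required = {"states", "rates", "outputs", "parameters", "initial_state"}
    missing = required - set(cfg)
    if missing:
        raise ConfigurationError(f"model definition missing fields: {sorted(missing)}")
    return OdeModel.from_expressions(
        states=list(cfg["states"]),
        rates=list(cfg["rates"]),
        outputs=list(cfg["outputs"]),
        parameters=dict(cfg["parameters"]),
        initial_state=list(cfg["initial_state"]),
        inputs=list(cfg.get("inputs", ["u"])),
        output_labels=cfg.get("output_labels"),
        name=cfg.get("name", "model"),
    )
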