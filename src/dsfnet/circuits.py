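"""Benchmark genetic-circuit models and perturbation-experiment generation.

Nonlinear ODE models of small synthetic gene circuits (2-4 measured protein
nodes, hidden mRNA states), with equilibrium finding, linearization into the
measured-first partitioned form, stiff-capable simulation, and generation of
serial step-input perturbation experiments with additive measurement noise.

Built-in models
---------------
``iffl_ideal``
    Incoherent feedforward loop (LasR activator, TetR repressor, RFP target)
    with independent first-order enzymatic degradation per protein.
``iffl_crosstalk``
    The same circuit with a shared, saturable protease pool: all three
    degradation reactions compete for the same enzyme, which couples the
    protein states even though no transcriptional cross-regulation exists.
``event_detector``
    Two-input transcriptional event detector: a mutually repressing memory
    module (NIMPLY-logic hybrid promoters) whose two repressor proteins are
    the measured outputs.
``repressilator3``
    A generic three-node cyclic repressor ring with hidden mRNA states,
    per-node gain attenuation, and an optional shared-degradation loading
    term; inputs act as non-degrading inhibitor additions (step inputs).

Rate parameters are used numerically as printed in their sources; the time
unit is treated as abstract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal
from scipy.integrate import solve_ivp
import sympy as sp

from .dsf_core import DSF, PartitionedLTI, derive_dsf

logger = logging.getLogger("dsfnet")

__all__ = [
    "CircuitModel",
    "OperatingPoint",
    "Trajectory",
    "ExperimentSuite",
    "StepDesign",
    "builtin_model",
    "BUILTIN_MODELS",
    "find_equilibrium",
    "linearize",
    "simulate",
    "simulate_linear",
    "generate_experiments",
]


@dataclass
class CircuitModel:
    """A nonlinear ODE circuit model with symbolic vector field.

    States are ordered proteins first, then mRNAs; ``measured_indices``
    selects the fluorescently observable protein states.  The vector field
    is stored symbolically so that both symbolic and finite-difference
    Jacobians are available.
    """

    name: str
    state_names: list[str]
    measured_indices: list[int]
    input_names: list[str]
    parameters: dict[str, float]
    exprs: list[sp.Expr]                 # in x_syms, u_syms, param symbols
    x_syms: list[sp.Symbol]
    u_syms: list[sp.Symbol]

    def __post_init__(self):
        n = len(self.state_names)
        if len(self.exprs) != n or len(self.x_syms) != n:
            raise ValueError("state dimension mismatch")
        if len(set(self.measured_indices)) != len(self.measured_indices):
            raise ValueError("measured_indices must be distinct")
        if any(i < 0 or i >= n for i in self.measured_indices):
            raise ValueError("measured index out of range")
        for k, v in self.parameters.items():
            if not (v > 0):
                raise ValueError(f"parameter {k!r} must be strictly positive, got {v}")
        self._compile()

    def _compile(self):
        subs = {sp.Symbol(k): float(v) for k, v in self.parameters.items()}
        exprs_num = [e.subs(subs) for e in self.exprs]
        X = sp.Matrix(exprs_num)
        jx = X.jacobian(self.x_syms)
        ju = X.jacobian(self.u_syms)
        args = (self.x_syms, self.u_syms)
        self._f = sp.lambdify(args, exprs_num, "numpy")
        self._jx = sp.lambdify(args, jx, "numpy")
        self._ju = sp.lambdify(args, ju, "numpy")

    # -- evaluation --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.state_names)

    @property
    def m(self) -> int:
        return len(self.input_names)

    @property
    def p(self) -> int:
        return len(self.measured_indices)

    @property
    def hidden_indices(self) -> list[int]:
        return [i for i in range(self.n) if i not in self.measured_indices]

    @property
    def measured_names(self) -> list[str]:
        return [self.state_names[i] for i in self.measured_indices]

    def f(self, x, u) -> np.ndarray:
        return np.asarray(self._f(np.asarray(x, float), np.asarray(u, float)),
                          dtype=float).ravel()

    def jac_x(self, x, u) -> np.ndarray:
        return np.asarray(self._jx(np.asarray(x, float), np.asarray(u, float)),
                          dtype=float)

    def jac_u(self, x, u) -> np.ndarray:
        return np.asarray(self._ju(np.asarray(x, float), np.asarray(u, float)),
                          dtype=float)

    def jac_x_fd(self, x, u, h_rel: float = 1e-5) -> np.ndarray:
        """Central finite-difference state Jacobian (independent of sympy)."""
        x = np.asarray(x, dtype=float)
        J = np.empty((self.n, self.n))
        for k in range(self.n):
            h = h_rel * max(1.0, abs(x[k]))
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            J[:, k] = (self.f(xp, u) - self.f(xm, u)) / (2 * h)
        return J

    def jac_u_fd(self, x, u, h_rel: float = 1e-5) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        J = np.empty((self.n, self.m))
        for k in range(self.m):
            h = h_rel * max(1.0, abs(u[k]))
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            J[:, k] = (self.f(x, up) - self.f(x, um)) / (2 * h)
        return J

    def with_overrides(self, overrides: dict[str, float] | None) -> "CircuitModel":
        if not overrides:
            return self
        params = dict(self.parameters)
        for k, v in overrides.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r} for model {self.name!r}")
            params[k] = float(v)
        return CircuitModel(self.name, list(self.state_names),
                            list(self.measured_indices), list(self.input_names),
                            params, list(self.exprs), list(self.x_syms),
                            list(self.u_syms))

    def symbolic_system(self):
        """The raw symbolic vector field (parameters left as symbols)."""
        return list(self.exprs), list(self.x_syms), list(self.u_syms)


@dataclass
class OperatingPoint:
    """A state/input pair the model is linearized about."""

    x: np.ndarray
    u: np.ndarray
    residual_norm: float

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.u = np.asarray(self.u, dtype=float)


@dataclass
class Trajectory:
    """One uniformly sampled perturbation experiment."""

    t: np.ndarray        # uniform time grid
    Y: np.ndarray        # T x p measured outputs
    U: np.ndarray        # T x m applied inputs
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        dts = np.diff(self.t)
        if dts.size and (np.max(dts) - np.min(dts)) > 1e-6 * np.mean(dts):
            raise ValueError("time grid is not uniform")
        if not (np.all(np.isfinite(self.Y)) and np.all(np.isfinite(self.U))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class ExperimentSuite:
    """A set of perturbation trajectories sharing channel names."""

    trajectories: list[Trajectory]
    output_names: list[str]
    input_names: list[str]
    truth: DSF | None = None


# ----------------------------------------------------------------------------
# built-in models
# ----------------------------------------------------------------------------

_IFFL_DEFAULTS = {
    "rho1": 641.4, "rho2": 585.1, "rho3": 652.8,
    "alpha1": 7.8, "alpha2": 7.1, "alpha3": 7.92,
    "k1d": 200.0, "k2d": 200.0, "k3d": 200.0,
    "kMu1": 4000.0, "kMu2": 4000.0, "kMu3": 4000.0,
    "kM2": 200.0,   # TetR repression Michaelis constant (scale of k_d)
    "C0": 1.0, "delta_m": 10.0,
}


def _iffl_exprs(crosstalk: bool):
    x1, x2, x3, m1, m2, m3 = sp.symbols("x1 x2 x3 m1 m2 m3")
    u1, u2, u3 = sp.symbols("u1 u2 u3")
    P = {k: sp.Symbol(k) for k in _IFFL_DEFAULTS}
    if crosstalk:
        # shared protease pool: one saturable denominator for all three tags
        load = 1 + x1 / P["k1d"] + x2 / P["k2d"] + x3 / P["k3d"]
        degr = [P["C0"] * (x / kd) / load
                for x, kd in ((x1, P["k1d"]), (x2, P["k2d"]), (x3, P["k3d"]))]
    else:
        degr = [P["C0"] * (x / kd) / (1 + x / kd)
                for x, kd in ((x1, P["k1d"]), (x2, P["k2d"]), (x3, P["k3d"]))]
    act2 = x1 * u2 / P["kMu2"]
    exprs = [
        P["rho1"] * m1 - degr[0],
        P["rho2"] * m2 - degr[1],
        P["rho3"] * m3 - degr[2],
        P["alpha1"] * u1 / (P["kMu1"] + u1) - P["delta_m"] * m1,
        P["alpha2"] * act2 / (1 + act2) - P["delta_m"] * m2,
        P["alpha3"] * act2 / (1 + act2 + x2 / (P["kM2"] + u3 / P["kMu3"]))
        - P["delta_m"] * m3,
    ]
    return ([x1, x2, x3, m1, m2, m3], [u1, u2, u3], exprs)


_EVENT_DEFAULTS = {
    # implementation defaults (abstract units)
    "k1": 10.0, "k2": 10.0, "k3": 10.0, "k4": 10.0,
    "kl": 0.01, "rho1": 5.0, "rho2": 5.0, "rho3": 5.0, "rho4": 5.0,
    "delta_p": 0.1, "delta_m": 1.0,
    "kMu1": 1000.0, "kMu2": 1000.0, "kM2": 1000.0, "kM3": 1000.0,
}


def _event_exprs():
    xs = sp.symbols("x1 x2 x3 x4")
    ms = sp.symbols("m1 m2 m3 m4")
    u1, u2 = sp.symbols("u1 u2")
    P = {k: sp.Symbol(k) for k in _EVENT_DEFAULTS}
    x1, x2, x3, x4 = xs
    m1, m2, m3, m4 = ms
    exprs = [
        P["rho1"] * m1 - P["delta_p"] * x1,
        P["rho2"] * m2 - P["delta_p"] * x2,
        P["rho3"] * m3 - P["delta_p"] * x3,
        P["rho4"] * m4 - P["delta_p"] * x4,
        P["k1"] * (P["kl"] + u1 / P["kMu1"]) / (1 + u1 / P["kMu1"])
        - P["delta_m"] * m1,
        P["k2"] * (P["kl"] + u1 / P["kMu1"]) / (1 + x3 / P["kM3"] + u1 / P["kMu1"])
        - P["delta_m"] * m2,
        P["k3"] * (P["kl"] + u2 / P["kMu2"]) / (1 + x2 / P["kM2"] + u2 / P["kMu2"])
        - P["delta_m"] * m3,
        P["k4"] * (P["kl"] + u2 / P["kMu2"]) / (1 + u2 / P["kMu2"])
        - P["delta_m"] * m4,
    ]
    return (list(xs) + list(ms), [u1, u2], exprs)


_REP3_DEFAULTS = {
    "beta": 20.0, "rho": 1.0, "delta_p": 0.5, "delta_m": 1.0,
    "K": 100.0, "Ku": 100.0, "hill": 2.0,
    "atten1": 1.0, "atten2": 1.0, "atten3": 1.0,
    # shared-degradation loading scale; the default is large enough that
    # loading is negligible unless deliberately lowered
    "K_load": 1e9,
}


def _rep3_exprs():
    x1, x2, x3, m1, m2, m3 = sp.symbols("x1 x2 x3 m1 m2 m3")
    u1, u2, u3 = sp.symbols("u1 u2 u3")
    P = {k: sp.Symbol(k) for k in _REP3_DEFAULTS}
    load = 1 + (x1 + x2 + x3) / P["K_load"]
    repress = {  # node i repressed by predecessor: y1<-y3, y2<-y1, y3<-y2
        1: x3, 2: x1, 3: x2,
    }
    att = {1: P["atten1"], 2: P["atten2"], 3: P["atten3"]}
    u = {1: u1, 2: u2, 3: u3}
    exprs_x = [P["rho"] * m - P["delta_p"] * x / load
               for x, m in ((x1, m1), (x2, m2), (x3, m3))]
    exprs_m = [
        P["beta"] * att[i] / (1 + (repress[i] / P["K"]) ** P["hill"] + u[i] / P["Ku"])
        - P["delta_m"] * sp.Symbol(f"m{i}")
        for i in (1, 2, 3)
    ]
    return ([x1, x2, x3, m1, m2, m3], [u1, u2, u3], exprs_x + exprs_m)


def _make_builtin(name: str) -> CircuitModel:
    if name == "iffl_ideal":
        xs, us, exprs = _iffl_exprs(crosstalk=False)
        defaults = _IFFL_DEFAULTS
        measured = [0, 1, 2]
    elif name == "iffl_crosstalk":
        xs, us, exprs = _iffl_exprs(crosstalk=True)
        defaults = _IFFL_DEFAULTS
        measured = [0, 1, 2]
    elif name == "event_detector":
        xs, us, exprs = _event_exprs()
        defaults = _EVENT_DEFAULTS
        measured = [1, 2]  # x2 (TetR reporter) and x3 (LacI reporter)
    elif name == "repressilator3":
        xs, us, exprs = _rep3_exprs()
        defaults = _REP3_DEFAULTS
        measured = [0, 1, 2]
    else:
        raise ValueError(f"unknown builtin model {name!r}")
    return CircuitModel(
        name=name,
        state_names=[str(s) for s in xs],
        measured_indices=measured,
        input_names=[str(u) for u in us],
        parameters=dict(defaults),
        exprs=exprs,
        x_syms=xs,
        u_syms=us,
    )


BUILTIN_MODELS = ("iffl_ideal", "iffl_crosstalk", "event_detector", "repressilator3")


def builtin_model(name: str, overrides: dict[str, float] | None = None) -> CircuitModel:
    """Construct a built-in benchmark model, optionally overriding parameters."""
    return _make_builtin(name).with_overrides(overrides)


# ----------------------------------------------------------------------------
# equilibria and linearization
# ----------------------------------------------------------------------------

def find_equilibrium(model: CircuitModel, u_fixed, x_guess=None,
                     tol: float = 1e-9, max_restarts: int = 12) -> OperatingPoint:
    """Solve f(x_e, u_fixed) = 0 with multi-start root finding.

    Restarts rescale the initial guess over log-spaced factors; the accepted
    root must satisfy ||f||_inf < tol * (1 + ||x_e||_inf).
    """
    u_fixed = np.asarray(u_fixed, dtype=float)
    if np.any(u_fixed < 0):
        raise ValueError("inputs must be nonnegative")
    if x_guess is None:
        x_guess = np.ones(model.n)
    x_guess = np.asarray(x_guess, dtype=float)

    guesses = [x_guess, np.zeros(model.n)]
    for fac in np.logspace(-2, 3, max_restarts - 2):
        guesses.append(np.maximum(x_guess, 1.0) * fac)
    best = None
    for g in guesses:
        try:
            sol = scipy.optimize.root(
                lambda x: model.f(x, u_fixed), g,
                jac=lambda x: model.jac_x(x, u_fixed), method="hybr",
            )
        except (FloatingPointError, ValueError):
            continue
        if not sol.success:
            continue
        res = np.max(np.abs(model.f(sol.x, u_fixed)))
        scale = 1.0 + np.max(np.abs(sol.x))
        if res < tol * scale and np.all(sol.x > -1e-9 * scale):
            return OperatingPoint(np.maximum(sol.x, 0.0) if np.min(sol.x) < 0 else sol.x,
                                  u_fixed, float(res))
        if best is None or res < best[0]:
            best = (res, sol.x)
    raise RuntimeError(
        f"equilibrium search failed for {model.name!r}: best residual "
        f"{best[0]:.3e}" if best else "no solver progress"
    )


def linearize(model: CircuitModel, op: OperatingPoint,
              method: str = "symbolic", residual_warn: float = 1e-6) -> PartitionedLTI:
    """Jacobian linearization about an operating point, measured states first.

    Non-equilibrium operating points are allowed (transient or oscillatory
    regimes are legitimate linearization targets); a warning is issued when
    the vector-field residual is large.
    """
    res = np.max(np.abs(model.f(op.x, op.u)))
    if res > residual_warn * (1.0 + np.max(np.abs(op.x))):
        warnings.warn(
            f"linearizing about a non-equilibrium point (||f||_inf = {res:.3e})",
            stacklevel=2,
        )
    if method == "symbolic":
        A = model.jac_x(op.x, op.u)
        B = model.jac_u(op.x, op.u)
    elif method == "fd":
        A = model.jac_x_fd(op.x, op.u)
        B = model.jac_u_fd(op.x, op.u)
    else:
        raise ValueError(f"unknown linearization method {method!r}")
    perm = list(model.measured_indices) + model.hidden_indices
    A = A[np.ix_(perm, perm)]
    B = B[perm, :]
    p = model.p
    return PartitionedLTI(
        A[:p, :p], A[:p, p:], A[p:, :p], A[p:, p:], B[:p, :], B[p:, :],
        output_names=model.measured_names,
        input_names=list(model.input_names),
        hidden_names=[model.state_names[i] for i in model.hidden_indices],
    )


# ----------------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------------

def _input_function(t_breaks, u_values):
    """Piecewise-constant input: u(t) = u_values[k] on [t_breaks[k], t_breaks[k+1])."""
    t_breaks = np.asarray(t_breaks, dtype=float)
    u_values = np.atleast_2d(np.asarray(u_values, dtype=float))

    def u_of_t(t):
        k = int(np.searchsorted(t_breaks, t, side="right") - 1)
        return u_values[max(k, 0)]

    return u_of_t


def simulate(model: CircuitModel, input_schedule, x0, t_grid,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the nonlinear model under a piecewise-constant input schedule.

    ``input_schedule`` is a pair ``(t_breaks, u_values)`` with break times
    (the first must be <= t_grid[0]) and the held input vector on each
    interval.  Integration is segment-wise with a stiff (BDF) method so step
    discontinuities never cross an integrator step.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t_breaks, u_values = input_schedule
    t_breaks = np.asarray(t_breaks, dtype=float)
    u_values = np.atleast_2d(np.asarray(u_values, dtype=float))
    u_of_t = _input_function(t_breaks, u_values)

    edges = np.unique(np.concatenate([[t_grid[0], t_grid[-1]],
                                      t_breaks[(t_breaks > t_grid[0])
                                               & (t_breaks < t_grid[-1])]]))
    x = np.asarray(x0, dtype=float).copy()
    X = np.empty((t_grid.size, model.n))
    filled = np.zeros(t_grid.size, dtype=bool)
    if np.isclose(t_grid[0], edges[0]):
        X[0] = x
        filled[0] = True
    for a, b in zip(edges[:-1], edges[1:]):
        u_seg = u_of_t((a + b) / 2.0)
        mask = (t_grid > a + 1e-12 * max(1.0, abs(a))) & (t_grid <= b)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            lambda t, xx: model.f(xx, u_seg), (a, b), x,
            method="BDF", jac=lambda t, xx: model.jac_x(xx, u_seg),
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{a:g}, {b:g}] for model "
                f"{model.name!r}: {sol.message}"
            )
        if t_eval.size:
            X[mask] = sol.y.T
            filled[mask] = True
        x = sol.y[:, -1] if sol.y.size else x
    if not np.all(filled):
        raise RuntimeError("simulation did not cover the whole time grid")
    U = np.vstack([u_of_t(t) for t in t_grid])
    Y = X[:, model.measured_indices]
    return Trajectory(t_grid, Y, U, metadata={"model": model.name})


def simulate_linear(sys: PartitionedLTI, U: np.ndarray, dt: float) -> np.ndarray:
    """Exact response of the linearized system to a piecewise-constant input
    held over each sample; returns measured deviations (T x p), x(0) = 0."""
    A, B = sys.A, sys.B
    C = np.eye(A.shape[0])
    D = np.zeros((A.shape[0], B.shape[1]))
    Ad, Bd, _, _, _ = scipy.signal.cont2discrete((A, B, C, D), dt)
    U = np.atleast_2d(np.asarray(U, dtype=float))
    T = U.shape[0]
    x = np.zeros(A.shape[0])
    out = np.empty((T, sys.p))
    for k in range(T):
        out[k] = x[: sys.p]
        x = Ad @ x + Bd @ U[k]
    return out


# ----------------------------------------------------------------------------
# perturbation experiment generation
# ----------------------------------------------------------------------------

@dataclass
class StepDesign:
    """Serial step-input perturbation design.

    One perturbation channel per measured node.  ``amplitudes[i]`` is the
    step size applied to channel i at time ``onsets[i]``; steps are held to
    the end of the trace unless ``duration`` is given (added inhibitor does
    not degrade, so a hold is the physical default).  ``mode`` selects a
    single trajectory with staggered steps (``"serial"``) or one trajectory
    per perturbed node (``"separate"``).

    ``input_mode`` chooses what a channel physically is.  ``"direct"`` (the
    default) is an additive rate perturbation injected straight into the
    measured node -- the in-vitro "pipette a small amount of inhibitor at
    node i" design -- which realizes an exactly diagonal control structure
    P(s) as the identifiability conditions require.  ``"model"`` steps the
    circuit's own inducer inputs instead; note that shared promoters can
    make the resulting P(s) non-diagonal (one inducer driving two genes),
    in which case the structured estimator is misspecified.
    """

    amplitudes: np.ndarray
    onsets: np.ndarray
    dt: float
    t_end: float
    u_baseline: np.ndarray
    duration: float | None = None
    mode: str = "serial"
    input_mode: str = "direct"

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.u_baseline = np.asarray(self.u_baseline, dtype=float)
        if self.mode not in ("serial", "separate"):
            raise ValueError("mode must be 'serial' or 'separate'")
        if self.input_mode not in ("direct", "model"):
            raise ValueError("input_mode must be 'direct' or 'model'")
        if self.amplitudes.size != self.onsets.size:
            raise ValueError("amplitudes and onsets must have equal length")


def _schedule_for(design: StepDesign, channels: list[int], m: int):
    """Break times and held input vectors for steps on the given channels."""
    events = []
    for ch in channels:
        on = design.onsets[ch]
        events.append((on, ch, design.amplitudes[ch]))
        if design.duration is not None:
            events.append((on + design.duration, ch, -design.amplitudes[ch]))
    events.sort()
    t_breaks = [0.0]
    u = design.u_baseline.astype(float).copy()
    u_values = [u.copy()]
    for t_ev, ch, amp in events:
        u = u.copy()
        u[ch] += amp
        t_breaks.append(t_ev)
        u_values.append(u)
    return np.array(t_breaks), np.array(u_values)


def generate_experiments(model: CircuitModel, design: StepDesign,
                         noise_sd: float = 0.0, seed: int = 0,
                         linearized: bool = False, noise_relative: bool = False,
                         attach_truth: bool = True,
                         op: OperatingPoint | None = None) -> ExperimentSuite:
    """Simulate step-perturbation experiments around an operating point.

    The system is settled at its equilibrium under the baseline input, then
    each measured node's input channel receives a step per ``design``.
    Additive i.i.d. Gaussian noise (sd ``noise_sd``; interpreted as a
    fraction of each channel's peak deviation when ``noise_relative``) is
    applied to the measured outputs only.  With ``linearized=True`` the
    response is generated from the linearized model (exact discrete-time
    stepping); otherwise the full nonlinear ODE is integrated.

    The ground-truth DSF of the linearization is attached to the suite when
    ``attach_truth`` is set.
    """
    if design.amplitudes.size < model.p or np.count_nonzero(design.amplitudes) < model.p:
        warnings.warn(
            "fewer perturbed nodes than measured outputs: the estimation "
            "problem will not be identifiable (needs p-1 known entries per "
            "column)", stacklevel=2,
        )
    if op is None:
        op = find_equilibrium(model, design.u_baseline)
    sys_model = linearize(model, op)
    direct = design.input_mode == "direct"
    if direct:
        # additive per-node rate perturbations: B1 = I, B2 = 0, so the
        # control structure P = (sI - D)^-1 is exactly diagonal
        sys = PartitionedLTI(
            sys_model.A11, sys_model.A12, sys_model.A21, sys_model.A22,
            np.eye(model.p), np.zeros((model.n - model.p, model.p)),
            output_names=model.measured_names,
            input_names=[f"d:{n}" for n in model.measured_names],
            hidden_names=list(sys_model.hidden_names),
        )
        pert_baseline = np.zeros(model.p)
    else:
        sys = sys_model
        pert_baseline = design.u_baseline
    truth = derive_dsf(sys) if attach_truth else None

    t_grid = np.arange(0.0, design.t_end + 0.5 * design.dt, design.dt)
    rng = np.random.default_rng(seed)
    channel_sets = ([list(range(model.p))] if design.mode == "serial"
                    else [[i] for i in range(model.p)])

    trajectories = []
    for channels in channel_sets:
        base_design = design if not direct else StepDesign(
            design.amplitudes, design.onsets, design.dt, design.t_end,
            pert_baseline, design.duration, design.mode, "direct")
        t_breaks, u_values = _schedule_for(base_design, channels, sys.m)
        if linearized:
            u_of_t = _input_function(t_breaks, u_values)
            U = np.vstack([u_of_t(t) for t in t_grid])
            dY = simulate_linear(sys, U - pert_baseline, design.dt)
            Y = op.x[model.measured_indices] + dY
            traj = Trajectory(t_grid, Y, U)
        elif direct:
            traj = _simulate_direct(model, op, (t_breaks, u_values), t_grid)
        else:
            traj = simulate(model, (t_breaks, u_values), op.x, t_grid)
        clean = traj.Y.copy()
        if noise_sd > 0:
            if noise_relative:
                amp = np.max(np.abs(clean - clean[0]), axis=0)
                sd = noise_sd * np.where(amp > 0, amp, 1.0)
            else:
                sd = np.full(model.p, noise_sd)
            traj.Y = clean + rng.standard_normal(clean.shape) * sd
        first_onset = np.min(design.onsets[channels])
        baseline_n = int(np.searchsorted(t_grid, first_onset))
        traj.metadata.update({
            "seed": seed, "noise_sd": noise_sd, "noise_relative": noise_relative,
            "baseline_n": baseline_n, "model": model.name,
            "linearized": linearized,
        })
        trajectories.append(traj)
    return ExperimentSuite(trajectories, model.measured_names,
                           list(sys.input_names), truth)


def symbolic_dsf(model: CircuitModel, param_subs: dict | None = None):
    """Fully symbolic DSF of a circuit model at a general symbolic point.

    Linearizes the symbolic vector field (parameters left as symbols unless
    ``param_subs`` maps them), reorders measured states first, eliminates the
    hidden block symbolically and returns ``(Q, P, s)`` as sympy matrices.
    Intended for structural verification on small models; the numeric path
    is orders of magnitude faster for simulation work.
    """
    from .dsf_core import compute_QP_symbolic, compute_WV_symbolic

    exprs, xs, us = model.symbolic_system()
    if param_subs:
        subs = {sp.Symbol(k) if isinstance(k, str) else k: v
                for k, v in param_subs.items()}
        exprs = [e.subs(subs) for e in exprs]
    F = sp.Matrix(exprs)
    A = F.jacobian(xs)
    B = F.jacobian(us)
    perm = list(model.measured_indices) + model.hidden_indices
    A = A.extract(perm, perm)
    B = B.extract(perm, list(range(model.m)))
    p = model.p
    W, V, s = compute_WV_symbolic(A[:p, :p], A[:p, p:], A[p:, :p], A[p:, p:],
                                  B[:p, :], B[p:, :])
    Q, P = compute_QP_symbolic(W, V, s)
    return Q, P, s


IFFL_BASELINE_INPUT = np.array([1.6, 0.02, 4.0])
"""Reference inducer baseline for the feedforward-loop studies.

Chosen so that both the ideal and the shared-protease circuit have stable,
well-separated positive equilibria: total protease demand stays below the
saturable capacity (the loaded circuit loses its equilibrium entirely at
roughly 1.5x these levels), and every designed edge carries a worst-case
gain at least ~20% of the largest.
"""


def iffl_study_designs(n_rep: int = 12, dt: float = 10.0,
                       amplitude: float = 0.013,
                       t_end: float = 26500.0) -> list[StepDesign]:
    """Replicated serial-perturbation designs for the feedforward-loop study.

    Each replicate is a single trajectory with one direct (additive-rate)
    step per measured node, applied in series; replicates rotate the onset
    order and alternate held steps with finite pulses so the stacked
    regression sees excitation from different mixing patterns.  Onsets are
    spaced several times the slowest closed-loop time constant apart.
    """
    onset_patterns = [np.array([2500.0, 10500.0, 18500.0]),
                      np.array([18500.0, 2500.0, 10500.0]),
                      np.array([10500.0, 18500.0, 2500.0])]
    amps = np.full(3, amplitude)
    out = []
    for k in range(n_rep):
        out.append(StepDesign(
            amplitudes=amps, onsets=onset_patterns[k % 3], dt=dt, t_end=t_end,
            u_baseline=IFFL_BASELINE_INPUT.copy(),
            duration=None if (k // 3) % 2 == 0 else 4000.0,
            mode="serial", input_mode="direct"))
    return out


def build_replicate_suite(model: CircuitModel, designs: list[StepDesign],
                          noise_sd: float, seed: int, linearized: bool = True,
                          op: OperatingPoint | None = None) -> ExperimentSuite:
    """Stack several perturbation designs into one suite (N_exp replicates).

    Noise streams are independent across replicates (seed offset per
    design); the ground-truth DSF of the first design is attached.
    """
    if op is None:
        op = find_equilibrium(model, designs[0].u_baseline)
    trajs = []
    truth = None
    names = None
    for r, ds in enumerate(designs):
        s = generate_experiments(model, ds, noise_sd=noise_sd,
                                 seed=seed * 100 + r, linearized=linearized,
                                 noise_relative=True, op=op,
                                 attach_truth=(r == 0))
        trajs += s.trajectories
        if r == 0:
            truth = s.truth
        names = (s.output_names, s.input_names)
    return ExperimentSuite(trajs, names[0], names[1], truth)


def _simulate_direct(model: CircuitModel, op: OperatingPoint, schedule,
                     t_grid, rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Nonlinear simulation with additive per-node rate perturbations."""
    t_breaks, d_values = schedule
    d_of_t = _input_function(t_breaks, d_values)
    E = np.zeros((model.n, model.p))
    for k, idx in enumerate(model.measured_indices):
        E[idx, k] = 1.0
    t_grid = np.asarray(t_grid, dtype=float)
    edges = np.unique(np.concatenate([[t_grid[0], t_grid[-1]],
                                      np.asarray(t_breaks)[(np.asarray(t_breaks) > t_grid[0])
                                                           & (np.asarray(t_breaks) < t_grid[-1])]]))
    x = op.x.copy()
    X = np.empty((t_grid.size, model.n))
    filled = np.zeros(t_grid.size, dtype=bool)
    if np.isclose(t_grid[0], edges[0]):
        X[0] = x
        filled[0] = True
    for a, b in zip(edges[:-1], edges[1:]):
        d_seg = E @ d_of_t((a + b) / 2.0)
        mask = (t_grid > a + 1e-12 * max(1.0, abs(a))) & (t_grid <= b)
        t_eval = t_grid[mask]
        sol = solve_ivp(lambda t, xx: model.f(xx, op.u) + d_seg, (a, b), x,
                        method="BDF", jac=lambda t, xx: model.jac_x(xx, op.u),
                        t_eval=t_eval if t_eval.size else None,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a:g}, {b:g}]: {sol.message}")
        if t_eval.size:
            X[mask] = sol.y.T
            filled[mask] = True
        x = sol.y[:, -1] if sol.y.size else x
    if not np.all(filled):
        raise RuntimeError("simulation did not cover the whole time grid")
    D = np.vstack([d_of_t(t) for t in t_grid])
    return Trajectory(t_grid, X[:, model.measured_indices], D,
                      metadata={"model": model.name, "input_mode": "direct"})
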