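"""Direct data-driven estimation of dynamical structure functions.

The estimator works row by row.  For measured output i, the discrete-time
DSF row is an ARX-form model with one shared characteristic polynomial of
order ``n_d``:

    y_i[t] = -a_1 y_i[t-1] - ... - a_nd y_i[t-nd]
             + sum_{j != i} ( b_1^(ij) y_j[t-1] + ... + b_nd^(ij) y_j[t-nd] )
             + c_1^(i) u_i[t-1] + ... + c_nd^(i) u_i[t-nd],

i.e. Q_ij(z) and P_ii(z) share the denominator z^nd + a_1 z^(nd-1) + ... +
a_nd and have numerator degree <= nd - 1 (strict properness).  The diagonal
of Q and the off-diagonal of P are structural zeros: they are simply never
given regressors, so the estimates are exactly zero by construction.

Stacking the equation over timepoints and experiments gives the normal form
B = X Theta, solved by rank-revealing least squares.  Two hyperparameters
are searched: the model order ``n_d`` and the number of retained subsampled
timepoints ``h_max`` per trace (densely sampled slow transients produce
near-duplicate rows and an ill-conditioned X; equal-stride subsampling to
h_max points is the conditioning control).  Selection minimizes the n-step
(free-run) L1 prediction error on a held-out final segment of each trace.

A standard discrete-to-continuous transformation (bilinear/Tustin by
default; zero-order-hold and matched-pole alternatives) maps the estimates
back to (Q(s), P(s)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .circuits import ExperimentSuite, Trajectory
from .dsf_core import DSF
from .tfalgebra import RationalFunction, TransferMatrix

logger = logging.getLogger("dsfnet")

__all__ = [
    "DiscreteRow",
    "DiscreteDSF",
    "EstimationConfig",
    "FitReport",
    "IdentifiabilityReport",
    "diagonal_p_mask",
    "check_identifiability",
    "detrend",
    "build_row_regression",
    "fit_dsf",
    "to_continuous",
    "discretize",
    "predict_score",
    "simulate_discrete",
    "random_discrete_dsf",
]


# ----------------------------------------------------------------------------
# types
# ----------------------------------------------------------------------------

@dataclass
class DiscreteRow:
    """One output row of a discrete-time DSF in ARX form."""

    output_index: int
    a: np.ndarray                      # (nd,) shared characteristic coefficients
    q_num: dict[int, np.ndarray]       # j -> (nd,) numerator of Q_ij(z), j != i
    p_num: dict[int, np.ndarray]       # input index -> (nd,) numerator of P_ij(z)
    dt: float

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.q_num = {int(j): np.asarray(v, dtype=float) for j, v in self.q_num.items()}
        self.p_num = {int(j): np.asarray(v, dtype=float) for j, v in self.p_num.items()}
        if self.output_index in self.q_num:
            raise ValueError("Q diagonal blocks are structural zeros")
        nd = self.a.size
        for blk in (*self.q_num.values(), *self.p_num.values()):
            if blk.size != nd:
                raise ValueError("numerator block length must equal n_d")

    @property
    def nd(self) -> int:
        return self.a.size

    def denominator(self) -> np.ndarray:
        """z^nd + a_1 z^(nd-1) + ... + a_nd, descending powers."""
        return np.concatenate(([1.0], self.a))


@dataclass
class DiscreteDSF:
    """Row-wise discrete-time DSF estimate.

    Each row may carry its own sampling interval (rows are fitted with their
    own subsampling stride); ``dt`` is the common interval when uniform.
    """

    rows: list[DiscreteRow]
    output_names: list[str]
    input_names: list[str]

    @property
    def p(self) -> int:
        return len(self.rows)

    @property
    def m(self) -> int:
        return len(self.input_names)

    @property
    def dt(self) -> float | None:
        dts = {r.dt for r in self.rows}
        return dts.pop() if len(dts) == 1 else None

    def q_entry(self, i: int, j: int) -> RationalFunction:
        row = self.rows[i]
        if j == i or j not in row.q_num:
            return RationalFunction.zero("z")
        return RationalFunction(row.q_num[j], row.denominator(), "z")

    def p_entry(self, i: int, j: int) -> RationalFunction:
        row = self.rows[i]
        if j not in row.p_num:
            return RationalFunction.zero("z")
        return RationalFunction(row.p_num[j], row.denominator(), "z")

    def as_transfer_matrices(self) -> tuple[TransferMatrix, TransferMatrix]:
        Q = TransferMatrix([[self.q_entry(i, j) for j in range(self.p)]
                            for i in range(self.p)],
                           list(self.output_names), list(self.output_names))
        P = TransferMatrix([[self.p_entry(i, j) for j in range(self.m)]
                            for i in range(self.p)],
                           list(self.output_names), list(self.input_names))
        return Q, P


@dataclass
class EstimationConfig:
    """Hyperparameter grids and numerical guards for the estimator."""

    nd_grid: tuple = (1, 2, 3, 4, 5, 6)
    hmax_grid: tuple = (None,)        # None = keep every timepoint
    horizon: int | None = None        # free-run scoring horizon; None = holdout length
    holdout_frac: float = 0.25
    rcond: float = 1e-10              # rank-revealing least-squares threshold
    cond_warn: float = 1e8
    cond_max: float = 1e12            # grid points with cond(X) above this are rejected
    ridge: float = 0.0                # optional Tikhonov weight (0 = plain LS)
    tie_rtol: float = 1e-6            # scores within this relative band tie -> smaller n_d

    def __post_init__(self):
        if not self.nd_grid or not self.hmax_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.horizon is not None and self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class RowFit:
    """Diagnostics for one accepted row fit."""

    output_index: int
    nd: int
    hmax: int | None
    cond: float
    train_l1: float
    nstep_l1: float
    accuracy: float
    n_rows: int
    grid: list = field(default_factory=list)  # (nd, hmax, cond, score | None reason)


@dataclass
class FitReport:
    rows: list[RowFit]
    n_exp: int
    identifiable: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class IdentifiabilityReport:
    p: int
    m: int
    known_per_column: np.ndarray
    required: int
    identifiable: bool
    columns_ok: np.ndarray


# ----------------------------------------------------------------------------
# identifiability
# ----------------------------------------------------------------------------

def diagonal_p_mask(p: int, m: int) -> np.ndarray:
    """Known-entry mask for the standard design: P diagonal (off-diagonal
    entries known to be zero), Q fully unknown.  Shape (p+m) x p, column i
    listing the entries of row i of [Q P]."""
    mask = np.zeros((p + m, p), dtype=bool)
    for i in range(p):
        for j in range(m):
            if j != i:
                mask[p + j, i] = True
    return mask


def check_identifiability(p: int, m: int,
                          known_mask: np.ndarray | None = None) -> IdentifiabilityReport:
    """Reconstruction is possible iff at least p-1 entries in each column of
    [Q(s) P(s)]* are known a priori.

    With no prior knowledge, only the trivial p = 1 case is identifiable.
    The standard diagonal-P perturbation design (every node independently
    perturbed) passes whenever m = p.
    """
    if known_mask is None:
        known_mask = np.zeros((p + m, p), dtype=bool)
    known_mask = np.asarray(known_mask, dtype=bool)
    if known_mask.shape != (p + m, p):
        raise ValueError(f"known_mask must have shape ({p + m}, {p})")
    counts = known_mask.sum(axis=0)
    ok = counts >= (p - 1)
    return IdentifiabilityReport(p, m, counts, p - 1, bool(np.all(ok)), ok)


# ----------------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------------

def detrend(suite: ExperimentSuite, baseline_window: int | None = None) -> ExperimentSuite:
    """Subtract the pre-perturbation baseline from every channel.

    The linearized model applies to deviations with zero initial condition,
    so the per-channel mean over the baseline window (the samples before the
    first perturbation onset) is removed from Y, and the corresponding mean
    input level from U.
    """
    out = []
    for traj in suite.trajectories:
        nb = baseline_window if baseline_window is not None else traj.metadata.get("baseline_n", 0)
        if nb is None or nb < 1:
            raise ValueError("empty baseline window: record baseline_n or pass baseline_window")
        y0 = traj.Y[:nb].mean(axis=0)
        u0 = traj.U[:nb].mean(axis=0)
        meta = dict(traj.metadata)
        meta.update({"detrended": True, "y_baseline": y0, "u_baseline_level": u0,
                     "baseline_n": nb})
        out.append(Trajectory(traj.t.copy(), traj.Y - y0, traj.U - u0, meta))
    return ExperimentSuite(out, list(suite.output_names), list(suite.input_names),
                           suite.truth)


def _block_mean(A: np.ndarray, stride: int) -> np.ndarray:
    T = (A.shape[0] // stride) * stride
    return A[:T].reshape(-1, stride, A.shape[1]).mean(axis=1)


def _subsample(traj: Trajectory, hmax: int | None):
    """Equal-stride decimation to at most hmax retained timepoints.

    Each retained point is the mean of its stride block (anti-aliased
    decimation).  Averaging is a linear filter applied identically to every
    output and input channel, so the LTI relation between them is
    preserved while per-sample noise shrinks by sqrt(stride).
    Returns (Y, U, dt_effective).
    """
    T = traj.t.size
    stride = 1 if hmax is None or hmax >= T else int(np.ceil(T / hmax))
    if stride == 1:
        return traj.Y, traj.U, traj.dt
    return (_block_mean(traj.Y, stride), _block_mean(traj.U, stride),
            traj.dt * stride)


def _own_input_index(suite: ExperimentSuite, i: int) -> int:
    """Input channel perturbing output i (diagonal-P design: same index)."""
    if i >= len(suite.input_names):
        raise ValueError(
            f"no input channel for output {suite.output_names[i]!r}: the "
            "diagonal-P design needs one input per measured node"
        )
    return i


def _row_blocks(Y, U, i, own_u, nd):
    """Regressor matrix and target for one (subsampled) trace."""
    T, p = Y.shape
    if T <= nd + 1:
        raise ValueError(f"trace too short after subsampling: {T} samples for n_d={nd}")
    t_idx = np.arange(nd, T)
    cols = []
    for k in range(1, nd + 1):
        cols.append(-Y[t_idx - k, i])
    for j in range(p):
        if j == i:
            continue
        for k in range(1, nd + 1):
            cols.append(Y[t_idx - k, j])
    for k in range(1, nd + 1):
        cols.append(U[t_idx - k, own_u])
    X = np.column_stack(cols)
    b = Y[t_idx, i]
    return X, b


def build_row_regression(suite: ExperimentSuite, i: int, nd: int,
                         hmax: int | None = None):
    """Stacked normal-form regression (X, b) for output row i.

    Columns: nd lagged own-output samples, nd lagged samples of every other
    output (Q numerators), nd lagged samples of the row's own input (P
    numerator); structural zeros (Q diagonal, P off-diagonal) have no
    columns.  Rows stack over all experiments.
    """
    own_u = _own_input_index(suite, i)
    Xs, bs = [], []
    for traj in suite.trajectories:
        Y, U, _ = _subsample(traj, hmax)
        X, b = _row_blocks(Y, U, i, own_u, nd)
        Xs.append(X)
        bs.append(b)
    X = np.vstack(Xs)
    b = np.concatenate(bs)
    col_scale = np.max(np.abs(X), axis=0)
    col_sd = np.std(X, axis=0)
    degenerate = (col_scale > 0) & (col_sd < 1e-12 * np.maximum(col_scale, 1.0))
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} regressor column(s) are constant; the "
            "normal form is rank deficient", stacklevel=2,
        )
    return X, b


def _col_scale(X: np.ndarray) -> np.ndarray:
    """Per-column scale factors (max-abs); zero columns get scale 1."""
    cs = np.max(np.abs(X), axis=0)
    cs[cs == 0.0] = 1.0
    return cs


def _cond(X: np.ndarray) -> float:
    """Condition number of the column-normalized regression matrix.

    Column scaling removes the (arbitrary) channel units so the number
    reflects genuine regressor collinearity.
    """
    if X.size == 0 or np.max(np.abs(X)) == 0.0:
        return 0.0
    s = np.linalg.svd(X / _col_scale(X), compute_uv=False)
    smin = s[s > 0].min() if np.any(s > 0) else 0.0
    return float(s[0] / smin) if smin > 0 else np.inf


def _solve(X, b, config: EstimationConfig):
    """Rank-revealing least squares on the column-normalized problem."""
    if np.max(np.abs(X)) == 0.0:
        return np.zeros(X.shape[1])
    cs = _col_scale(X)
    Xs = X / cs
    if config.ridge > 0:
        G = Xs.T @ Xs + config.ridge * np.eye(Xs.shape[1])
        theta = np.linalg.solve(G, Xs.T @ b)
    else:
        theta, *_ = np.linalg.lstsq(Xs, b, rcond=config.rcond)
    return theta / cs


def _theta_to_row(theta, i, p, own_u, nd, dt) -> DiscreteRow:
    a = theta[:nd]
    q_num = {}
    pos = nd
    for j in range(p):
        if j == i:
            continue
        q_num[j] = theta[pos:pos + nd]
        pos += nd
    p_num = {own_u: theta[pos:pos + nd]}
    return DiscreteRow(i, a, q_num, p_num, dt)


def _row_theta(row: DiscreteRow, p: int, own_u: int) -> np.ndarray:
    parts = [row.a]
    for j in range(p):
        if j != row.output_index:
            parts.append(row.q_num[j])
    parts.append(row.p_num[own_u])
    return np.concatenate(parts)


# ----------------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------------

def _predict_row(row: DiscreteRow, Y, U, own_u, mode: str, start: int,
                 horizon: int | None = None):
    """Predictions for one row on a (subsampled, detrended) trace.

    one_step: every lag comes from measured data.  free_run: from ``start``
    on, the row's own output is fed back recursively; other outputs and the
    input stay measured (the row model is a p x 1 MISO system).
    Returns (t_indices, predictions).
    """
    nd = row.nd
    T = Y.shape[0]
    i = row.output_index
    start = max(start, nd)
    stop = T if horizon is None else min(T, start + horizon)
    t_idx = np.arange(start, stop)
    if t_idx.size == 0:
        raise ValueError("prediction horizon exceeds trace length")
    if mode == "one_step":
        preds = np.empty(t_idx.size)
        for n, t in enumerate(t_idx):
            acc = -np.dot(row.a, Y[t - np.arange(1, nd + 1), i])
            for j, bq in row.q_num.items():
                acc += np.dot(bq, Y[t - np.arange(1, nd + 1), j])
            acc += np.dot(row.p_num[own_u], U[t - np.arange(1, nd + 1), own_u])
            preds[n] = acc
        return t_idx, preds
    if mode == "free_run":
        own = Y[:, i].astype(float).copy()
        preds = np.empty(t_idx.size)
        for n, t in enumerate(t_idx):
            acc = -np.dot(row.a, own[t - np.arange(1, nd + 1)])
            for j, bq in row.q_num.items():
                acc += np.dot(bq, Y[t - np.arange(1, nd + 1), j])
            acc += np.dot(row.p_num[own_u], U[t - np.arange(1, nd + 1), own_u])
            own[t] = acc
            preds[n] = acc
        return t_idx, preds
    raise ValueError(f"unknown prediction mode {mode!r}")


def predict_score(model, suite: ExperimentSuite, horizon: int | None = None,
                  mode: str = "one_step"):
    """Per-output L1 prediction error and accuracy percentage.

    ``accuracy_i = 100 * max(0, 1 - sum_t |yhat_i - y_i| / sum_t |y_i|)``
    on detrended signals.  ``free_run`` recursively feeds each row its own
    predictions over the horizon; a continuous DSF is discretized
    (zero-order hold at the suite sampling interval) and scored in free-run
    mode.
    """
    if isinstance(model, DSF):
        if mode != "free_run":
            raise ValueError("a continuous DSF supports free_run scoring only")
        dt0 = suite.trajectories[0].dt
        model = discretize(model, dt0)
    suite = _ensure_detrended(suite)
    results = []
    for i, row in enumerate(model.rows):
        own_u = _own_input_index(suite, i)
        err = 0.0
        denom = 0.0
        for traj in suite.trajectories:
            Y, U, dts = _subsample_to_dt(traj, row.dt)
            T = Y.shape[0]
            start = row.nd if mode == "one_step" else max(row.nd, T - (horizon or T))
            t_idx, preds = _predict_row(row, Y, U, own_u, mode, start, horizon)
            err += float(np.sum(np.abs(preds - Y[t_idx, i])))
            denom += float(np.sum(np.abs(Y[t_idx, i])))
        acc = 100.0 * max(0.0, 1.0 - err / denom) if denom > 0 else (100.0 if err == 0 else 0.0)
        results.append({"output": suite.output_names[i], "l1": err, "accuracy": acc})
    return results


def _subsample_to_dt(traj: Trajectory, dt_target: float):
    stride = max(1, int(round(dt_target / traj.dt)))
    if abs(stride * traj.dt - dt_target) > 1e-6 * dt_target:
        raise ValueError("model sampling interval is not a multiple of the trace interval")
    return traj.Y[::stride], traj.U[::stride], traj.dt * stride


def _ensure_detrended(suite: ExperimentSuite) -> ExperimentSuite:
    if all(t.metadata.get("detrended") for t in suite.trajectories):
        return suite
    if all(t.metadata.get("baseline_n", 0) for t in suite.trajectories):
        return detrend(suite)
    return suite  # assume already centered when no baseline is recorded


# ----------------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------------

def fit_dsf(suite: ExperimentSuite, config: EstimationConfig | None = None):
    """Estimate a discrete-time DSF from a perturbation-experiment suite.

    Per output row, every (n_d, h_max) grid point is fitted by least squares
    on the leading (1 - holdout) fraction of each trace and scored by
    free-run L1 error on the held-out tail; the best point (ties toward
    smaller n_d, then smaller h_max) is refitted on the full data.  Grid
    points whose regression matrix exceeds the condition-number cap are
    rejected.
    """
    config = config or EstimationConfig()
    ident = check_identifiability(len(suite.output_names), len(suite.input_names),
                                  diagonal_p_mask(len(suite.output_names),
                                                  len(suite.input_names)))
    notes = []
    if not ident.identifiable:
        warnings.warn("identifiability conditions not met; returning a "
                      "best-effort fit", stacklevel=2)
        notes.append("identifiability check failed: best-effort fit")
    suite = _ensure_detrended(suite)
    p = len(suite.output_names)
    rows, row_fits = [], []
    for i in range(p):
        row, fit = _fit_row(suite, i, config)
        rows.append(row)
        row_fits.append(fit)
    report = FitReport(row_fits, len(suite.trajectories), ident.identifiable, notes)
    ddsf = DiscreteDSF(rows, list(suite.output_names), list(suite.input_names))
    return ddsf, report


def _split_train(traj: Trajectory, frac: float) -> tuple[Trajectory, int]:
    T = traj.t.size
    cut = max(int(np.floor((1.0 - frac) * T)), 2)
    train = Trajectory(traj.t[:cut], traj.Y[:cut], traj.U[:cut], dict(traj.metadata))
    return train, cut


def _fit_row(suite: ExperimentSuite, i: int, config: EstimationConfig):
    own_u = _own_input_index(suite, i)
    p = len(suite.output_names)
    grid_log = []
    candidates = []
    train_suite = ExperimentSuite(
        [_split_train(t, config.holdout_frac)[0] for t in suite.trajectories],
        suite.output_names, suite.input_names,
    )
    for nd in config.nd_grid:
        for hmax in config.hmax_grid:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    X, b = build_row_regression(train_suite, i, nd, hmax)
            except ValueError as exc:
                grid_log.append((nd, hmax, None, f"skipped: {exc}"))
                continue
            cond = _cond(X)
            if cond > config.cond_max:
                grid_log.append((nd, hmax, cond, "rejected: condition number"))
                continue
            if cond > config.cond_warn:
                logger.info("row %d (n_d=%d, h_max=%s): cond(X)=%.2e", i, nd, hmax, cond)
            theta = _solve(X, b, config)
            # score: free-run over the held-out tail of each full trace
            score = 0.0
            ok = True
            for traj in suite.trajectories:
                Y, U, dts = _subsample(traj, hmax)
                row = _theta_to_row(theta, i, p, own_u, nd, dts)
                T = Y.shape[0]
                start = max(nd, int(np.floor((1.0 - config.holdout_frac) * T)))
                try:
                    t_idx, preds = _predict_row(row, Y, U, own_u, "free_run",
                                                start, config.horizon)
                except ValueError:
                    ok = False
                    break
                if not np.all(np.isfinite(preds)):
                    ok = False
                    break
                score += float(np.sum(np.abs(preds - Y[t_idx, i])))
            if not ok:
                grid_log.append((nd, hmax, cond, "rejected: divergent free run"))
                continue
            grid_log.append((nd, hmax, cond, score))
            candidates.append((score, nd, hmax, cond))
    if not candidates:
        raise RuntimeError(
            f"all hyperparameter grid points rejected for row {i}; "
            f"diagnostics: {grid_log}"
        )
    best_score = min(c[0] for c in candidates)
    tol = config.tie_rtol * max(best_score, 1e-300)
    tied = [c for c in candidates if c[0] <= best_score + tol]
    tied.sort(key=lambda c: (c[1], np.inf if c[2] is None else c[2]))
    _, nd, hmax, _ = tied[0]
    # refit on the full data at the chosen hyperparameters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, b = build_row_regression(suite, i, nd, hmax)
    cond = _cond(X)
    theta = _solve(X, b, config)
    dts = _subsample(suite.trajectories[0], hmax)[2]
    row = _theta_to_row(theta, i, p, own_u, nd, dts)
    train_l1 = float(np.sum(np.abs(X @ theta - b)))
    nstep = 0.0
    denom = 0.0
    for traj in suite.trajectories:
        Y, U, _ = _subsample(traj, hmax)
        T = Y.shape[0]
        start = max(nd, int(np.floor((1.0 - config.holdout_frac) * T)))
        t_idx, preds = _predict_row(row, Y, U, own_u, "free_run", start, config.horizon)
        nstep += float(np.sum(np.abs(preds - Y[t_idx, i])))
        denom += float(np.sum(np.abs(Y[t_idx, i])))
    acc = 100.0 * max(0.0, 1.0 - nstep / denom) if denom > 0 else (100.0 if nstep == 0 else 0.0)
    fit = RowFit(i, nd, hmax, cond, train_l1, nstep, acc, X.shape[0], grid_log)
    return row, fit


# ----------------------------------------------------------------------------
# discrete <-> continuous
# ----------------------------------------------------------------------------

def _tustin_d2c(rf: RationalFunction, dt: float) -> RationalFunction:
    """Substitute z = (1 + s dt/2) / (1 - s dt/2) into a z-domain rational."""
    den = rf.den
    # singularity: denominator root at z = -1 maps to s = infinity
    if abs(np.polyval(den, -1.0)) < 1e-9 * np.max(np.abs(den)):
        raise ValueError(
            "denominator root at z = -1: the bilinear transform is singular "
            "here; use method='zoh' or 'matched'"
        )
    n = den.size - 1
    up = np.array([dt / 2.0, 1.0])    # 1 + s dt/2, ascending-in-s descending coeffs
    um = np.array([-dt / 2.0, 1.0])   # 1 - s dt/2

    def compose(coeffs):
        deg = coeffs.size - 1
        acc = np.zeros(1)
        for k, c in enumerate(coeffs):
            e = deg - k  # power of z
            term = np.array([c])
            for _ in range(e):
                term = np.polymul(term, up)
            for _ in range(n - e):
                term = np.polymul(term, um)
            acc = np.polyadd(acc, term)
        return acc

    return RationalFunction(compose(rf.num), compose(den), "s")


def _zoh_d2c(rf: RationalFunction, dt: float) -> RationalFunction:
    """Invert the zero-order-hold map via the matrix logarithm of a
    state-space realization."""
    A_d, B_d, C_d, D_d = scipy.signal.tf2ss(rf.num, rf.den)
    lam = np.linalg.eigvals(A_d)
    if np.any(np.abs(lam) < 1e-12):
        raise ValueError("pole at z = 0: zero-order-hold inversion undefined")
    Ac = scipy.linalg.logm(A_d) / dt
    if np.max(np.abs(np.imag(Ac))) > 1e-8 * max(1.0, np.max(np.abs(Ac))):
        raise ValueError(
            "matrix logarithm is not real (negative real discrete pole); "
            "use method='tustin' or 'matched'"
        )
    Ac = np.real(Ac)
    M = A_d - np.eye(A_d.shape[0])
    if np.linalg.cond(M) > 1e12:
        raise ValueError("pole at z = 1: zero-order-hold inversion is singular")
    Bc = np.linalg.solve(M, Ac @ B_d)
    num, den = scipy.signal.ss2tf(Ac, Bc, C_d, np.zeros_like(D_d))
    return RationalFunction(num.ravel(), den, "s").cancel()


def _matched_d2c(rf: RationalFunction, dt: float) -> RationalFunction:
    """Map poles and zeros by s = ln(z)/dt, matching the DC gain."""
    poles = np.log(rf.poles().astype(complex)) / dt
    zeros = np.log(rf.zeros().astype(complex)) / dt if rf.num_degree else np.array([])
    num = np.real_if_close(np.atleast_1d(np.poly(zeros)), tol=1000)
    den = np.real_if_close(np.atleast_1d(np.poly(poles)), tol=1000)
    cand = RationalFunction(np.real(num), np.real(den), "s")
    # gain match at z = 1 <-> s = 0 (fall back to a nearby point on a pole hit)
    for z0, s0 in ((1.0, 0.0), (np.exp(0.1), 0.1 / dt)):
        try:
            g = rf(z0) / cand(s0)
            break
        except Exception:
            continue
    else:
        raise ValueError("could not find a gain-matching point")
    return RationalFunction(np.real(g) * cand.num, cand.den, "s")


def to_continuous(ddsf: DiscreteDSF, method: str = "tustin") -> DSF:
    """Map a discrete-time DSF estimate to continuous time, entrywise.

    ``tustin`` (default) is the bilinear transform; ``zoh`` inverts the
    zero-order hold exactly; ``matched`` maps poles/zeros by s = ln(z)/dt.
    Structural zeros are preserved exactly.  The bilinear map does not
    preserve relative degree, so Tustin-mapped entries are proper but may
    carry a feedthrough term; zoh and matched preserve strict properness.
    """
    d2c = {"tustin": _tustin_d2c, "zoh": _zoh_d2c, "matched": _matched_d2c}
    if method not in d2c:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(d2c)}")
    fn = d2c[method]

    def convert(rf: RationalFunction, dt: float) -> RationalFunction:
        if rf.is_zero:
            return RationalFunction.zero("s")
        return fn(rf.cancel(), dt).cancel()

    p, m = ddsf.p, ddsf.m
    Q = [[convert(ddsf.q_entry(i, j), ddsf.rows[i].dt) for j in range(p)]
         for i in range(p)]
    P = [[convert(ddsf.p_entry(i, j), ddsf.rows[i].dt) for j in range(m)]
         for i in range(p)]
    return DSF(
        TransferMatrix(Q, list(ddsf.output_names), list(ddsf.output_names)),
        TransferMatrix(P, list(ddsf.output_names), list(ddsf.input_names)),
        require_strict=(method != "tustin"),
    )


def discretize(dsf: DSF, dt: float, method: str = "zoh") -> DiscreteDSF:
    """Discretize a continuous DSF row-wise (for scoring against sampled data).

    Each row's entries are converted with a shared sampling interval and put
    over the product denominator, so this is a scoring aid, not a minimal
    realization.  The default zero-order-hold map preserves strict
    properness, which the ARX row form requires.
    """
    rows = []
    for i in range(dsf.p):
        entries = {}
        for j in range(dsf.p):
            e = dsf.Q.entries[i][j]
            if not e.is_zero:
                entries[("q", j)] = _c2d_entry(e, dt, method)
        for j in range(dsf.m):
            e = dsf.P.entries[i][j]
            if not e.is_zero:
                entries[("p", j)] = _c2d_entry(e, dt, method)
        den = np.array([1.0])
        for rf in entries.values():
            den = np.polymul(den, rf.den)
        nd = den.size - 1
        q_num, p_num = {}, {}
        for (kind, j), rf in entries.items():
            quot, _ = np.polydiv(den, rf.den)   # exact: den is the product
            num = np.polymul(rf.num, quot)
            if num.size > nd:
                raise ValueError(
                    f"discretized entry is not strictly proper under "
                    f"method={method!r}; use method='zoh'"
                )
            num = np.concatenate([np.zeros(nd - num.size), num])
            (q_num if kind == "q" else p_num)[j] = num
        rows.append(DiscreteRow(i, den[1:], q_num, p_num, dt))
    return DiscreteDSF(rows, list(dsf.output_names), list(dsf.input_names))


def _c2d_entry(rf: RationalFunction, dt: float, method: str) -> RationalFunction:
    numd, dend, _ = scipy.signal.cont2discrete((rf.num, rf.den), dt, method=method)
    return RationalFunction(np.atleast_1d(numd.ravel()), dend, "z").cancel()


# ----------------------------------------------------------------------------
# synthetic discrete ground truths (for estimator studies)
# ----------------------------------------------------------------------------

def simulate_discrete(ddsf: DiscreteDSF, U: np.ndarray) -> np.ndarray:
    """Coupled forward simulation of a discrete DSF from zero initial rest.

    All rows must share one sampling interval.  Output j lags feed row i
    through the Q numerators, inputs through P; this is the exact data
    generator the ARX regression assumes.
    """
    if ddsf.dt is None:
        raise ValueError("coupled simulation needs a common sampling interval")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    T = U.shape[0]
    p = ddsf.p
    Y = np.zeros((T, p))
    ndmax = max(r.nd for r in ddsf.rows)
    for t in range(ndmax, T):
        for i, row in enumerate(ddsf.rows):
            acc = -np.dot(row.a, Y[t - np.arange(1, row.nd + 1), i])
            for j, bq in row.q_num.items():
                acc += np.dot(bq, Y[t - np.arange(1, row.nd + 1), j])
            for j, bp in row.p_num.items():
                acc += np.dot(bp, U[t - np.arange(1, row.nd + 1), j])
            Y[t, i] = acc
    return Y


def _coupled_state_matrix(ddsf: DiscreteDSF) -> np.ndarray:
    """Companion-form state matrix of the coupled recursion (stability check)."""
    p = ddsf.p
    nd = max(r.nd for r in ddsf.rows)
    N = p * nd
    M = np.zeros((N, N))
    for i, row in enumerate(ddsf.rows):
        r0 = i * nd
        for k in range(1, row.nd + 1):
            M[r0, i * nd + (k - 1)] += -row.a[k - 1]
        for j, bq in row.q_num.items():
            for k in range(1, row.nd + 1):
                M[r0, j * nd + (k - 1)] += bq[k - 1]
        for k in range(1, nd):
            M[r0 + k, i * nd + (k - 1)] = 1.0
    return M


def random_discrete_dsf(p: int, nd: int, rng: np.random.Generator,
                        dt: float = 1.0, coupling: float = 0.2,
                        max_tries: int = 200) -> DiscreteDSF:
    """A random stable discrete DSF ground truth with diagonal P.

    Row poles are drawn in (0.2, 0.85) on the positive real axis; coupling
    and input numerators are small random vectors.  Candidates are resampled
    until the coupled recursion's companion matrix has spectral radius below
    0.95.
    """
    for _ in range(max_tries):
        rows = []
        for i in range(p):
            poles = rng.uniform(0.2, 0.85, size=nd)
            a = np.atleast_1d(np.poly(poles))[1:]
            q_num = {j: coupling * rng.uniform(-1, 1, size=nd)
                     for j in range(p) if j != i}
            p_num = {i: rng.uniform(0.5, 1.5) * rng.uniform(0.2, 1.0, size=nd)}
            rows.append(DiscreteRow(i, a, q_num, p_num, dt))
        ddsf = DiscreteDSF(rows, [f"y{i + 1}" for i in range(p)],
                           [f"u{i + 1}" for i in range(p)])
        rad = np.max(np.abs(np.linalg.eigvals(_coupled_state_matrix(ddsf))))
        if rad < 0.95:
            return ddsf
    raise RuntimeError("failed to draw a stable random discrete DSF")
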