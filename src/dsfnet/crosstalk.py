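"""Crosstalk quantification: designed vs. estimated network structure.

Comparing an idealized (designed) network structure Q_ref with one estimated
from data, the entrywise difference Q_ref - Q_est is, to first order in the
perturbation size, the frequency response of the crosstalk-induced deviation
of the measured trajectories from their idealized counterparts.  In
particular, every estimated edge where the designed structure is
identically zero is a crosstalk interaction (shared-protease loading,
RNase/ribosome competition, retroactivity, ...).

Edges are ranked by their H-infinity (or H2) gains normalized by the
largest entry, and classified as designed-active, crosstalk, absent, or
gain-mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dsf_core import DSF
from .tfalgebra import (
    RationalFunction,
    TransferMatrix,
    UnstableEntryError,
    h2_norm,
    hinf_norm,
    tf_eval,
)

__all__ = [
    "CrosstalkReport",
    "dsf_delta",
    "classify_edges",
    "normalized_gain_matrix",
    "finite_horizon_laplace",
    "first_order_residual",
    "crosstalk_scaling_residuals",
]

GAIN_MISMATCH_BAND = (0.5, 2.0)


@dataclass
class CrosstalkReport:
    """Edge classification of an estimated network against a reference."""

    labels: np.ndarray                 # p x p of {designed-active, crosstalk, absent, gain-mismatch}
    gains: np.ndarray                  # raw entry gains of the estimate
    normalized_gains: np.ndarray       # gains / max gain, zero diagonal
    ref_support: np.ndarray            # p x p bool
    tol: float
    norm: str
    delta: TransferMatrix | None = None
    output_names: list[str] = field(default_factory=list)

    def edges(self):
        """(i, j, label, normalized_gain) for every retained edge j -> i."""
        out = []
        p = self.labels.shape[0]
        for i in range(p):
            for j in range(p):
                if i != j and self.labels[i, j] != "absent":
                    out.append((i, j, str(self.labels[i, j]),
                                float(self.normalized_gains[i, j])))
        return out


def dsf_delta(Q_ref: TransferMatrix, Q_est: TransferMatrix) -> TransferMatrix:
    """Entrywise difference Q_ref - Q_est (the first-order crosstalk map).

    Where the reference entry is identically zero the delta reduces to
    -Q_est_ij: the estimated edge *is* the crosstalk term.
    """
    if Q_ref.shape != Q_est.shape:
        raise ValueError(f"shape mismatch: {Q_ref.shape} vs {Q_est.shape}")
    return (Q_ref - Q_est).cancel()


def _entry_gain(e: RationalFunction, norm: str) -> float:
    if e.is_zero:
        return 0.0
    return hinf_norm(e) if norm == "hinf" else h2_norm(e)


def normalized_gain_matrix(Q: TransferMatrix, norm: str = "hinf") -> np.ndarray:
    """Entrywise norms scaled by the maximum gain; zero diagonal.

    The largest entry maps to 1.00, matching the conventional display of
    worst-case edge gains.  An all-zero matrix returns all zeros.
    """
    if norm not in ("hinf", "h2"):
        raise ValueError("norm must be 'hinf' or 'h2'")
    p, c = Q.rows, Q.cols
    G = np.zeros((p, c))
    for i in range(p):
        for j in range(c):
            if i == j:
                continue
            G[i, j] = _entry_gain(Q.entries[i][j], norm)
    mx = G.max()
    return G / mx if mx > 0 else G


def classify_edges(Q_ref, Q_est: TransferMatrix, tol: float = 0.05,
                   norm: str = "hinf") -> CrosstalkReport:
    """Classify the edges of an estimated Q against a reference structure.

    ``Q_ref`` may be a boolean support matrix or a reference TransferMatrix
    (in which case designed edges additionally get a gain-mismatch check:
    estimated/reference H-inf gain outside [0.5, 2]).  ``tol`` thresholds the
    max-normalized gain: entries below it are absent; above it they are
    crosstalk where the reference support is zero and designed-active where
    it is nonzero.  Classification is invariant to global rescaling of the
    estimate.
    """
    if not 0 < tol < 1:
        raise ValueError("tol must lie in (0, 1)")
    ref_tm = None
    if isinstance(Q_ref, TransferMatrix):
        ref_tm = Q_ref
        ref_support = np.array([[not ref_tm.entries[i][j].is_zero
                                 for j in range(ref_tm.cols)]
                                for i in range(ref_tm.rows)])
    else:
        ref_support = np.asarray(Q_ref, dtype=bool)
    np.fill_diagonal(ref_support, False)
    if ref_support.shape != (Q_est.rows, Q_est.cols):
        raise ValueError("reference support shape mismatch")

    p = Q_est.rows
    gains = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            e = Q_est.entries[i][j]
            try:
                gains[i, j] = _entry_gain(e, norm)
            except UnstableEntryError:
                warnings.warn(
                    f"entry ({i},{j}) is unstable; excluded from gain ranking",
                    stacklevel=2,
                )
                gains[i, j] = np.nan
    mx = np.nanmax(gains) if np.any(np.isfinite(gains)) else 0.0
    norm_gains = gains / mx if mx > 0 else gains.copy()
    norm_gains = np.nan_to_num(norm_gains, nan=0.0)

    labels = np.full((p, p), "absent", dtype=object)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if norm_gains[i, j] < tol:
                continue
            if not ref_support[i, j]:
                labels[i, j] = "crosstalk"
                continue
            labels[i, j] = "designed-active"
            if ref_tm is not None:
                try:
                    g_ref = _entry_gain(ref_tm.entries[i][j], norm)
                except UnstableEntryError:
                    g_ref = np.nan
                if np.isfinite(g_ref) and g_ref > 0:
                    ratio = gains[i, j] / g_ref
                    lo, hi = GAIN_MISMATCH_BAND
                    if not (lo <= ratio <= hi):
                        labels[i, j] = "gain-mismatch"
    delta = dsf_delta(ref_tm, Q_est) if ref_tm is not None else None
    return CrosstalkReport(labels, np.nan_to_num(gains, nan=0.0), norm_gains,
                           ref_support, tol, norm, delta,
                           list(Q_est.row_names))


# ----------------------------------------------------------------------------
# first-order crosstalk prediction (frequency-domain deviation)
# ----------------------------------------------------------------------------

def finite_horizon_laplace(t: np.ndarray, x: np.ndarray, s_values) -> np.ndarray:
    """Finite-horizon Laplace transform int_0^T exp(-s t) x(t) dt by
    trapezoidal quadrature; x may be (T,) or (T, k).  Returns (len(s), k)."""
    t = np.asarray(t, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T  # (T, k)
    s_values = np.asarray(s_values, dtype=float)
    out = np.empty((s_values.size, x.shape[1]))
    for a, s in enumerate(s_values):
        w = np.exp(-s * (t - t[0]))
        out[a] = np.trapezoid(x * w[:, None], t, axis=0)
    return out


def first_order_residual(dsf_ref: DSF, dsf_est: DSF, t: np.ndarray,
                         dy_ref: np.ndarray, dy_est: np.ndarray,
                         du: np.ndarray, s_grid) -> float:
    """Residual of the first-order crosstalk prediction of the trajectory
    deviation, in the frequency domain.

    Subtracting the two linearized relations Y = Q Y + P U for the reference
    (idealized) and estimated (crosstalk) models gives, for the deviation
    zeta = y_ref - y_est (each a deviation from its own operating point),

        L(zeta) = (I - Q_ref)^-1 [ (Q_ref - Q_est) L(y_est)
                                   + (P_ref - P_est) L(u) ] + O(eps^2),

    where eps is the perturbation amplitude: the neglected remainder is the
    nonlinear correction, quadratic in the perturbation.  This function
    evaluates the left and right sides with finite-horizon transforms on a
    positive real s-grid and returns the root-sum-square mismatch, which
    should scale as eps^2.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    zeta = dy_ref - dy_est
    Lz = finite_horizon_laplace(t, zeta, s_grid)         # (S, p)
    Ly = finite_horizon_laplace(t, dy_est, s_grid)
    Lu = finite_horizon_laplace(t, du, s_grid)
    total = 0.0
    p = dsf_ref.p
    for a, s in enumerate(s_grid):
        Qr = tf_eval(dsf_ref.Q, s)
        Qe = tf_eval(dsf_est.Q, s)
        Pr = tf_eval(dsf_ref.P, s)
        Pe = tf_eval(dsf_est.P, s)
        rhs = np.linalg.solve(np.eye(p) - Qr,
                              (Qr - Qe) @ Ly[a] + (Pr - Pe) @ Lu[a])
        total += float(np.sum(np.abs(Lz[a] - np.real(rhs)) ** 2))
    return np.sqrt(total)


def crosstalk_scaling_residuals(model_ideal, model_crosstalk, u_baseline,
                                eps_rel=(1e-2, 5e-3, 2.5e-3),
                                t_end: float = 20000.0, dt: float = 20.0,
                                s_grid=None) -> list[float]:
    """First-order prediction residuals across perturbation amplitudes.

    Both circuits are settled at their own equilibria under ``u_baseline``,
    then stepped at t = 0 by ``eps * u_baseline`` (held).  For each relative
    amplitude the nonlinear deviation trajectories are compared, in the
    frequency domain, with the first-order crosstalk prediction built from
    the two linearizations' DSFs.  The returned residual sequence should
    fall roughly fourfold per halving of eps (the remainder is quadratic in
    the perturbation).
    """
    from .circuits import find_equilibrium, linearize, simulate
    from .dsf_core import derive_dsf

    u_baseline = np.asarray(u_baseline, dtype=float)
    op_a = find_equilibrium(model_ideal, u_baseline)
    op_c = find_equilibrium(model_crosstalk, u_baseline)
    dsf_a = derive_dsf(linearize(model_ideal, op_a))
    dsf_c = derive_dsf(linearize(model_crosstalk, op_c))
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    if s_grid is None:
        s_grid = np.logspace(-3.3, -1.0, 8)
    out = []
    for eps in eps_rel:
        sched = (np.array([0.0]), np.array([(1.0 + eps) * u_baseline]))
        tr_a = simulate(model_ideal, sched, op_a.x, t)
        tr_c = simulate(model_crosstalk, sched, op_c.x, t)
        dy_a = tr_a.Y - op_a.x[model_ideal.measured_indices]
        dy_c = tr_c.Y - op_c.x[model_crosstalk.measured_indices]
        du = tr_a.U - u_baseline
        out.append(first_order_residual(dsf_a, dsf_c, t, dy_a, dy_c, du, s_grid))
    return out
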