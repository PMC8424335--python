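"""Dynamical structure functions from partitioned linear systems.

Given a linear(ized) state-space model whose state is split into measured
outputs ``y`` (first ``p`` components, ``C = [I 0]``) and hidden states
``x_h``, the hidden block is eliminated in the Laplace domain:

    s Y = W(s) Y + V(s) U,
    W(s) = A11 + A12 (sI - A22)^-1 A21,
    V(s) = B1  + A12 (sI - A22)^-1 B2.

Subtracting the diagonal D(s) = diag(W) and solving for Y gives the
dynamical structure function (DSF),

    Y = Q(s) Y + P(s) U,
    Q = (sI - D)^-1 (W - D),     P = (sI - D)^-1 V,

whose entries are strictly proper transfer functions describing *open-loop*
causal influence among measured species (Q) and from inputs (P).  Q has an
identically zero diagonal, which makes the pair (Q, P) unique and
identifiable under independent per-node perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .tfalgebra import (
    KernelResponse,
    RationalFunction,
    TransferMatrix,
    impulse_kernel,
    tm_inverse,
)

__all__ = [
    "PartitionedLTI",
    "DSF",
    "StructureReport",
    "compute_WV",
    "compute_QP",
    "derive_dsf",
    "dsf_closed_loop",
    "kernel_matrix",
    "structure_report",
    "compute_WV_symbolic",
    "compute_QP_symbolic",
]


@dataclass
class PartitionedLTI:
    """Linear system with measured-first state ordering and C = [I 0]."""

    A11: np.ndarray
    A12: np.ndarray
    A21: np.ndarray
    A22: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    output_names: list[str] = field(default_factory=list)
    input_names: list[str] = field(default_factory=list)
    hidden_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.A11 = np.atleast_2d(np.asarray(self.A11, dtype=float))
        p = self.A11.shape[0]
        self.A12 = np.asarray(self.A12, dtype=float).reshape(p, -1)
        h = self.A12.shape[1]
        self.A21 = np.asarray(self.A21, dtype=float).reshape(h, p)
        self.A22 = np.asarray(self.A22, dtype=float).reshape(h, h)
        self.B1 = np.asarray(self.B1, dtype=float).reshape(p, -1)
        m = self.B1.shape[1]
        self.B2 = np.asarray(self.B2, dtype=float).reshape(h, m)
        if self.A11.shape != (p, p):
            raise ValueError("A11 must be square")
        if not self.output_names:
            self.output_names = [f"y{i + 1}" for i in range(p)]
        if not self.input_names:
            self.input_names = [f"u{j + 1}" for j in range(m)]
        if not self.hidden_names:
            self.hidden_names = [f"h{k + 1}" for k in range(h)]
        if (len(self.output_names), len(self.input_names), len(self.hidden_names)) != (p, m, h):
            raise ValueError("name lists inconsistent with block dimensions")

    @property
    def p(self) -> int:
        return self.A11.shape[0]

    @property
    def m(self) -> int:
        return self.B1.shape[1]

    @property
    def n(self) -> int:
        return self.p + self.A22.shape[0]

    @property
    def A(self) -> np.ndarray:
        return np.block([[self.A11, self.A12], [self.A21, self.A22]])

    @property
    def B(self) -> np.ndarray:
        return np.vstack([self.B1, self.B2])

    @property
    def C(self) -> np.ndarray:
        return np.hstack([np.eye(self.p), np.zeros((self.p, self.n - self.p))])

    @classmethod
    def from_full(cls, A, B, p, output_names=None, input_names=None, hidden_names=None):
        """Partition a full (A, B) whose first ``p`` states are the measured ones."""
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.asarray(B, dtype=float).reshape(A.shape[0], -1)
        return cls(A[:p, :p], A[:p, p:], A[p:, :p], A[p:, p:], B[:p, :], B[p:, :],
                   output_names or [], input_names or [], hidden_names or [])


@dataclass
class DSF:
    """A dynamical structure function: the pair (Q(s), P(s)).

    Invariants: diag(Q) is identically zero and every nonzero entry of Q and
    P is strictly proper.
    """

    Q: TransferMatrix
    P: TransferMatrix
    require_strict: bool = True

    def __post_init__(self):
        if self.Q.rows != self.Q.cols:
            raise ValueError("Q must be square")
        if self.P.rows != self.Q.rows:
            raise ValueError("P row count must match Q")
        for i in range(self.Q.rows):
            if not self.Q.entries[i][i].is_zero:
                raise ValueError(f"Q diagonal entry ({i},{i}) is not zero")
        for name, tm in (("Q", self.Q), ("P", self.P)):
            for i in range(tm.rows):
                for j in range(tm.cols):
                    e = tm.entries[i][j]
                    ok = e.is_strictly_proper if self.require_strict else e.is_proper
                    if not ok:
                        raise ValueError(f"{name}[{i},{j}] is not strictly proper")

    @property
    def p(self) -> int:
        return self.Q.rows

    @property
    def m(self) -> int:
        return self.P.cols

    @property
    def output_names(self) -> list[str]:
        return self.Q.row_names

    @property
    def input_names(self) -> list[str]:
        return self.P.col_names


# ----------------------------------------------------------------------------
# hidden-state elimination (numeric path)
# ----------------------------------------------------------------------------

def _resolvent_polys(A22: np.ndarray):
    """Faddeev-LeVerrier: (sI - A22)^-1 = sum_k M_k s^(h-1-k) / charpoly(s).

    Returns (list of h matrices M_0..M_{h-1}, charpoly coeffs length h+1).
    """
    h = A22.shape[0]
    Ms = []
    c = np.zeros(h + 1)
    c[0] = 1.0
    M = np.eye(h)
    for k in range(1, h + 1):
        Ms.append(M)
        N = A22 @ M
        c[k] = -np.trace(N) / k
        M = N + c[k] * np.eye(h)
    return Ms, c


def compute_WV(sys: PartitionedLTI) -> tuple[TransferMatrix, TransferMatrix]:
    """Eliminate the hidden block: W = A11 + A12 (sI-A22)^-1 A21 and
    V = B1 + A12 (sI-A22)^-1 B2, as rational matrices over det(sI - A22)."""
    p, m, h = sys.p, sys.m, sys.n - sys.p
    if h == 0:
        W = TransferMatrix.from_constant(sys.A11, "s", sys.output_names, sys.output_names)
        V = TransferMatrix.from_constant(sys.B1, "s", sys.output_names, sys.input_names)
        return W, V
    Ms, den = _resolvent_polys(sys.A22)
    # numerator polynomial coefficient stacks: shape (h, p, p) and (h, p, m)
    w_num = np.stack([sys.A12 @ M @ sys.A21 for M in Ms])
    v_num = np.stack([sys.A12 @ M @ sys.B2 for M in Ms])

    def build(const, numstack, i, j):
        # const*den + sum_k numstack[k, i, j] s^(h-1-k)
        coeffs = const[i, j] * den
        coeffs[1:] += numstack[:, i, j]
        return RationalFunction(coeffs, den, "s")

    W = TransferMatrix(
        [[build(sys.A11, w_num, i, j) for j in range(p)] for i in range(p)],
        list(sys.output_names), list(sys.output_names),
    )
    V = TransferMatrix(
        [[build(sys.B1, v_num, i, j) for j in range(m)] for i in range(p)],
        list(sys.output_names), list(sys.input_names),
    )
    return W, V


def compute_QP(W: TransferMatrix, V: TransferMatrix) -> DSF:
    """Form Q = (sI - D)^-1 (W - D) and P = (sI - D)^-1 V, D = diag(W)."""
    if W.rows != W.cols:
        raise ValueError("W must be square")
    if V.rows != W.rows:
        raise ValueError("V must be row-conformal with W")
    p = W.rows
    s = RationalFunction.identity_var("s")
    row_inv = [(s - W.entries[i][i]) for i in range(p)]  # (sI - D) is diagonal
    Q = [[RationalFunction.zero("s") for _ in range(p)] for _ in range(p)]
    P = [[None] * V.cols for _ in range(p)]
    # genuinely common factors (the shared det(sI - A22)) agree to near
    # machine precision; a tight tolerance avoids perturbing true poles
    ctol = 1e-12
    for i in range(p):
        for j in range(p):
            if i != j and not W.entries[i][j].is_zero:
                Q[i][j] = (W.entries[i][j] / row_inv[i]).cancel(ctol)
        for j in range(V.cols):
            P[i][j] = (V.entries[i][j] / row_inv[i]).cancel(ctol)
    Qm = TransferMatrix(Q, list(W.row_names), list(W.col_names))
    Pm = TransferMatrix(P, list(W.row_names), list(V.col_names))
    return DSF(Qm, Pm)


def derive_dsf(sys: PartitionedLTI) -> DSF:
    """Full pipeline: hidden-state elimination then DSF construction."""
    W, V = compute_WV(sys)
    return compute_QP(W, V)


def dsf_closed_loop(dsf: DSF) -> TransferMatrix:
    """Closed-loop transfer function G = (I - Q)^-1 P."""
    ImQ = (TransferMatrix.identity(dsf.p, "s", list(dsf.output_names))
           - dsf.Q).cancel(1e-9)
    G = tm_inverse(ImQ) @ dsf.P
    G.row_names = list(dsf.output_names)
    G.col_names = list(dsf.input_names)
    return G.cancel(1e-9)


def kernel_matrix(dsf: DSF, t_grid) -> KernelResponse:
    """Entrywise inverse-Laplace kernels Q(t) on ``t_grid``; diagonal zero."""
    t = np.asarray(t_grid, dtype=float)
    vals = np.zeros((dsf.p, dsf.p, t.size))
    for i in range(dsf.p):
        for j in range(dsf.p):
            e = dsf.Q.entries[i][j]
            if not e.is_zero:
                vals[i, j] = impulse_kernel(e, t)
    return KernelResponse(t, vals, list(dsf.output_names), list(dsf.output_names))


@dataclass
class StructureReport:
    """Support and sign pattern of Q evaluated on a positive real s-grid."""

    support: np.ndarray            # p x p bool, diagonal False
    signs: np.ndarray              # p x p of {"absent","activating","repressing","mixed"}
    max_abs: np.ndarray            # p x p max |Q_ij| over the grid
    s_grid: np.ndarray
    tol: float
    output_names: list[str] = field(default_factory=list)


def structure_report(dsf: DSF, s_grid=None, tol: float = 1e-2) -> StructureReport:
    """Label each off-diagonal entry of Q as absent / activating / repressing
    / mixed, by its sign on a positive real s-grid.

    An entry is *absent* when its largest magnitude on the grid is below
    ``tol`` times the largest entry magnitude overall (robust to numeric
    cancellation residue).  On the positive real axis the sign of Q_ij
    matches the regulatory character of the interaction (activation > 0,
    repression < 0).
    """
    if s_grid is None:
        s_grid = np.logspace(-3, 2, 25)
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("empty s-grid")
    if np.any(s_grid <= 0):
        raise ValueError("s-grid must be strictly positive")
    p = dsf.p
    vals = np.zeros((p, p, s_grid.size))
    for i in range(p):
        for j in range(p):
            e = dsf.Q.entries[i][j]
            if not e.is_zero:
                vals[i, j] = [np.real(e(s)) for s in s_grid]
    max_abs = np.max(np.abs(vals), axis=2)
    overall = np.max(max_abs)
    thr = tol * (overall if overall > 0 else 1.0)
    support = max_abs >= thr
    np.fill_diagonal(support, False)
    signs = np.full((p, p), "absent", dtype=object)
    for i in range(p):
        for j in range(p):
            if i == j or not support[i, j]:
                continue
            v = vals[i, j]
            if np.all(v > 0):
                signs[i, j] = "activating"
            elif np.all(v < 0):
                signs[i, j] = "repressing"
            else:
                signs[i, j] = "mixed"
    return StructureReport(support, signs, max_abs, s_grid, tol,
                           list(dsf.output_names))


# ----------------------------------------------------------------------------
# symbolic path (used when the source model has expression form)
# ----------------------------------------------------------------------------

def compute_WV_symbolic(A11, A12, A21, A22, B1, B2, s=None):
    """Symbolic hidden-state elimination on sympy block matrices."""
    if s is None:
        s = sp.Symbol("s")
    A11, A12, A21, A22 = map(sp.Matrix, (A11, A12, A21, A22))
    B1, B2 = sp.Matrix(B1), sp.Matrix(B2)
    h = A22.shape[0]
    if h == 0:
        return A11, B1, s
    R = (s * sp.eye(h) - A22).inv()
    W = A11 + A12 * R * A21
    V = B1 + A12 * R * B2
    return sp.simplify(W), sp.simplify(V), s


def compute_QP_symbolic(W, V, s):
    """Symbolic Q = (sI - D)^-1 (W - D), P = (sI - D)^-1 V."""
    p = W.shape[0]
    Q = sp.zeros(p, p)
    P = sp.zeros(p, V.shape[1])
    for i in range(p):
        g = s - W[i, i]
        for j in range(p):
            if i != j:
                Q[i, j] = sp.simplify(sp.cancel(W[i, j] / g))
        for j in range(V.shape[1]):
            P[i, j] = sp.simplify(sp.cancel(V[i, j] / g))
    return Q, P
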