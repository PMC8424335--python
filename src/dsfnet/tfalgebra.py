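"""Rational-function and transfer-matrix algebra.

This layer provides the scalar and matrix transfer-function arithmetic that
the dynamical-structure machinery is built on: evaluation, inversion,
inverse-Laplace impulse kernels, and the H-infinity / H2 gains used to rank
network edges.  Entries are rational functions in the Laplace variable ``s``
(continuous time) or the z-transform variable ``z`` (discrete time), stored
as real coefficient arrays in descending powers with monic denominators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.signal

logger = logging.getLogger("dsfnet")

__all__ = [
    "RationalFunction",
    "TransferMatrix",
    "KernelResponse",
    "PoleProximityError",
    "SingularMatrixError",
    "UnstableEntryError",
    "tf_eval",
    "tm_inverse",
    "impulse_kernel",
    "hinf_norm",
    "h2_norm",
]

# Numerical policy (shared by the whole package)
POLE_PROXIMITY_RTOL = 1e-12     # |den(s0)| below this times max|coeff| is a pole hit
ROOT_CLUSTER_RTOL = 1e-7        # roots closer than this (relative) are one pole
COEFF_ZERO_RTOL = 1e-12         # coefficient magnitudes below this times the largest are trimmed


class PoleProximityError(ValueError):
    """Evaluation point is (numerically) a pole of an entry."""


class SingularMatrixError(ValueError):
    """Transfer matrix with identically-zero determinant."""


class UnstableEntryError(ValueError):
    """Norm requested for an entry with a pole outside the stability region."""


# ----------------------------------------------------------------------------
# polynomial helpers (descending-power coefficient arrays)
# ----------------------------------------------------------------------------

def _trim(c: np.ndarray) -> np.ndarray:
    """Strip leading (high-order) coefficients that are negligible."""
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if c.size == 0:
        return np.array([0.0])
    scale = np.max(np.abs(c))
    if scale == 0.0:
        return np.array([0.0])
    keep = np.abs(c) > COEFF_ZERO_RTOL * scale
    first = int(np.argmax(keep))
    return c[first:].copy()


def _polyadd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.polyadd(a, b)


def _polymul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.polymul(a, b)


def _poly_from_roots(roots: np.ndarray, lead: float = 1.0) -> np.ndarray:
    p = np.atleast_1d(np.poly(roots)) if len(roots) else np.array([1.0])
    p = np.real_if_close(p, tol=1000)
    return lead * np.real(p)


@dataclass(frozen=True)
class RationalFunction:
    """A real-coefficient ratio of polynomials, ``num(x)/den(x)``.

    Coefficients are stored in descending powers; the denominator is
    normalized to be monic.  The zero function is ``num=[0], den=[1]``.
    ``var`` tags the transform domain: ``"s"`` (Laplace) or ``"z"``.
    """

    num: np.ndarray
    den: np.ndarray
    var: str = "s"

    def __post_init__(self):
        num = _trim(self.num)
        den = _trim(self.den)
        if den.size == 1 and den[0] == 0.0:
            raise ValueError("denominator is identically zero")
        if self.var not in ("s", "z"):
            raise ValueError(f"var must be 's' or 'z', got {self.var!r}")
        lead = den[0]
        den = den / lead
        if np.all(num == 0.0):
            num = np.array([0.0])
            den = np.array([1.0])
        else:
            num = num / lead
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    # -- constructors ------------------------------------------------------
    @classmethod
    def zero(cls, var: str = "s") -> "RationalFunction":
        return cls(np.array([0.0]), np.array([1.0]), var)

    @classmethod
    def constant(cls, c: float, var: str = "s") -> "RationalFunction":
        return cls(np.array([float(c)]), np.array([1.0]), var)

    @classmethod
    def identity_var(cls, var: str = "s") -> "RationalFunction":
        """The transfer function equal to the transform variable itself."""
        return cls(np.array([1.0, 0.0]), np.array([1.0]), var)

    # -- structure ---------------------------------------------------------
    @property
    def is_zero(self) -> bool:
        return self.num.size == 1 and self.num[0] == 0.0

    @property
    def num_degree(self) -> int:
        return self.num.size - 1

    @property
    def den_degree(self) -> int:
        return self.den.size - 1

    @property
    def is_proper(self) -> bool:
        return self.is_zero or self.num_degree <= self.den_degree

    @property
    def is_strictly_proper(self) -> bool:
        return self.is_zero or self.num_degree < self.den_degree

    def poles(self) -> np.ndarray:
        if self.den_degree == 0:
            return np.array([], dtype=complex)
        return np.roots(self.den)

    def zeros(self) -> np.ndarray:
        if self.is_zero or self.num_degree == 0:
            return np.array([], dtype=complex)
        return np.roots(self.num)

    def is_stable(self) -> bool:
        p = self.poles()
        if self.var == "s":
            return bool(np.all(np.real(p) < 0))
        return bool(np.all(np.abs(p) < 1))

    # -- evaluation --------------------------------------------------------
    def __call__(self, x0: complex) -> complex:
        dval = np.polyval(self.den, x0)
        scale = np.max(np.abs(self.den)) * max(1.0, abs(x0)) ** self.den_degree
        if abs(dval) < POLE_PROXIMITY_RTOL * scale:
            raise PoleProximityError(
                f"evaluation point {x0} is numerically a pole "
                f"(|den| = {abs(dval):.3e})"
            )
        return complex(np.polyval(self.num, x0)) / complex(dval)

    # -- arithmetic --------------------------------------------------------
    def _check_var(self, other: "RationalFunction"):
        if self.var != other.var:
            raise ValueError(f"mixed transform variables: {self.var!r} vs {other.var!r}")

    def __add__(self, other):
        if not isinstance(other, RationalFunction):
            other = RationalFunction.constant(other, self.var)
        self._check_var(other)
        num = _polyadd(_polymul(self.num, other.den), _polymul(other.num, self.den))
        den = _polymul(self.den, other.den)
        return RationalFunction(num, den, self.var)

    __radd__ = __add__

    def __neg__(self):
        return RationalFunction(-self.num, self.den, self.var)

    def __sub__(self, other):
        if not isinstance(other, RationalFunction):
            other = RationalFunction.constant(other, self.var)
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, RationalFunction):
            other = RationalFunction.constant(other, self.var)
        self._check_var(other)
        if self.is_zero or other.is_zero:
            return RationalFunction.zero(self.var)
        return RationalFunction(
            _polymul(self.num, other.num), _polymul(self.den, other.den), self.var
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, RationalFunction):
            other = RationalFunction.constant(other, self.var)
        self._check_var(other)
        if other.is_zero:
            raise ZeroDivisionError("division by the zero rational function")
        if self.is_zero:
            return RationalFunction.zero(self.var)
        return RationalFunction(
            _polymul(self.num, other.den), _polymul(self.den, other.num), self.var
        )

    def __rtruediv__(self, other):
        return RationalFunction.constant(other, self.var) / self

    # -- simplification ----------------------------------------------------
    def cancel(self, rtol: float = ROOT_CLUSTER_RTOL) -> "RationalFunction":
        """Cancel near-common numerator/denominator root pairs.

        Root pairs closer than ``rtol`` (relative to the overall root scale)
        are removed.  Cancellation is numeric; a debug log records what was
        cancelled so silent pole/zero deletions are traceable.
        """
        if self.is_zero or self.num_degree == 0 or self.den_degree == 0:
            return self
        nz = np.roots(self.num)
        dz = np.roots(self.den)
        lead = self.num[0]
        scale = max(1.0, np.max(np.abs(nz)) if nz.size else 0.0,
                    np.max(np.abs(dz)) if dz.size else 0.0)
        keep_d = np.ones(dz.size, dtype=bool)
        keep_n = np.ones(nz.size, dtype=bool)
        cancelled = 0
        for i, r in enumerate(nz):
            d = np.where(keep_d)[0]
            if d.size == 0:
                break
            j = d[np.argmin(np.abs(dz[d] - r))]
            if abs(dz[j] - r) < rtol * scale:
                keep_n[i] = False
                keep_d[j] = False
                cancelled += 1
        if cancelled == 0:
            return self
        logger.debug("cancelled %d near-common root pair(s)", cancelled)
        num = _poly_from_roots(nz[keep_n], lead)
        den = _poly_from_roots(dz[keep_d], 1.0)
        return RationalFunction(num, den, self.var)

    def __repr__(self):
        return f"RationalFunction(num={self.num.tolist()}, den={self.den.tolist()}, var={self.var!r})"

    def __eq__(self, other):
        if not isinstance(other, RationalFunction):
            return NotImplemented
        return (self.var == other.var
                and self.num.shape == other.num.shape
                and self.den.shape == other.den.shape
                and np.array_equal(self.num, other.num)
                and np.array_equal(self.den, other.den))


@dataclass
class TransferMatrix:
    """A grid of rational functions sharing one transform variable."""

    entries: list  # list of lists of RationalFunction
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        rows = len(self.entries)
        if rows == 0:
            raise ValueError("empty transfer matrix")
        cols = len(self.entries[0])
        for r in self.entries:
            if len(r) != cols:
                raise ValueError("ragged transfer matrix")
        vs = {e.var for row in self.entries for e in row}
        if len(vs) != 1:
            raise ValueError(f"entries mix transform variables: {vs}")
        if not self.row_names:
            self.row_names = [f"y{i + 1}" for i in range(rows)]
        if not self.col_names:
            self.col_names = [f"c{j + 1}" for j in range(cols)]
        if len(self.row_names) != rows or len(self.col_names) != cols:
            raise ValueError("name lists inconsistent with shape")

    @property
    def rows(self) -> int:
        return len(self.entries)

    @property
    def cols(self) -> int:
        return len(self.entries[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def var(self) -> str:
        return self.entries[0][0].var

    def __getitem__(self, ij) -> RationalFunction:
        i, j = ij
        return self.entries[i][j]

    @classmethod
    def zeros(cls, rows, cols, var="s", row_names=None, col_names=None):
        ent = [[RationalFunction.zero(var) for _ in range(cols)] for _ in range(rows)]
        return cls(ent, row_names or [], col_names or [])

    @classmethod
    def identity(cls, n, var="s", names=None):
        ent = [
            [RationalFunction.constant(1.0 if i == j else 0.0, var) for j in range(n)]
            for i in range(n)
        ]
        return cls(ent, names or [], names or [])

    @classmethod
    def from_constant(cls, M, var="s", row_names=None, col_names=None):
        M = np.atleast_2d(np.asarray(M, dtype=float))
        ent = [[RationalFunction.constant(M[i, j], var) for j in range(M.shape[1])]
               for i in range(M.shape[0])]
        return cls(ent, row_names or [], col_names or [])

    def map(self, fn) -> "TransferMatrix":
        return TransferMatrix(
            [[fn(e) for e in row] for row in self.entries],
            list(self.row_names), list(self.col_names),
        )

    def cancel(self, rtol: float = ROOT_CLUSTER_RTOL) -> "TransferMatrix":
        return self.map(lambda e: e.cancel(rtol))

    def __sub__(self, other: "TransferMatrix") -> "TransferMatrix":
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        ent = [[self.entries[i][j] - other.entries[i][j] for j in range(self.cols)]
               for i in range(self.rows)]
        return TransferMatrix(ent, list(self.row_names), list(self.col_names))

    def __matmul__(self, other: "TransferMatrix") -> "TransferMatrix":
        if self.cols != other.rows:
            raise ValueError("inner dimensions do not match")
        ent = []
        for i in range(self.rows):
            row = []
            for j in range(other.cols):
                acc = RationalFunction.zero(self.var)
                for k in range(self.cols):
                    acc = acc + self.entries[i][k] * other.entries[k][j]
                row.append(acc)
            ent.append(row)
        return TransferMatrix(ent, list(self.row_names), list(other.col_names))


@dataclass
class KernelResponse:
    """Impulse-response kernels of a transfer matrix on a time grid."""

    t_grid: np.ndarray          # increasing, in the time units of the source data
    values: np.ndarray          # rows x cols x T
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")


# ----------------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------------

def tf_eval(tm: TransferMatrix, s0: complex) -> np.ndarray:
    """Evaluate every entry at ``s0``; errors if ``s0`` hits a pole."""
    out = np.empty((tm.rows, tm.cols), dtype=complex)
    for i in range(tm.rows):
        for j in range(tm.cols):
            try:
                out[i, j] = tm.entries[i][j](s0)
            except PoleProximityError as exc:
                raise PoleProximityError(
                    f"entry ({tm.row_names[i]}, {tm.col_names[j]}): {exc}"
                ) from exc
    return out


def _det(entries: list[list[RationalFunction]], var: str) -> RationalFunction:
    n = len(entries)
    if n == 1:
        return entries[0][0]
    acc = RationalFunction.zero(var)
    for j in range(n):
        if entries[0][j].is_zero:
            continue
        minor = [[entries[i][k] for k in range(n) if k != j] for i in range(1, n)]
        term = entries[0][j] * _det(minor, var)
        acc = acc + term if j % 2 == 0 else acc - term
    return acc


def tm_inverse(tm: TransferMatrix) -> TransferMatrix:
    """Invert a square transfer matrix via cofactor expansion.

    Practical for the small (p <= 4) matrices this package works with.
    """
    if tm.rows != tm.cols:
        raise ValueError("inverse requires a square transfer matrix")
    n = tm.rows
    var = tm.var
    det = _det(tm.entries, var).cancel(1e-9)
    if det.is_zero:
        raise SingularMatrixError("transfer matrix determinant is identically zero")
    if n == 1:
        return TransferMatrix([[(1.0 / det).cancel(1e-9)]],
                              list(tm.col_names), list(tm.row_names))
    out = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            minor = [[tm.entries[r][c] for c in range(n) if c != j]
                     for r in range(n) if r != i]
            cof = _det(minor, var)
            if (i + j) % 2 == 1:
                cof = -cof
            out[j][i] = (cof / det).cancel(1e-9)  # adjugate transposes indices
    return TransferMatrix(out, list(tm.col_names), list(tm.row_names))


def _clustered_residues(rf: RationalFunction):
    """Partial fractions with pole clustering; returns (terms, poly_part).

    Each term is ``(residue, pole, power)`` contributing
    ``residue * t**(power-1)/ (power-1)! * exp(pole*t)`` to the kernel.
    """
    all_poles = rf.poles()
    scale = max(1.0, np.max(np.abs(all_poles)) if all_poles.size else 0.0)
    r, p, k = scipy.signal.residue(rf.num, rf.den, tol=ROOT_CLUSTER_RTOL * scale,
                                   rtype="avg")
    terms = []
    i = 0
    while i < len(p):
        j = i
        while j + 1 < len(p) and abs(p[j + 1] - p[i]) <= 1e-12 * scale:
            j += 1
        # scipy lists repeated poles consecutively with powers 1..(j-i+1)
        for power, idx in enumerate(range(i, j + 1), start=1):
            terms.append((r[idx], p[idx], power))
        i = j + 1
    return terms, k


def impulse_kernel(rf: RationalFunction, t_grid) -> np.ndarray:
    """Inverse Laplace transform of a strictly proper ``rf`` on ``t_grid``.

    Uses partial fractions with clustered poles, so distinct-real,
    complex-conjugate, and repeated poles (polynomial-times-exponential
    terms) are all handled.  The result is real.
    """
    if rf.var != "s":
        raise ValueError("impulse_kernel requires a continuous-time (var='s') entry")
    if not rf.is_strictly_proper:
        raise ValueError("impulse_kernel requires a strictly proper rational function")
    t = np.asarray(t_grid, dtype=float)
    if rf.is_zero:
        return np.zeros_like(t)
    terms, _ = _clustered_residues(rf)
    out = np.zeros(t.shape, dtype=complex)
    for res, pole, power in terms:
        out += res * t ** (power - 1) / math.factorial(power - 1) * np.exp(pole * t)
    imag_scale = np.max(np.abs(out)) or 1.0
    if np.max(np.abs(out.imag)) > 1e-8 * imag_scale:
        raise ValueError("kernel has a non-negligible imaginary part; "
                         "complex poles did not pair up")
    return np.real(out)


def _require_stable(rf: RationalFunction, what: str):
    p = rf.poles()
    if rf.var == "s":
        bad = p[np.real(p) >= 0] if p.size else np.array([])
    else:
        bad = p[np.abs(p) >= 1] if p.size else np.array([])
    if bad.size:
        raise UnstableEntryError(
            f"{what} undefined: pole {bad[0]:.6g} is not strictly stable"
        )


def hinf_norm(rf: RationalFunction, n_grid: int = 2000) -> float:
    """Worst-case gain sup_w |rf(jw)| of a stable proper entry.

    A dense log-spaced frequency sweep over [1e-6, 1e6] (plus DC) locates the
    peak, then a bounded scalar maximization refines it.
    """
    if rf.var != "s":
        raise ValueError("hinf_norm is defined for continuous-time entries")
    if rf.is_zero:
        return 0.0
    if not rf.is_proper:
        raise ValueError("hinf_norm requires a proper rational function")
    _require_stable(rf, "H-infinity norm")

    def gain(w):
        return abs(rf(1j * w))

    grid = np.concatenate(([0.0], np.logspace(-6, 6, n_grid)))
    vals = np.array([gain(w) for w in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    best = vals[k]
    if hi > lo:
        res = scipy.optimize.minimize_scalar(
            lambda w: -gain(w), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12 * max(1.0, hi)},
        )
        best = max(best, -res.fun)
    return float(best)


def h2_norm(rf: RationalFunction) -> float:
    """H2 norm ( (1/2pi) integral |rf(jw)|^2 dw )**0.5 of a strictly proper
    stable entry, computed exactly via the controllability Gramian."""
    if rf.var != "s":
        raise ValueError("h2_norm is defined for continuous-time entries")
    if rf.is_zero:
        return 0.0
    if not rf.is_strictly_proper:
        raise ValueError("h2_norm requires a strictly proper rational function")
    _require_stable(rf, "H2 norm")
    A, B, C, D = scipy.signal.tf2ss(rf.num, rf.den)
    P = scipy.linalg.solve_continuous_lyapunov(A, -B @ B.T)
    val = float(np.squeeze(C @ P @ C.T))
    return math.sqrt(max(val, 0.0))
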