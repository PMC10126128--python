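"""Nonlinear DNA crossbar-array read-out solver.

The array is a resistive ladder network: wordlines (rows) and bitlines
(columns) are chains of interconnect segments of resistance ``R_int``; a DNA
memory cell (a nonlinear resistor described by an I-V lookup table) bridges
the wordline and bitline node at every junction.  To read row ``i`` a bias
``V_in`` is applied to that wordline through one lead segment, all other
wordlines float, and every bitline is grounded at the bottom of its column;
the currents through the grounding segments are the measured read-out.

Two solvers are provided:

* :func:`solve_kirchhoff` — the reference nodal-analysis solution.  Each
  cell is linearized at its operating point through the I-V secant and the
  linear network is solved exactly; the linearization is iterated (starting
  from the secant at 0.05 V) until node voltages settle.  The linear solves
  exploit the ladder structure: bitline chains are eliminated exactly
  (tridiagonal), leaving a block-tridiagonal system over wordline nodes that
  is factored once and re-solved cheaply; the driven-row lead enters by a
  Sherman-Morrison rank-one update, and conductance drift is absorbed by an
  Anderson-accelerated residual iteration with adaptive refactorization.
* :func:`iterate_parametric` — the fast approximation: a closed-form
  voltage-distribution expression along the driven wordline, scaled by
  row/column sneak-path factors ``alpha_i`` / ``beta_j`` that are calibrated
  once against the Kirchhoff solution of the homogeneous array at the mean
  cell conductance.

Both report read-out currents per bitline; :func:`readout_map` drives every
row in turn to produce the full current map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .transport import IVTable

__all__ = [
    "CrossbarSpec",
    "SneakParams",
    "CrossbarState",
    "ReadoutMap",
    "CellBank",
    "LinearCells",
    "ConvergenceError",
    "solve_kirchhoff",
    "estimate_sneak_parameters",
    "voltage_distribution",
    "iterate_parametric",
    "readout_map",
    "array_power",
]

#: seed voltage for the initial conductance linearization (V)
SEED_VOLTAGE = 0.05
#: cell voltages below this use the seed-voltage secant (avoids 0/0)
SECANT_FLOOR = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when the nonlinear iteration fails to settle."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


class CellBank:
    """Per-cell nonlinear I-V model of an ``m x n`` array.

    ``bits`` selects the logic-1 (``iv1``) or logic-0 (``iv0``) species per
    cell; ``delta`` is a scalar or per-cell Fermi offset (eV) applied by
    interpolation in the tables' delta axis.
    """

    def __init__(self, bits: np.ndarray, iv0: IVTable, iv1: IVTable, delta=0.0):
        self.bits = np.asarray(bits)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be binary")
        self.iv0 = iv0
        self.iv1 = iv1
        self.delta = np.broadcast_to(np.asarray(delta, float), self.bits.shape)

    @property
    def shape(self):
        return self.bits.shape

    def current(self, v: np.ndarray) -> np.ndarray:
        """Cell currents (A) at per-cell voltages ``v``.

        The tables cover ``V >= 0``; negative drops (cells back-fed through
        sneak paths on floating rows) use the odd extension
        ``I(-V) = -I(V)``.
        """
        v = np.asarray(v, float)
        mag = np.minimum(np.abs(v), self.iv0.bias_grid[-1])
        i0 = self.iv0.interpolate(mag, self.delta)
        i1 = self.iv1.interpolate(mag, self.delta)
        return np.sign(v) * np.where(self.bits == 1, i1, i0)

    def secant_conductance(self, v: np.ndarray) -> np.ndarray:
        """Secant conductance ``I(|V|)/|V|``; tiny drops use the 0.05 V secant."""
        v = np.abs(np.asarray(v, float))
        v_eff = np.where(v >= SECANT_FLOOR, v, SEED_VOLTAGE)
        return self.current(v_eff) / v_eff

    def tangent_conductance(self, v: np.ndarray) -> np.ndarray:
        """Slope dI/dV of the interpolated I-V at per-cell voltages ``v``.

        For the piecewise-bilinear tables this is the exact bracketing
        segment slope (an even function of ``v``), which makes it the exact
        per-cell Jacobian of :meth:`current` away from table knots.
        """
        bg = self.iv0.bias_grid
        v = np.minimum(np.abs(np.asarray(v, float)), bg[-1])
        idx = np.clip(np.searchsorted(bg, v, side="right") - 1, 0, bg.size - 2)
        lo, hi = bg[idx], bg[idx + 1]
        return (self.current(hi) - self.current(lo)) / (hi - lo)


class LinearCells:
    """Ohmic cells of fixed per-cell conductance (calibration and tests)."""

    def __init__(self, conductance, shape=None):
        g = np.asarray(conductance, dtype=float)
        if g.ndim == 0:
            if shape is None:
                raise ValueError("shape required for scalar conductance")
            g = np.full(shape, float(g))
        self.G = g

    @property
    def shape(self):
        return self.G.shape

    def current(self, v):
        return self.G * np.asarray(v, float)

    def secant_conductance(self, v):
        return self.G.copy()

    def tangent_conductance(self, v):
        return self.G.copy()


@dataclass
class CrossbarSpec:
    """Array geometry, interconnects, stored bits and species I-V tables."""

    bits: np.ndarray
    iv0: IVTable | None
    iv1: IVTable | None
    r_int: float
    v_in: float = 1.0
    delta: float | np.ndarray = 0.0

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("bits must be an m x n matrix")
        if self.r_int <= 0:
            raise ValueError("R_int must be positive")

    @property
    def m(self) -> int:
        return self.bits.shape[0]

    @property
    def n(self) -> int:
        return self.bits.shape[1]

    def cells(self) -> CellBank:
        return CellBank(self.bits, self.iv0, self.iv1, self.delta)


@dataclass
class SneakParams:
    """Calibrated row/column sneak-path scaling factors.

    ``alpha_i`` (one per driven row) lies in (0, 1]: parasitics can only
    degrade the wordline voltage.  ``beta_j`` (one per column) is positive
    but may exceed 1: far columns collect net sneak inflow from the floating
    rows, so the measured bitline current can exceed the driven cell's own
    current.  Both are independent of the read bias.
    """

    alpha: np.ndarray
    beta: np.ndarray
    g_avg: float
    variant: str = "full"


@dataclass
class CrossbarState:
    """Converged solution of one driven-row read."""

    driven_row: int
    V: np.ndarray               # (m, n) cell voltages
    i_bitline: np.ndarray       # (n,) currents at the bitline grounds
    iterations: int
    max_residual: float         # max |KCL residual| (A) for kirchhoff
    solver: str
    power: float = np.nan       # total dissipated power (W), kirchhoff only
    i_source: float = np.nan    # source current (A), kirchhoff only
    node_voltages: tuple | None = None  # (Vw, Vb) for kirchhoff


@dataclass
class ReadoutMap:
    """Row-by-row read of the full array."""

    I_out: np.ndarray           # (m, n): row i = bitline currents driving row i
    V_read: np.ndarray          # (m, n): V_ij from the read that drives row i
    power: np.ndarray           # (m,) total power per read (kirchhoff)
    solver: str

    @property
    def mean_power(self) -> float:
        p = self.power[~np.isnan(self.power)]
        return float(p.mean()) if p.size else float("nan")


# ----------------------------------------------------------------- kirchhoff


class _LadderFactor:
    """Exact factorization of the linear ladder network at fixed cell G.

    Bitline chains are eliminated per column (tridiagonal solves), leaving a
    block-tridiagonal system over wordline nodes, one dense ``m x m`` block
    per column, whose block-Thomas inverses are stored so new right-hand
    sides re-solve in O(n m^2).  The driven-row lead is *not* part of the
    factorization (applied via Sherman-Morrison), so one factorization
    serves every driven row.
    """

    def __init__(self, m: int, n: int, g: float, G: np.ndarray):
        self.m, self.n, self.g = m, n, g
        self.G = G.copy()
        # the factorization is only a preconditioner for the residual
        # iteration, so it is built and applied in single precision; the
        # converged solution's accuracy is set by the float64 residuals
        # work in units of g; single precision unless the cells are so weak
        # relative to the interconnect that the nearly-floating wordline
        # chains would fall below float32 resolution
        well_grounded = (G.min() / g) * min(m, n) > 3e-4
        dt = np.float32 if well_grounded else np.float64
        self.dtype = dt
        Gs = (G / g).astype(dt)
        eye = np.eye(m, dtype=dt)
        self.Binv = np.empty((n, m, m), dtype=dt)
        self.BG = np.empty((n, m, m), dtype=dt)
        D = np.empty((n, m, m), dtype=dt)
        ab = np.zeros((3, m), dtype=dt)
        w_links = np.full(max(n, 1), 2.0, dtype=dt)
        w_links[0] -= 1.0
        w_links[-1] -= 1.0
        idx = np.arange(m)
        for j in range(n):
            Gj = Gs[:, j]
            # bitline chain: m-1 inter-row links plus the grounding segment
            bdiag = Gj + dt(2.0)
            bdiag[0] = Gj[0] + dt(1.0)
            ab[:] = 0.0
            ab[0, 1:] = -1.0
            ab[1, :] = bdiag
            ab[2, :-1] = -1.0
            Binv = sla.solve_banded((1, 1), ab, eye)
            self.Binv[j] = Binv
            BG = Binv * Gj[None, :]
            self.BG[j] = BG
            D[j] = -Gj[:, None] * BG
            D[j][idx, idx] += Gj + w_links[j]
        # block-Thomas inverses
        self.M = np.empty((n, m, m), dtype=dt)
        self.M[0] = np.linalg.inv(D[0])
        for j in range(1, n):
            self.M[j] = np.linalg.inv(D[j] - self.M[j - 1])
        self._lead_cache: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}

    def resolve(self, Rw: np.ndarray, Rb: np.ndarray):
        """Solve the lead-free network for wordline/bitline RHS (A)."""
        m, n = self.m, self.n
        dt = self.dtype
        inv_g = dt(1.0 / self.g)
        Vw = np.empty((m, n), dtype=dt)
        # reduce bitline RHS onto wordline equations (batched BLAS);
        # diag(G) Binv == BG^T since Binv is symmetric
        RbT = np.asarray(Rb.T, dtype=dt)[:, :, None]
        Rp = (
            np.asarray(Rw, dtype=dt)
            + (np.swapaxes(self.BG, 1, 2) @ RbT)[:, :, 0].T
        ) * inv_g
        h = np.empty((m, n), dtype=dt)
        h[:, 0] = self.M[0] @ Rp[:, 0]
        for j in range(1, n):
            h[:, j] = self.M[j] @ (Rp[:, j] + h[:, j - 1])
        Vw[:, n - 1] = h[:, n - 1]
        for j in range(n - 2, -1, -1):
            Vw[:, j] = h[:, j] + self.M[j] @ Vw[:, j + 1]
        Vb = (self.Binv @ RbT)[:, :, 0].T * inv_g + (
            self.BG @ Vw.T[:, :, None]
        )[:, :, 0].T
        return Vw.astype(float), Vb.astype(float)

    def solve_with_lead(self, driven_row: int, Rw: np.ndarray, Rb: np.ndarray):
        """Solve with the lead conductance g added at wl(driven_row, 0)."""
        uw, ub, denom = self._lead_vec(driven_row)
        xw, xb = self.resolve(Rw, Rb)
        c = self.g * xw[driven_row, 0] / denom
        return xw - c * uw, xb - c * ub

    def _lead_vec(self, driven_row: int):
        try:
            return self._lead_cache[driven_row]
        except KeyError:
            ew = np.zeros((self.m, self.n))
            ew[driven_row, 0] = 1.0
            uw, ub = self.resolve(ew, np.zeros((self.m, self.n)))
            denom = 1.0 + self.g * uw[driven_row, 0]
            self._lead_cache[driven_row] = (uw, ub, denom)
            return uw, ub, denom


def _kcl_residual(cells, g, driven_row, v_in, Vw, Vb):
    """Nonlinear KCL residual (A) at every node of the network.

    Cell branches carry the true table current ``I_cell(Vw - Vb)``;
    the residual vanishes exactly at the converged read.
    """
    m, n = Vw.shape
    i_cell = cells.current(Vw - Vb)
    rw = -i_cell
    rb = i_cell.copy()
    if n > 1:  # wordline chains
        d = g * (Vw[:, 1:] - Vw[:, :-1])
        rw[:, :-1] += d
        rw[:, 1:] -= d
    rw[driven_row, 0] += g * (v_in - Vw[driven_row, 0])  # lead
    if m > 1:  # bitline chains
        d = g * (Vb[1:, :] - Vb[:-1, :])
        rb[:-1, :] += d
        rb[1:, :] -= d
    rb[-1, :] -= g * Vb[-1, :]  # grounding segment
    return rw, rb


def _solve_read(
    cells,
    r_int,
    v_in,
    driven_row,
    tol=1e-6,
    max_iter=200,
    factor=None,
    g_init=None,
    rtol_linear=1e-10,
):
    """Nonlinear Kirchhoff solve of one read; returns (state, factor).

    Preconditioned residual iteration: the nonlinear KCL residual (true
    table currents in every cell branch) is repeatedly solved through the
    factorized linear ladder network whose cells hold secant conductances —
    seeded at 0.05 V, refreshed (with a refactorization) only if progress
    stalls — with Anderson mixing to remove the slowly contracting error
    modes.  Each update is one O(n m^2) re-solve, and convergence is
    declared on both the node-voltage change (``tol``, volts) and the KCL
    residual (``rtol_linear`` relative to the source current ``g v_in``).
    """
    m, n = cells.shape
    if not (0 <= driven_row < m):
        raise ValueError("driven_row out of range")
    g = 1.0 / r_int
    if factor is None:
        G = (
            g_init.copy()
            if g_init is not None
            else cells.secant_conductance(np.full((m, n), SEED_VOLTAGE))
        )
        factor = _LadderFactor(m, n, g, G)
    lin_tol = rtol_linear * g * max(abs(v_in), 1e-12)

    mn = m * n
    x = np.zeros(2 * mn)
    history: list[float] = []
    refactors = 0
    X: list[np.ndarray] = []
    F: list[np.ndarray] = []
    depth = 3  # Anderson mixing depth
    it = 0
    for it in range(1, max_iter + 1):
        Vw = x[:mn].reshape(m, n)
        Vb = x[mn:].reshape(m, n)
        rw, rb = _kcl_residual(cells, g, driven_row, v_in, Vw, Vb)
        resid = max(np.abs(rw).max(), np.abs(rb).max())
        history.append(resid)
        if (
            len(history) >= 5
            and resid > 0.5 * history[-5]
            and refactors < 4
        ):
            # stalled: the factorization no longer tracks the operating
            # point; rebuild at the tangent slopes (the exact per-cell
            # Jacobian for the piecewise-linear tables) and restart mixing
            factor = _LadderFactor(m, n, g, cells.tangent_conductance(Vw - Vb))
            refactors += 1
            X.clear()
            F.clear()
        dw, db = factor.solve_with_lead(driven_row, rw, rb)
        dv = max(np.abs(dw).max(), np.abs(db).max())  # predicted next step
        if resid <= lin_tol and dv <= tol:
            break
        f = np.concatenate([dw.ravel(), db.ravel()])
        # Anderson mixing over the preconditioned fixed point x -> x + P r(x)
        X.append(x)
        F.append(f)
        if len(X) > depth:
            X.pop(0)
            F.pop(0)
        if len(X) >= 2:
            dX = np.stack([X[i + 1] - X[i] for i in range(len(X) - 1)], axis=1)
            dF = np.stack([F[i + 1] - F[i] for i in range(len(F) - 1)], axis=1)
            gamma, *_ = np.linalg.lstsq(dF, f, rcond=None)
            x_new = x + f - (dX + dF) @ gamma
        else:
            x_new = x + f
        x = x_new
    else:
        raise ConvergenceError(
            f"read of row {driven_row} did not converge in {max_iter} iterations "
            f"(last residual {history[-1]:.3e} A)",
            history,
        )

    v_cells = Vw - Vb
    i_bitline = g * Vb[-1, :]
    i_source = g * (v_in - Vw[driven_row, 0])
    power = _dissipated_power(g, cells, driven_row, v_in, Vw, Vb, v_cells)
    state = CrossbarState(
        driven_row=driven_row,
        V=v_cells,
        i_bitline=i_bitline,
        iterations=it,
        max_residual=resid,
        solver="kirchhoff",
        power=power,
        i_source=i_source,
        node_voltages=(Vw, Vb),
    )
    return state, factor


def _dissipated_power(g, cells, driven_row, v_in, Vw, Vb, v_cells):
    """Total power: cells (V.I at the nonlinear I-V) + every interconnect."""
    p = float(np.sum(v_cells * cells.current(v_cells)))  # odd I-V: always >= 0
    if Vw.shape[1] > 1:
        p += float(np.sum(g * (Vw[:, 1:] - Vw[:, :-1]) ** 2))
    if Vw.shape[0] > 1:
        p += float(np.sum(g * (Vb[1:, :] - Vb[:-1, :]) ** 2))
    p += float(np.sum(g * Vb[-1, :] ** 2))          # grounding segments
    p += g * (v_in - Vw[driven_row, 0]) ** 2        # lead segment
    return p


def solve_kirchhoff(
    spec: CrossbarSpec,
    driven_row: int,
    cells=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CrossbarState:
    """Reference nodal solution of one driven-row read.

    The nonlinear cells are linearized through their I-V secants and the
    linear ladder network is solved exactly; the linearization point is
    iterated (seeded from the 0.05 V secant) until the largest node-voltage
    change drops below ``tol`` volts.  Oscillations trigger a damped update;
    persistent non-convergence raises :class:`ConvergenceError` carrying the
    residual history.
    """
    if cells is None:
        cells = spec.cells()
    state, _ = _solve_read(
        cells, spec.r_int, spec.v_in, driven_row, tol=tol, max_iter=max_iter
    )
    return state


# ---------------------------------------------------------------- parametric


def voltage_distribution(
    G_row: np.ndarray,
    g_int: float,
    alpha_i: float,
    v_in: float,
    variant: str = "full",
) -> np.ndarray:
    """Driven-row cell voltages from the closed-form wordline expression.

    ``V_ij = [1 + sum_{k>j} G_ik sum_{w=j+1}^{k} 1/g] /
    [1 + sum_k G_ik sum_w 1/g] * V_in * alpha_i``.

    ``variant="literal"`` takes every empty inner sum (upper index below the
    lower index) as zero; the denominator then equals the numerator for all
    columns and the fraction collapses to one, leaving ``V_in alpha_i``
    (the column dependence must live entirely in ``beta_j``).
    ``variant="full"`` starts the denominator's inner sum at ``w = 1`` so it
    accumulates the whole wordline voltage divider; this variant tracks the
    Kirchhoff solution and is the shipped default.
    """
    G_row = np.asarray(G_row, float)
    if g_int <= 0:
        raise ValueError("interconnect conductance must be positive")
    n = G_row.size
    r = 1.0 / g_int
    k = np.arange(1, n + 1)
    j = np.arange(1, n + 1)[:, None]  # column index of the cell being read
    seg = np.clip(k[None, :] - j, 0, None) * r       # sum_{w=j+1}^{k} 1/g
    numer = 1.0 + (G_row[None, :] * seg).sum(axis=1)
    if variant == "literal":
        denom = numer
    elif variant == "full":
        denom = 1.0 + float((G_row * k * r).sum())
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return numer / denom * (v_in * alpha_i)


def _homogeneous_reference(m, n, r_int, g_avg, v_in):
    """Kirchhoff solution of the homogeneous linear array, every row driven.

    Returns the driven-row cell voltages ``V[i, j]`` and measured bitline
    currents ``I[i, j]`` for each driven row ``i``.  One factorization is
    shared by all reads (the cells are linear).
    """
    cells = LinearCells(g_avg, (m, n))
    V = np.empty((m, n))
    I = np.empty((m, n))
    factor = None
    for i in range(m):
        st, factor = _solve_read(cells, r_int, v_in, i, factor=factor)
        V[i] = st.V[i]
        I[i] = st.i_bitline
    return V, I


def estimate_sneak_parameters(
    m: int,
    n: int,
    r_int: float,
    g_avg: float,
    v_in: float = 1.0,
    variant: str = "full",
) -> SneakParams:
    """Calibrate ``alpha_i`` and ``beta_j`` against the Kirchhoff oracle.

    The homogeneous array (every cell linear at the mean conductance
    ``g_avg``) is solved exactly for every driven row.  ``alpha_i`` is the
    mean over columns of the ratio between the solved driven-row cell
    voltage and the closed-form wordline fraction at ``alpha = 1``;
    ``beta_j`` is the mean over rows of the measured bitline current over
    the driven cell's own current.  Both are independent of ``v_in`` (the
    reference network is linear).
    """
    if g_avg <= 0:
        raise ValueError("g_avg must be positive")
    V, I = _homogeneous_reference(m, n, r_int, g_avg, v_in)
    G_row = np.full(n, g_avg)
    f = voltage_distribution(G_row, 1.0 / r_int, 1.0, 1.0, variant=variant)
    alpha = (V / (v_in * f[None, :])).mean(axis=1)
    beta = (I / (g_avg * V)).mean(axis=0)
    return SneakParams(alpha=alpha, beta=beta, g_avg=g_avg, variant=variant)


def iterate_parametric(
    spec: CrossbarSpec,
    driven_row: int,
    sneak: SneakParams,
    cells=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CrossbarState:
    """Fast parametric read of one row using calibrated alpha/beta.

    Seeds the driven row's conductances from the 0.05 V secant, alternates
    the closed-form voltage distribution with conductance updates
    ``G_ij = I_DNA(V_ij)/V_ij`` until the voltages settle, then reports the
    measured currents ``I_ij = beta_j I_DNA(V_ij)``.
    """
    if cells is None:
        cells = spec.cells()
    m, n = cells.shape
    g_int = 1.0 / spec.r_int
    alpha_i = float(sneak.alpha[driven_row])

    def row_secant(v_row):
        v = np.full((m, n), SEED_VOLTAGE)
        v[driven_row, :] = v_row
        return cells.secant_conductance(v)[driven_row, :]

    v_row = np.full(n, SEED_VOLTAGE)
    G_row = row_secant(v_row)
    damping = 1.0
    prev_dv = np.inf
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        v_new = voltage_distribution(
            G_row, g_int, alpha_i, spec.v_in, variant=sneak.variant
        )
        dv = float(np.abs(v_new - v_row).max())
        history.append(dv)
        v_row = v_new
        if dv < tol:
            break
        G_new = row_secant(v_row)
        if dv > prev_dv * 1.000001:
            damping = 0.5
        G_row = G_row + damping * (G_new - G_row)
        prev_dv = dv
    else:
        raise ConvergenceError(
            f"parametric read of row {driven_row} did not converge", history
        )

    v_full = np.zeros((m, n))
    v_full[driven_row, :] = v_row
    i_row = cells.current(v_full)[driven_row, :]
    return CrossbarState(
        driven_row=driven_row,
        V=v_full,
        i_bitline=sneak.beta * i_row,
        iterations=it,
        max_residual=np.nan,
        solver="parametric",
    )


def readout_map(
    spec: CrossbarSpec,
    solver: str = "kirchhoff",
    sneak: SneakParams | None = None,
    tol: float = 1e-6,
    cells=None,
) -> ReadoutMap:
    """Read every row sequentially and assemble the current map.

    Row ``i`` of ``I_out`` holds the bitline currents measured while row
    ``i`` is driven; ``V_read[i, j]`` is the voltage across cell ``(i, j)``
    during its own read.  For the Kirchhoff solver one network factorization
    is shared across reads (conductances warm-started from the previous
    read) and the per-read total power is recorded.
    """
    if cells is None:
        cells = spec.cells()
    m, n = cells.shape
    I_out = np.empty((m, n))
    V_read = np.empty((m, n))
    power = np.full(m, np.nan)
    if solver == "kirchhoff":
        factor = None
        for i in range(m):
            st, factor = _solve_read(
                cells, spec.r_int, spec.v_in, i, tol=tol, factor=factor
            )
            I_out[i] = st.i_bitline
            V_read[i] = st.V[i]
            power[i] = st.power
    elif solver == "parametric":
        if sneak is None:
            g_avg = float(
                cells.secant_conductance(np.full((m, n), SEED_VOLTAGE)).mean()
            )
            sneak = estimate_sneak_parameters(m, n, spec.r_int, g_avg, spec.v_in)
        for i in range(m):
            st = iterate_parametric(spec, i, sneak, cells=cells, tol=tol)
            I_out[i] = st.i_bitline
            V_read[i] = st.V[i]
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return ReadoutMap(I_out=I_out, V_read=V_read, power=power, solver=solver)


def array_power(spec: CrossbarSpec, cells=None, tol: float = 1e-6) -> float:
    """Average total power (W) over sequential row reads (Kirchhoff).

    Power needs branch currents, so it is always evaluated on the Kirchhoff
    solution: cells dissipate ``V_ij I_DNA(V_ij)`` and every interconnect
    segment ``I^2 R_int``.
    """
    rm = readout_map(spec, solver="kirchhoff", tol=tol, cells=cells)
    return rm.mean_power
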