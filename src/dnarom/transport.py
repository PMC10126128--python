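"""Decoherent quantum transport through a nucleotide-blocked Hamiltonian.

A DNA duplex between two metallic contacts is treated in the non-equilibrium
Green's function picture with Büttiker dephasing probes.  The open-system
retarded Green's function is

    [E - (H_b + Sigma_L + Sigma_R + Sigma_B)] G^r = I,

with wide-band contact self-energies ``Sigma_{L,R} = -i Gamma_{L,R}/2`` on the
3' and 5' terminal nucleotide blocks and a probe self-energy
``-i Gamma_k/2`` on every other nucleotide block.  Probe-to-probe/contact
transmissions ``T_kl = Tr(Gamma_k G^r Gamma_l G^a)`` feed the elimination of
the probe terminals: each fictitious probe floats to the occupation that makes
its energy-resolved current vanish, leaving the effective two-terminal
transmission

    T_eff(E) = T_LR(E) + sum_kl T_Lk [W^-1]_kl T_lR,

where ``W_kl = (1 - R_kk) delta_kl - T_kl (1 - delta_kl)`` over the probe
index set.  The terminal current is the Landauer integral of ``T_eff`` over
the bias window between the contact Fermi levels, ``E_fR = E_fL + q V_bias``.

Currents are reported in amperes with the spin-degenerate prefactor
``2e^2/h``; the sign convention is positive current flowing left→right for
positive bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .basis import BlockHamiltonian, apply_bias_ramp

__all__ = [
    "CONDUCTANCE_QUANTUM",
    "TransportParams",
    "SelfEnergySet",
    "TransmissionResult",
    "IVTable",
    "DecoherenceEliminationError",
    "build_self_energies",
    "fermi",
    "retarded_green",
    "transmission_matrix",
    "effective_transmission",
    "transmission_spectrum",
    "terminal_current",
    "terminal_currents_lr",
    "probe_balance_residual",
    "iv_sweep",
    "find_transmission_peaks",
]

#: 2 e^2 / h in siemens (spin-degenerate conductance quantum)
CONDUCTANCE_QUANTUM = 7.748091729863649e-05


class DecoherenceEliminationError(RuntimeError):
    """Raised when the probe-elimination matrix W cannot be inverted."""


@dataclass
class TransportParams:
    """Contact/probe couplings and integration settings.

    Parameters
    ----------
    gamma_contact : float
        Contact broadening ``Gamma_L = Gamma_R`` (eV).  Default 1.0 eV.
    gamma_probe : float
        Dephasing-probe coupling ``Gamma_k`` (eV).  Default 0.010 eV.
    kT : float
        Thermal energy (eV); default 0.0259 eV (300 K).
    e_f_left : float
        Left-contact Fermi energy ``E_fL`` (eV).
    v_bias : float
        Applied bias (V); sets ``E_fR = E_fL + q V_bias``.
    energy_step : float
        Integration grid spacing (eV).  Default 1 meV, resolving the 10 meV
        probe broadening.
    fermi_margin : float
        Half-width of the integration window beyond the Fermi window, in
        units of ``kT``.  Default 10.
    """

    gamma_contact: float = 1.0
    gamma_probe: float = 0.010
    kT: float = 0.0259
    e_f_left: float = 0.0
    v_bias: float = 0.0
    energy_step: float = 1e-3
    fermi_margin: float = 10.0

    def __post_init__(self):
        if self.gamma_contact < 0 or self.gamma_probe < 0:
            raise ValueError("couplings must be nonnegative")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def e_f_right(self) -> float:
        return self.e_f_left + self.v_bias

    def energy_window(self) -> tuple[float, float]:
        lo = min(self.e_f_left, self.e_f_right) - self.fermi_margin * self.kT
        hi = max(self.e_f_left, self.e_f_right) + self.fermi_margin * self.kT
        return lo, hi

    def energy_grid(self) -> np.ndarray:
        lo, hi = self.energy_window()
        n = max(int(np.ceil((hi - lo) / self.energy_step)) + 1, 2)
        return np.linspace(lo, hi, n)


@dataclass
class SelfEnergySet:
    """Diagonal broadening operators for the contact and probe terminals.

    ``coupling`` has one row per terminal, ordered ``[L, probes..., R]``; row
    ``t`` holds the diagonal of ``Gamma_t`` over all orbitals (nonzero only
    on the terminal's nucleotide block).
    """

    coupling: np.ndarray
    probe_sites: list[int] = field(default_factory=list)

    @property
    def n_terminals(self) -> int:
        return self.coupling.shape[0]

    @property
    def n_probes(self) -> int:
        return self.n_terminals - 2

    @property
    def total_gamma(self) -> np.ndarray:
        return self.coupling.sum(axis=0)


def build_self_energies(
    hb: BlockHamiltonian,
    gamma_contact: float = 1.0,
    gamma_probe: float = 0.010,
) -> SelfEnergySet:
    """Attach contacts to the terminal nucleotides and probes elsewhere.

    ``Gamma_{L,R}`` enters as ``gamma_contact`` times the identity on the 3'
    and 5' terminal nucleotide blocks; every other nucleotide carries a
    dephasing probe of strength ``gamma_probe`` (``N_b = N_nuc - 2`` probes).
    A zero ``gamma_probe`` yields a coherent two-terminal system.
    """
    n = hb.n_orbitals
    left, right = hb.contact_sites
    probe_sites = [
        k for k in range(hb.n_nucleotides) if k not in (left, right)
    ]
    if gamma_probe == 0.0:
        probe_sites = []
    C = np.zeros((2 + len(probe_sites), n))
    C[0, hb.block_slice(left)] = gamma_contact
    C[-1, hb.block_slice(right)] = gamma_contact
    for t, k in enumerate(probe_sites, start=1):
        C[t, hb.block_slice(k)] = gamma_probe
    return SelfEnergySet(coupling=C, probe_sites=probe_sites)


def fermi(E: np.ndarray, mu: float, kT: float) -> np.ndarray:
    """Fermi-Dirac occupation, overflow-safe."""
    x = (np.asarray(E, dtype=float) - mu) / kT
    return 0.5 * (1.0 - np.tanh(0.5 * x))


def retarded_green(
    E: float | np.ndarray, hb: BlockHamiltonian, se: SelfEnergySet
) -> np.ndarray:
    """Retarded Green's function at one or many energies.

    Solves ``[E - (H_b + Sigma)] G^r = I`` with
    ``Sigma = -(i/2) sum_t Gamma_t``.  For an energy array of length ``nE``
    the result has shape ``(nE, n, n)`` (batched dense inversion; the blocks
    are small).
    """
    E = np.asarray(E, dtype=float)
    scalar = E.ndim == 0
    Ev = np.atleast_1d(E)
    n = hb.n_orbitals
    A = np.zeros((Ev.size, n, n), dtype=complex)
    A -= hb.H
    half_gamma = 0.5 * se.total_gamma
    idx = np.arange(n)
    A[:, idx, idx] += Ev[:, None] + 1j * half_gamma
    try:
        G = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:  # all Gammas zero, E on an eigenvalue
        raise RuntimeError(f"Green's function system is singular at E={E}") from exc
    return G[0] if scalar else G


@dataclass
class TransmissionResult:
    """Energy-resolved transmissions for the terminal set ``[L, probes, R]``.

    ``T`` has shape ``(nE, nt, nt)`` with zero diagonal, ``T_LR = T[:, 0, -1]``
    the coherent contribution and ``T_eff`` the probe-corrected effective
    transmission.  ``R_kk = 1 - sum_{l != k} T_kl`` are reflection
    probabilities.
    """

    energies: np.ndarray
    T: np.ndarray
    T_eff: np.ndarray

    @property
    def T_LR(self) -> np.ndarray:
        return self.T[:, 0, -1]

    @property
    def R_kk(self) -> np.ndarray:
        return 1.0 - self.T.sum(axis=2)

    def W(self) -> np.ndarray:
        """Probe elimination matrices, shape ``(nE, N_b, N_b)``."""
        return _w_matrix(self.T)


def transmission_matrix(
    G: np.ndarray, se: SelfEnergySet
) -> np.ndarray:
    """All pairwise terminal transmissions from a (batched) Green's function.

    ``T_kl = Tr(Gamma_k G^r Gamma_l G^a)``; for the diagonal broadenings used
    here this reduces to ``sum_ab Gamma_k[a] |G_ab|^2 Gamma_l[b]``.  The
    diagonal ``k = l`` entries are zeroed (self-transmission is not part of
    the multi-probe current formula).  For real Hamiltonians ``T`` is
    symmetric (reciprocity).
    """
    G = np.asarray(G)
    batched = G.ndim == 3
    Gb = G if batched else G[None]
    G2 = Gb.real**2 + Gb.imag**2
    C = se.coupling
    T = np.einsum("ka,eab,lb->ekl", C, G2, C, optimize=True)
    nt = C.shape[0]
    idx = np.arange(nt)
    T[:, idx, idx] = 0.0
    return T if batched else T[0]


def _w_matrix(T: np.ndarray) -> np.ndarray:
    """W over the probe subset: diag(sum_l T_kl) - off-diagonal probe T."""
    nt = T.shape[-1]
    probes = slice(1, nt - 1)
    W = -T[:, probes, probes].copy()
    row_sums = T.sum(axis=2)[:, probes]  # 1 - R_kk
    nb = nt - 2
    idx = np.arange(nb)
    W[:, idx, idx] = row_sums
    return W


def effective_transmission(T: np.ndarray) -> np.ndarray:
    """Probe-corrected transmission ``T_eff = T_LR + T_Lk W^-1_kl T_lR``.

    With no probes this is exactly ``T_LR``.  A singular elimination matrix
    raises :class:`DecoherenceEliminationError` with its condition estimate.
    """
    T = np.asarray(T)
    batched = T.ndim == 3
    Tb = T if batched else T[None]
    nt = Tb.shape[-1]
    t_lr = Tb[:, 0, -1]
    if nt == 2:
        return t_lr if batched else float(t_lr[0])
    W = _w_matrix(Tb)
    try:
        x = np.linalg.solve(W, Tb[:, 1:-1, -1][..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        conds = np.linalg.cond(W)
        raise DecoherenceEliminationError(
            f"singular probe-elimination matrix (max condition {np.max(conds):.3e})"
        ) from exc
    t_eff = t_lr + np.einsum("ek,ek->e", Tb[:, 0, 1:-1], x)
    return t_eff if batched else float(t_eff[0])


def transmission_spectrum(
    hb: BlockHamiltonian,
    se: SelfEnergySet,
    energies: np.ndarray,
) -> TransmissionResult:
    """Energy-resolved ``T`` matrix and ``T_eff`` on a grid."""
    energies = np.asarray(energies, dtype=float)
    G = retarded_green(energies, hb, se)
    T = transmission_matrix(G, se)
    t_eff = effective_transmission(T)
    return TransmissionResult(energies=energies, T=T, T_eff=np.asarray(t_eff))


def terminal_current(
    hb: BlockHamiltonian,
    params: TransportParams,
    spectrum: TransmissionResult | None = None,
) -> float:
    """Terminal (DNA) current in amperes at the params' bias and Fermi level.

    The bias ramp must already be applied to ``hb`` for ``params.v_bias``.
    ``I = (2e^2/h) ∫ T_eff(E) [f_R(E) - f_L(E)] dE`` with
    ``E_fR = E_fL + q V_bias``; the integral runs over the Fermi window
    plus a ``fermi_margin * kT`` guard band (trapezoidal rule).
    """
    if params.v_bias == 0.0:
        return 0.0
    E = params.energy_grid()
    if spectrum is None:
        se = build_self_energies(hb, params.gamma_contact, params.gamma_probe)
        spectrum = transmission_spectrum(hb, se, E)
        t_eff = spectrum.T_eff
    else:
        lo, hi = params.energy_window()
        if spectrum.energies[0] > lo + 1e-12 or spectrum.energies[-1] < hi - 1e-12:
            raise ValueError(
                "precomputed spectrum does not cover the bias integration window"
            )
        E = spectrum.energies
        t_eff = spectrum.T_eff
    f_l = fermi(E, params.e_f_left, params.kT)
    f_r = fermi(E, params.e_f_right, params.kT)
    return CONDUCTANCE_QUANTUM * float(np.trapezoid(t_eff * (f_r - f_l), E))


def terminal_currents_lr(
    hb: BlockHamiltonian, params: TransportParams
) -> tuple[float, float]:
    """Currents at the left and right contacts from the multi-probe balance.

    Probe occupations are reconstructed from the elimination step; electron
    conservation demands ``I_L + I_R = 0``.  Returned in amperes with the
    same sign convention as :func:`terminal_current` at the left contact.
    """
    se = build_self_energies(hb, params.gamma_contact, params.gamma_probe)
    E = params.energy_grid()
    res = transmission_spectrum(hb, se, E)
    f_l = fermi(E, params.e_f_left, params.kT)
    f_r = fermi(E, params.e_f_right, params.kT)
    f_terms = _terminal_occupations(res, f_l, f_r)
    # J_t(E) = sum_l T_tl (f_t - f_l); left terminal t=0, right t=-1
    diff_l = f_terms[:, 0, None] - f_terms
    diff_r = f_terms[:, -1, None] - f_terms
    j_l = np.einsum("el,el->e", res.T[:, 0, :], diff_l)
    j_r = np.einsum("el,el->e", res.T[:, -1, :], diff_r)
    i_l = CONDUCTANCE_QUANTUM * float(np.trapezoid(j_l, E))
    i_r = CONDUCTANCE_QUANTUM * float(np.trapezoid(j_r, E))
    # left-contact current with positive-for-positive-bias orientation
    return -i_l, -i_r


def _terminal_occupations(
    res: TransmissionResult, f_l: np.ndarray, f_r: np.ndarray
) -> np.ndarray:
    """Occupations of all terminals; probes float per the elimination step."""
    nE, nt, _ = res.T.shape
    f = np.empty((nE, nt))
    f[:, 0] = f_l
    f[:, -1] = f_r
    if nt > 2:
        W = res.W()
        phi = np.linalg.solve(W, res.T[:, 1:-1, -1][..., None])[..., 0]
        f[:, 1:-1] = f_l[:, None] + phi * (f_r - f_l)[:, None]
    return f


def probe_balance_residual(hb: BlockHamiltonian, params: TransportParams) -> float:
    """Max relative net probe current after elimination (should be ~0).

    Reconstructs every probe's energy-resolved current
    ``J_k(E) = sum_l T_kl (f_k - f_l)`` using the floated probe occupations
    and normalizes by the largest terminal spectral current.
    """
    se = build_self_energies(hb, params.gamma_contact, params.gamma_probe)
    if se.n_probes == 0:
        return 0.0
    E = params.energy_grid()
    res = transmission_spectrum(hb, se, E)
    f_l = fermi(E, params.e_f_left, params.kT)
    f_r = fermi(E, params.e_f_right, params.kT)
    f_terms = _terminal_occupations(res, f_l, f_r)
    diff = f_terms[:, 1:-1, None] - f_terms[:, None, :]
    J = np.einsum("ekl,ekl->ek", res.T[:, 1:-1, :], diff)
    scale = np.abs(
        np.einsum("el,el->e", res.T[:, 0, :], f_terms[:, 0, None] - f_terms)
    ).max()
    if scale == 0.0:
        return 0.0
    return float(np.abs(J).max() / scale)


@dataclass
class IVTable:
    """Current lookup surface ``I(V_bias, delta)`` for one strand species.

    ``delta`` is the Fermi offset above the HOMO-anchored reference
    ``e_f_anchor`` (eV): the left Fermi level used for column ``d`` was
    ``e_f_anchor + delta_grid[d]``.  ``current`` has shape
    ``(len(bias_grid), len(delta_grid))`` in amperes and is zero in the
    ``V = 0`` row.
    """

    species: str
    bias_grid: np.ndarray
    delta_grid: np.ndarray
    current: np.ndarray
    e_f_anchor: float

    def __post_init__(self):
        self.bias_grid = np.asarray(self.bias_grid, dtype=float)
        self.delta_grid = np.asarray(self.delta_grid, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.current.shape != (self.bias_grid.size, self.delta_grid.size):
            raise ValueError("current surface shape does not match grids")

    def interpolate(self, v, delta):
        """Bilinear interpolation of the current surface (vectorized).

        ``v`` and ``delta`` broadcast against each other; values outside the
        table grids raise ``ValueError`` (the table must bracket the use
        range; no extrapolation).
        """
        v, delta = np.broadcast_arrays(np.asarray(v, float), np.asarray(delta, float))
        bg, dg = self.bias_grid, self.delta_grid
        eps = 1e-12
        if (v.min() < bg[0] - eps or v.max() > bg[-1] + eps
                or delta.min() < dg[0] - eps or delta.max() > dg[-1] + eps):
            raise ValueError("query outside the I-V table grid")
        iv = np.clip(np.searchsorted(bg, v) - 1, 0, bg.size - 2)
        idl = np.clip(np.searchsorted(dg, delta) - 1, 0, dg.size - 2)
        tv = np.clip((v - bg[iv]) / (bg[iv + 1] - bg[iv]), 0.0, 1.0)
        td = np.clip((delta - dg[idl]) / (dg[idl + 1] - dg[idl]), 0.0, 1.0)
        c = self.current
        return (
            c[iv, idl] * (1 - tv) * (1 - td)
            + c[iv + 1, idl] * tv * (1 - td)
            + c[iv, idl + 1] * (1 - tv) * td
            + c[iv + 1, idl + 1] * tv * td
        )

    def current_at(self, v, delta=0.0):
        return self.interpolate(v, delta)

    def zero_bias_resistance(self, delta: float = 0.0) -> float:
        """Secant resistance V/I at the smallest positive grid bias (ohm)."""
        pos = self.bias_grid[self.bias_grid > 0]
        if pos.size == 0:
            raise ValueError("table has no positive bias points")
        v1 = float(pos[0])
        i1 = float(self.interpolate(v1, delta))
        return v1 / i1


def iv_sweep(
    hb: BlockHamiltonian,
    params: TransportParams,
    bias_grid: np.ndarray,
    delta_grid: np.ndarray,
    e_f_anchor: float | None = None,
    species: str = "",
) -> IVTable:
    """Current surface over a bias × Fermi-offset grid.

    For each bias the ramp is applied to a fresh copy of ``hb`` and the
    effective transmission is evaluated once on a grid wide enough for every
    Fermi offset; each ``delta`` column is then a Landauer integral with
    ``E_fL = e_f_anchor + delta``.  The ``V = 0`` row is identically zero.
    """
    bias_grid = np.asarray(bias_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    anchor = params.e_f_left if e_f_anchor is None else float(e_f_anchor)
    margin = params.fermi_margin * params.kT
    current = np.zeros((bias_grid.size, delta_grid.size))
    for bi, v in enumerate(bias_grid):
        if v == 0.0:
            continue
        ramped = apply_bias_ramp(hb, float(v))
        se = build_self_energies(ramped, params.gamma_contact, params.gamma_probe)
        mus = np.concatenate([anchor + delta_grid, anchor + delta_grid + v])
        lo, hi = mus.min() - margin, mus.max() + margin
        n = max(int(np.ceil((hi - lo) / params.energy_step)) + 1, 2)
        E = np.linspace(lo, hi, n)
        t_eff = transmission_spectrum(ramped, se, E).T_eff
        for di, d in enumerate(delta_grid):
            f_l = fermi(E, anchor + d, params.kT)
            f_r = fermi(E, anchor + d + v, params.kT)
            current[bi, di] = CONDUCTANCE_QUANTUM * np.trapezoid(
                t_eff * (f_r - f_l), E
            )
    return IVTable(
        species=species,
        bias_grid=bias_grid,
        delta_grid=delta_grid,
        current=current,
        e_f_anchor=anchor,
    )


def find_transmission_peaks(
    energies: np.ndarray,
    t_eff: np.ndarray,
    prominence_rel: float = 0.01,
) -> np.ndarray:
    """Energies of local maxima of ``T_eff`` above a relative prominence.

    Used to locate the HOMO resonance and its bias-induced shift.  An empty
    array (no peak) is a valid result, not an error.
    """
    t_eff = np.asarray(t_eff, dtype=float)
    if t_eff.size == 0 or np.all(t_eff == 0):
        return np.array([])
    idx, _ = scipy.signal.find_peaks(t_eff, prominence=prominence_rel * t_eff.max())
    return np.asarray(energies)[idx]
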