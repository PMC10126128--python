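"""Orthogonalization and nucleotide-blocking of electronic-structure matrices.

A DNA duplex described in an atomic-orbital basis comes as a pair of real
symmetric matrices: the Fock matrix ``F`` (eV) and the overlap matrix ``S``
(dimensionless, positive definite).  Transport works in an orthogonal basis
whose states are grouped per nucleotide, obtained in two steps:

1. Löwdin symmetric orthogonalization, ``H_a = S^{-1/2} F S^{-1/2}``, which
   maps the generalized eigenproblem ``(F, S)`` onto an ordinary one while
   preserving the spectrum.
2. A block-diagonalizing rotation ``H_b = U^T H_a U`` where ``U`` stacks the
   eigenvectors of each nucleotide's diagonal sub-block of ``H_a``.  The
   diagonal of each diagonal block of ``H_b`` then holds the molecular-orbital
   energies of that nucleotide, and off-diagonal blocks are inter-nucleotide
   electronic couplings.

Under bias, a fixed (non-self-consistent) potential ramp shifts the orbital
energies of base pair ``n`` by ``q V_n``: 40% of the applied voltage drops at
each contact and the remaining 20% drops linearly along the interior pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg as sla

__all__ = [
    "AtomicBasisSystem",
    "BlockHamiltonian",
    "OverlapMatrixError",
    "bias_ramp_voltages",
    "lowdin_orthogonalize",
    "block_diagonalize",
    "apply_bias_ramp",
]

#: elementary charge magnitude (C); energy shifts use q*V == V numerically in eV
ELEMENTARY_CHARGE = 1.602176634e-19


class OverlapMatrixError(ValueError):
    """Raised when the overlap matrix is not usable (non-SPD)."""


@dataclass(frozen=True)
class AtomicBasisSystem:
    """Fock/overlap matrices plus the orbital→nucleotide partition.

    Parameters
    ----------
    F : (n, n) ndarray
        Fock matrix in the atomic basis (eV), real symmetric.
    S : (n, n) ndarray
        Overlap matrix, real symmetric positive definite.
    partition : list of (start, stop)
        Half-open orbital index ranges, one per nucleotide, in strand order.
        The ranges must be disjoint and cover ``0..n``.
    basepair_groups : list of (nuc_a, nuc_b)
        Nucleotide-index pairs forming each base pair, in pair order along
        the strand; every nucleotide appears exactly once.
    """

    F: np.ndarray
    S: np.ndarray
    partition: list[tuple[int, int]]
    basepair_groups: list[tuple[int, int]]

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        S = np.asarray(self.S, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ValueError("F must be square")
        if S.shape != F.shape:
            raise ValueError(
                f"dimension mismatch: F is {F.shape}, S is {S.shape}"
            )
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "S", S)
        n = F.shape[0]
        covered = np.zeros(n, dtype=bool)
        for start, stop in self.partition:
            if not (0 <= start < stop <= n):
                raise ValueError(f"invalid partition range ({start}, {stop})")
            if covered[start:stop].any():
                raise ValueError("partition ranges overlap")
            covered[start:stop] = True
        if not covered.all():
            raise ValueError("partition does not cover all orbital indices")
        seen: set[int] = set()
        for a, b in self.basepair_groups:
            for x in (a, b):
                if not (0 <= x < len(self.partition)) or x in seen:
                    raise ValueError("basepair_groups must cover each nucleotide once")
                seen.add(x)
        if len(seen) != len(self.partition):
            raise ValueError("basepair_groups must cover every nucleotide")


@dataclass
class BlockHamiltonian:
    """Nucleotide-blocked orthogonal Hamiltonian of a DNA duplex.

    Attributes
    ----------
    H : (n, n) ndarray
        Blocked Hamiltonian ``H_b`` (eV); each diagonal block is diagonal.
    U : (n, n) ndarray
        Orthogonal transform with ``H_b = U.T @ H_a @ U``.
    blocks : list of (start, stop)
        Row/column range of each nucleotide block, in nucleotide order.
    contact_sites : (int, int)
        Nucleotide indices of the 3' and 5' terminal contacts.
    basepair_groups : list of (int, int)
        Nucleotide pairs forming each base pair, in pair order.
    """

    H: np.ndarray
    U: np.ndarray
    blocks: list[tuple[int, int]]
    contact_sites: tuple[int, int]
    basepair_groups: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_orbitals(self) -> int:
        return self.H.shape[0]

    @property
    def n_nucleotides(self) -> int:
        return len(self.blocks)

    @property
    def n_basepairs(self) -> int:
        return len(self.basepair_groups)

    def copy(self) -> "BlockHamiltonian":
        return replace(self, H=self.H.copy())

    def block_slice(self, nuc: int) -> slice:
        start, stop = self.blocks[nuc]
        return slice(start, stop)


def lowdin_orthogonalize(system: AtomicBasisSystem) -> np.ndarray:
    """Return the Löwdin-orthogonalized Hamiltonian ``H_a = S^-1/2 F S^-1/2``.

    The eigenvalues of ``H_a`` equal the generalized eigenvalues of
    ``(F, S)``.  Raises :class:`OverlapMatrixError` if ``S`` is not positive
    definite (the smallest offending eigenvalue is reported).
    """
    F, S = system.F, system.S
    w, V = sla.eigh(S)
    if w[0] <= 0.0:
        raise OverlapMatrixError(
            f"overlap matrix is not positive definite: smallest eigenvalue {w[0]:.6e}"
        )
    s_inv_half = (V / np.sqrt(w)) @ V.T
    H_a = s_inv_half @ F @ s_inv_half
    return 0.5 * (H_a + H_a.T)


def block_diagonalize(
    H_a: np.ndarray,
    partition: list[tuple[int, int]],
    contact_sites: tuple[int, int] | None = None,
    basepair_groups: list[tuple[int, int]] | None = None,
) -> BlockHamiltonian:
    """Rotate ``H_a`` so each nucleotide's diagonal block becomes diagonal.

    ``U`` is assembled nucleotide by nucleotide from the eigenvectors of the
    corresponding diagonal sub-block of ``H_a``, ordered by ascending
    eigenvalue with the sign fixed so the largest-magnitude component of each
    eigenvector is positive (deterministic up to degeneracies, which are
    tie-broken by original orbital index by the eigensolver's ordering).

    The spectrum and trace of ``H_a`` are preserved exactly (orthogonal
    similarity).
    """
    H_a = np.asarray(H_a, dtype=float)
    n = H_a.shape[0]
    U = np.zeros((n, n))
    for start, stop in partition:
        if stop <= start:
            raise ValueError(f"empty partition range ({start}, {stop})")
        w, V = sla.eigh(H_a[start:stop, start:stop])
        # deterministic sign: largest-|component| entry made positive
        idx = np.argmax(np.abs(V), axis=0)
        signs = np.sign(V[idx, np.arange(V.shape[1])])
        signs[signs == 0] = 1.0
        U[start:stop, start:stop] = V * signs
    H_b = U.T @ H_a @ U
    H_b = 0.5 * (H_b + H_b.T)
    if contact_sites is None:
        contact_sites = (0, len(partition) - 1)
    if basepair_groups is None:
        basepair_groups = []
    return BlockHamiltonian(
        H=H_b,
        U=U,
        blocks=[(int(a), int(b)) for a, b in partition],
        contact_sites=contact_sites,
        basepair_groups=list(basepair_groups),
    )


def bias_ramp_voltages(n_basepairs: int, v_bias: float) -> np.ndarray:
    """Per-base-pair potentials ``V_n`` (V) of the 40/20/40 ramp.

    ``V_1 = 0`` and ``V_N = V_bias`` at the two contact pairs; 40% of the
    bias drops at each contact and the interior pairs ramp linearly through
    the remaining 20%: ``V_n = V_bias (0.4 + 0.2 (n-2)/(N-3))`` for
    ``2 <= n <= N-1``.

    ``N = 3`` would divide by zero in the interior expression and is
    rejected along with any shorter strand.
    """
    N = int(n_basepairs)
    if N <= 3:
        raise ValueError(
            f"bias ramp needs at least 4 base pairs (interior ramp undefined), got {N}"
        )
    v = np.empty(N)
    v[0] = 0.0
    v[-1] = v_bias
    n = np.arange(2, N)  # 1-based interior indices 2..N-1
    v[1:-1] = v_bias * (0.4 + 0.2 * (n - 2) / (N - 3))
    return v


def apply_bias_ramp(hb: BlockHamiltonian, v_bias: float) -> BlockHamiltonian:
    """Return a copy of ``hb`` with the bias ramp added to the diagonals.

    The electrostatic energy ``q V_n`` (numerically ``V_n`` in eV) is added
    to every diagonal entry of both nucleotide blocks belonging to base pair
    ``n``; off-diagonal couplings are untouched.  ``V_bias = 0`` returns an
    identical Hamiltonian.
    """
    if not hb.basepair_groups:
        raise ValueError("BlockHamiltonian carries no base-pair grouping")
    v = bias_ramp_voltages(len(hb.basepair_groups), v_bias)
    out = hb.copy()
    diag = np.einsum("ii->i", out.H)
    for vn, (a, b) in zip(v, hb.basepair_groups):
        for nuc in (a, b):
            sl = hb.block_slice(nuc)
            diag[sl] += vn
    return out
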