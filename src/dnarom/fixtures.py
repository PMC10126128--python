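"""Surrogate inputs for the full simulation pipeline.

The electronic-structure matrices of the two memory-cell duplexes
(3'-CCCTCCC-5', "CT1C", and 3'-TTTCTTT-5', "TC1T") are not part of this
package; the generators here produce tight-binding stand-ins that reproduce
the features the array studies rely on:

* a two-leg ladder Hamiltonian — several HOMO-manifold orbitals per
  nucleotide on the contacted strand, one off-resonant orbital per
  complementary nucleotide — whose transmission peak sits at the HOMO
  anchor (-5.2 eV) at zero bias and shifts with the sign of the bias;
* mega-ohm-scale low-bias resistance under the standard contact/probe
  couplings (1 eV contacts, 10 meV dephasing probes);
* a conductance contrast between the logic-1 species (CT1C-like: denser,
  more strongly coupled orbital ladder) and the logic-0 species (TC1T-like)
  over the 0-1 V read window;
* current monotone in bias on [0, 1] V and falling monotonically as the
  Fermi level moves from the HOMO anchor into the gap (the delta axis of
  the I-V tables).

Several orbitals per nucleotide are essential here: the read bias drops 40%
at each contact, detuning neighbouring nucleotides by up to 0.4 eV, and a
single-orbital chain then shows strong negative differential resistance.  A
ladder of orbitals (as in a real nucleotide's HOMO manifold) keeps states
flowing into the bias window at every bias, which is what makes the I-V
monotone.

All generators are deterministic given their seed.  These are synthetic
surrogates: they target the qualitative/order-of-magnitude anchors above,
not the quantitative I-V curves of any real duplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .basis import BlockHamiltonian
from .transport import IVTable, TransportParams, iv_sweep

__all__ = [
    "SurrogateSpec",
    "FixtureContractError",
    "surrogate_hamiltonian",
    "surrogate_pair",
    "surrogate_iv_tables",
    "default_iv_tables",
    "random_bits",
    "synthetic_images",
]

#: per-orbital intra-strand hoppings (eV), top (HOMO) first; the top of the
#: ladder is weakly coupled (below the 10 meV probe broadening) so the
#: low-bias conductance stays in the MΩ-GΩ range, while the deeper orbitals
#: carry the high-bias current.
BASE_COUPLINGS = (0.0035, 0.010, 0.02, 0.05, 0.08, 0.11, 0.13)
#: index from which `deep_scale` rescales the hoppings (species contrast)
DEEP_START = 3

#: species defaults: (orbital spacing eV, deep coupling scale, seed offset)
SPECIES_DEFAULTS = {
    "CT1C": {"orbital_spacing": 0.11, "deep_scale": 1.0, "top_scale": 1.0},
    "TC1T": {"orbital_spacing": 0.14, "deep_scale": 0.6, "top_scale": 1.2},
}


class FixtureContractError(RuntimeError):
    """A generated fixture violates its stated contract."""


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of a surrogate duplex Hamiltonian.

    Parameters
    ----------
    species : str
        ``"CT1C"`` (logic 1, higher conductance) or ``"TC1T"`` (logic 0).
    n_basepairs : int
        Number of base pairs (default 7, matching the studied heptamers).
    homo_energy : float
        Target HOMO level (eV); the spectrum is rigidly shifted so the
        highest orbital sits exactly here (default -5.2 eV, the zero-bias
        HOMO anchor).
    orbital_spacing : float
        Energy spacing of the per-nucleotide orbital ladder (eV); larger
        spacing leaves fewer orbitals inside the 1 V read window.
    deep_scale : float
        Scale on the deeper orbitals' hoppings — the conductance-contrast
        knob between the two species.
    top_scale : float
        Scale on the top (HOMO-side) orbitals' hoppings, which set the
        low-bias conductance without affecting the 1 V current much.
    partner_offset, partner_coupling, pair_coupling : float
        Complementary strand orbital depth (eV), its intra-strand hopping
        and the inter-strand (base-pair) hopping.
    contact_coupling_scale : float
        Scale on the hoppings across the two junctions adjacent to the
        contacted terminal nucleotides.  Weak injection junctions set the
        overall current scale (read currents in the nA range, cell
        resistance of tens of MΩ at 1 V) without weakening the interior
        couplings that keep the I-V monotone.
    disorder : float
        Std-dev of seeded on-site disorder (eV), emulating molecular
        inhomogeneity.
    seed : int
        Disorder seed; identical seeds give identical matrices.
    """

    species: str = "CT1C"
    n_basepairs: int = 7
    homo_energy: float = -5.2
    orbital_spacing: float | None = None
    deep_scale: float | None = None
    contact_coupling_scale: float = 0.045
    top_scale: float | None = None
    partner_offset: float = 0.6
    partner_coupling: float = 0.03
    pair_coupling: float = 0.03
    disorder: float = 0.002
    seed: int = 0

    def resolved(self) -> tuple[float, float, float]:
        """(orbital_spacing, deep_scale, top_scale) with species defaults."""
        try:
            d = SPECIES_DEFAULTS[self.species]
        except KeyError:
            if self.orbital_spacing is None or self.deep_scale is None:
                raise ValueError(
                    f"unknown species {self.species!r}: give orbital_spacing "
                    "and deep_scale explicitly"
                ) from None
            d = {}
        spacing = self.orbital_spacing if self.orbital_spacing is not None else d["orbital_spacing"]
        scale = self.deep_scale if self.deep_scale is not None else d["deep_scale"]
        top = self.top_scale if self.top_scale is not None else d.get("top_scale", 1.0)
        return float(spacing), float(scale), float(top)


def surrogate_hamiltonian(spec: SurrogateSpec) -> BlockHamiltonian:
    """Two-leg ladder tight-binding stand-in for a duplex Hamiltonian.

    Nucleotides ``0..N-1`` form the contacted strand (3' terminal at
    nucleotide 0, 5' terminal at ``N-1`` — the two contact sites), each a
    block of ``len(BASE_COUPLINGS)`` orbitals spaced ``orbital_spacing``
    apart; nucleotides ``N..2N-1`` are the complementary strand (one
    off-resonant orbital each).  Neighbouring blocks couple orbital-to-
    orbital with hoppings ``sqrt(t_a t_b) 0.6^|a-b|``.  Base pair ``n``
    groups nucleotides ``n`` and ``N+n``.  The spectrum is rigidly shifted
    so the highest eigenvalue (the HOMO) equals ``spec.homo_energy``.
    """
    N = spec.n_basepairs
    if N < 2:
        raise ValueError("need at least 2 base pairs")
    spacing, deep_scale, top_scale = spec.resolved()
    if spacing <= 0 or deep_scale <= 0 or top_scale <= 0:
        raise ValueError("orbital_spacing, deep_scale and top_scale must be positive")
    t_orb = np.array(BASE_COUPLINGS)
    t_orb[:DEEP_START] *= top_scale
    t_orb[DEEP_START:] *= deep_scale
    n_orb = t_orb.size
    rng = np.random.default_rng(spec.seed)
    sizes = [n_orb] * N + [1] * N
    starts = np.concatenate([[0], np.cumsum(sizes)])
    n_tot = int(starts[-1])
    H = np.zeros((n_tot, n_tot))
    ladder = -spacing * np.arange(n_orb)
    for i in range(N):
        s = starts[i]
        H[range(s, s + n_orb), range(s, s + n_orb)] = ladder + rng.normal(
            0.0, spec.disorder, n_orb
        )
    for i in range(N):
        s = starts[N + i]
        H[s, s] = -spec.partner_offset + rng.normal(0.0, spec.disorder)
    a = np.arange(n_orb)
    C = np.sqrt(np.outer(t_orb, t_orb)) * 0.6 ** np.abs(a[:, None] - a[None, :])
    for i in range(N - 1):
        sa, sb = starts[i], starts[i + 1]
        # weak injection junctions next to the contacted terminal nucleotides
        w = spec.contact_coupling_scale if i in (0, N - 2) else 1.0
        H[sa : sa + n_orb, sb : sb + n_orb] = w * C
        H[sb : sb + n_orb, sa : sa + n_orb] = w * C.T
    for i in range(N - 1):
        sa, sb = starts[N + i], starts[N + i + 1]
        H[sa, sb] = H[sb, sa] = spec.partner_coupling
    for i in range(N):
        sa, sb = starts[i], starts[N + i]
        H[sa, sb] = H[sb, sa] = spec.pair_coupling
    shift = spec.homo_energy - np.linalg.eigvalsh(H)[-1]
    H[np.arange(n_tot), np.arange(n_tot)] += shift
    return BlockHamiltonian(
        H=H,
        U=np.eye(n_tot),
        blocks=[(int(starts[i]), int(starts[i + 1])) for i in range(2 * N)],
        contact_sites=(0, N - 1),
        basepair_groups=[(i, N + i) for i in range(N)],
    )


def surrogate_pair(
    seed: int = 0, n_basepairs: int = 7, contrast: float = 1.0
) -> tuple[SurrogateSpec, SurrogateSpec]:
    """Specs for the (logic 0, logic 1) species pair.

    ``contrast > 1`` widens the conductance gap by weakening the logic-0
    species' deep hoppings further.
    """
    s1 = SurrogateSpec(species="CT1C", n_basepairs=n_basepairs, seed=seed)
    s0 = SurrogateSpec(
        species="TC1T",
        n_basepairs=n_basepairs,
        deep_scale=SPECIES_DEFAULTS["TC1T"]["deep_scale"] / np.sqrt(contrast),
        seed=seed + 1,
    )
    return s0, s1


DEFAULT_BIAS_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)
DEFAULT_DELTA_GRID = np.round(np.arange(0.0, 0.2501, 0.025), 10)


def surrogate_iv_tables(
    spec0: SurrogateSpec | None = None,
    spec1: SurrogateSpec | None = None,
    bias_grid: np.ndarray | None = None,
    delta_grid: np.ndarray | None = None,
    params: TransportParams | None = None,
    check_contract: bool = True,
) -> tuple[IVTable, IVTable]:
    """Run the transport engine on the surrogate pair -> (iv0, iv1).

    The left Fermi level is anchored at each species' HOMO energy; the
    delta axis shifts it into the gap.  The tables are checked against the
    fixture contract (MΩ-scale resistance, species contrast, monotone
    decay in delta) unless ``check_contract`` is disabled.
    """
    if spec0 is None or spec1 is None:
        d0, d1 = surrogate_pair()
        spec0 = spec0 or d0
        spec1 = spec1 or d1
    bias_grid = DEFAULT_BIAS_GRID if bias_grid is None else np.asarray(bias_grid)
    delta_grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid)
    if 0.0 not in bias_grid or 0.0 not in delta_grid:
        raise ValueError("grids must include V = 0 and delta = 0")
    params = params or TransportParams()
    tables = []
    for spec in (spec0, spec1):
        hb = surrogate_hamiltonian(spec)
        tables.append(
            iv_sweep(
                hb,
                params,
                bias_grid,
                delta_grid,
                e_f_anchor=spec.homo_energy,
                species=spec.species,
            )
        )
    iv0, iv1 = tables
    if check_contract:
        _check_contract(iv0, iv1)
    return iv0, iv1


def _check_contract(iv0: IVTable, iv1: IVTable) -> None:
    """Fixture contract: resistance scale, species contrast, delta decay.

    The low-bias resistance is the secant at the smallest positive grid
    bias; its MΩ-GΩ bound is stated for the default 0.05 V resolution, so
    the check is skipped for coarser user grids (the strongly nonlinear
    logic-0 species looks more resistive through a coarse first step).
    """
    for iv in (iv0, iv1):
        first_bias = iv.bias_grid[iv.bias_grid > 0]
        if first_bias.size and first_bias[0] <= 0.0500001:
            r = iv.zero_bias_resistance()
            if not (1e6 <= r <= 1e9):
                raise FixtureContractError(
                    f"{iv.species}: low-bias resistance {r:.3e} ohm outside "
                    "[1 MOhm, 1 GOhm]"
                )
        if not np.all(np.diff(iv.current[-1, :]) < 0):
            raise FixtureContractError(
                f"{iv.species}: current not strictly decreasing in delta at "
                f"{iv.bias_grid[-1]:.2f} V"
            )
        if not np.all(np.diff(iv.current[:, 0]) > 0):
            raise FixtureContractError(
                f"{iv.species}: current not strictly increasing in bias at delta = 0"
            )
    vmax = float(iv1.bias_grid[-1])
    ratio = float(iv1.interpolate(vmax, 0.0) / iv0.interpolate(vmax, 0.0))
    if ratio <= 5.0:
        raise FixtureContractError(
            f"species contrast I1/I0 = {ratio:.2f} at {vmax:.2f} V (need > 5)"
        )


_TABLE_CACHE: dict = {}


def default_iv_tables(seed: int = 0) -> tuple[IVTable, IVTable]:
    """Default-condition surrogate tables, memoized per seed."""
    if seed not in _TABLE_CACHE:
        _TABLE_CACHE[seed] = surrogate_iv_tables(*surrogate_pair(seed=seed))
    return _TABLE_CACHE[seed]


def random_bits(m: int, n: int, p_one: float = 0.5, rng=None) -> np.ndarray:
    """Seeded Bernoulli bit matrix with ``P(bit = 1) = p_one``."""
    if not (0.0 <= p_one <= 1.0):
        raise ValueError("p_one must be in [0, 1]")
    rng = np.random.default_rng(rng)
    return (rng.random((m, n)) < p_one).astype(np.int8)


def synthetic_images(
    count: int,
    size: int = 128,
    bitload_range: tuple[float, float] = (40.0, 80.0),
    bitload_mean: float = 60.0,
    bitload_sd: float = 8.0,
    smoothness: float = 8.0,
    rng=None,
) -> list[np.ndarray]:
    """Grayscale test images with controlled bit loads.

    Each image is a Gaussian-smoothed random field, rank-normalized and
    grey-warped so that thresholding at mid-grey (0.5) leaves exactly the
    target fraction of pixels above threshold.  Target bit loads are drawn
    from a normal distribution (default mean 60%, sd 8%) clipped to
    ``bitload_range``, concentrating the benchmark in the critical 50-70%
    regime while spanning the stated range.  Pixel values are floats in
    [0, 1].
    """
    rng = np.random.default_rng(rng)
    lo, hi = bitload_range
    images = []
    for _ in range(count):
        target = float(np.clip(rng.normal(bitload_mean, bitload_sd), lo, hi))
        field = scipy.ndimage.gaussian_filter(
            rng.standard_normal((size, size)), smoothness, mode="wrap"
        )
        order = np.argsort(field, axis=None)
        ranks = np.empty(field.size)
        ranks[order] = (np.arange(field.size) + 0.5) / field.size
        ranks = ranks.reshape(field.shape)
        # piecewise-linear grey warp: quantile (1 - target) maps to 0.5
        q = 1.0 - target / 100.0
        img = np.where(
            ranks <= q, 0.5 * ranks / q, 0.5 + 0.5 * (ranks - q) / (1.0 - q)
        )
        images.append(img)
    return images
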