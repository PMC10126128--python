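"""Monte Carlo study of read accuracy under Fermi-energy variability.

Contact formation partially charges a single-molecule junction and shifts
its orbitals against the (fixed) contact Fermi level; across an array this
appears as a per-cell random deviation of the Fermi energy from the HOMO
anchor.  Each simulation draws a random bit pattern (equiprobable 0/1 by
default), draws Fermi offsets uniformly on ``[0, delta_max]`` (one per cell,
or one per simulation), reads the whole array through the crossbar solver,
places the read threshold optimally from the two current classes, and
records the bit error rate, mean cell voltage and power.  The run is fully
reproducible: a master seed spawns one independent substream per simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crossbar import CrossbarSpec, readout_map
from .fixtures import random_bits
from .transport import IVTable

__all__ = [
    "MonteCarloConfig",
    "BERReport",
    "sample_fermi_offsets",
    "optimal_threshold",
    "run_monte_carlo",
]


@dataclass
class MonteCarloConfig:
    """Settings of one variability study.

    ``sampling_mode="per_cell"`` draws an independent offset for every
    memory cell (each cell is its own single-molecule junction);
    ``"per_simulation"`` draws one offset for the whole array.
    """

    n_sims: int = 1000
    delta_max: float = 0.1
    r_int: float = 1e5
    m: int = 64
    n: int = 64
    v_in: float = 1.0
    seed: int = 0
    sampling_mode: str = "per_cell"
    p_one: float = 0.5
    solver: str = "kirchhoff"
    tol: float = 1e-6

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.delta_max < 0:
            raise ValueError("delta_max must be >= 0")
        if self.sampling_mode not in ("per_cell", "per_simulation"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")


@dataclass
class BERReport:
    """Aggregated outcome of a Monte Carlo run."""

    ber: np.ndarray            # (n_sims,) bit error rate per simulation (%)
    threshold: np.ndarray      # (n_sims,) optimal read threshold (A)
    mean_voltage: np.ndarray   # (n_sims,) mean converged cell voltage (V)
    power: np.ndarray          # (n_sims,) mean read power (W)
    class0: np.ndarray         # pooled logic-0 read currents (A)
    class1: np.ndarray         # pooled logic-1 read currents (A)
    failures: int = 0          # simulations aborted by solver errors
    config: MonteCarloConfig | None = None

    @property
    def mean_ber(self) -> float:
        return float(np.mean(self.ber))

    @property
    def max_ber(self) -> float:
        return float(np.max(self.ber))

    def summary(self) -> dict:
        return {
            "n_sims": int(self.ber.size),
            "mean_ber_pct": self.mean_ber,
            "max_ber_pct": self.max_ber,
            "mean_threshold_A": float(np.mean(self.threshold)),
            "mean_voltage_V": float(np.mean(self.mean_voltage)),
            "mean_power_W": float(np.mean(self.power)),
            "failures": self.failures,
        }


def sample_fermi_offsets(config: MonteCarloConfig, rng) -> np.ndarray:
    """Uniform Fermi offsets on ``[0, delta_max]`` for one simulation.

    Returns an ``(m, n)`` matrix; in ``per_simulation`` mode all entries
    share a single draw.
    """
    rng = np.random.default_rng(rng)
    if config.sampling_mode == "per_cell":
        return rng.uniform(0.0, config.delta_max, (config.m, config.n))
    return np.full((config.m, config.n), rng.uniform(0.0, config.delta_max))


def optimal_threshold(class0: np.ndarray, class1: np.ndarray):
    """Threshold minimizing misclassifications, and the resulting BER (%).

    A cell reads logic 1 when its current exceeds the threshold.  All
    midpoints of the pooled sorted currents (plus guards outside the range)
    are scanned; ties break toward the lower threshold.  Returns
    ``(threshold_A, ber_percent)``.
    """
    c0 = np.asarray(class0, float).ravel()
    c1 = np.asarray(class1, float).ravel()
    if c0.size == 0 or c1.size == 0:
        raise ValueError("both classes must be non-empty")
    pooled = np.sort(np.concatenate([c0, c1]))
    mids = 0.5 * (pooled[:-1] + pooled[1:])
    span = max(pooled[-1] - pooled[0], abs(pooled[0]), 1.0)
    cands = np.concatenate(
        [[pooled[0] - 1e-3 * span], mids, [pooled[-1] + 1e-3 * span]]
    )
    # errors(t) = #(class0 > t) + #(class1 <= t)
    n0_above = c0.size - np.searchsorted(np.sort(c0), cands, side="right")
    n1_below = np.searchsorted(np.sort(c1), cands, side="right")
    errors = n0_above + n1_below
    best = int(np.argmin(errors))  # argmin takes the first (lowest) on ties
    ber = 100.0 * errors[best] / (c0.size + c1.size)
    return float(cands[best]), float(ber)


def run_monte_carlo(
    config: MonteCarloConfig, iv0: IVTable, iv1: IVTable
) -> BERReport:
    """Run the full variability study.

    Per simulation: draw bits and Fermi offsets, solve the row-by-row
    read-out, threshold the measured current map, and record BER, mean cell
    voltage and mean read power.  Solver failures abort that simulation and
    are counted.  Identical configs (including seed) give bit-identical
    reports.
    """
    if iv0.delta_grid[-1] < config.delta_max or iv1.delta_grid[-1] < config.delta_max:
        raise ValueError("I-V tables do not bracket delta_max")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_sims)
    ber = []
    threshold = []
    mean_voltage = []
    power = []
    class0_all = []
    class1_all = []
    failures = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        bits = random_bits(config.m, config.n, config.p_one, rng)
        delta = sample_fermi_offsets(config, rng)
        spec = CrossbarSpec(
            bits=bits,
            iv0=iv0,
            iv1=iv1,
            r_int=config.r_int,
            v_in=config.v_in,
            delta=delta,
        )
        try:
            rm = readout_map(spec, solver=config.solver, tol=config.tol)
        except RuntimeError:
            failures += 1
            continue
        c0 = rm.I_out[bits == 0]
        c1 = rm.I_out[bits == 1]
        t, b = optimal_threshold(c0, c1)
        ber.append(b)
        threshold.append(t)
        mean_voltage.append(float(rm.V_read.mean()))
        power.append(rm.mean_power)
        class0_all.append(c0)
        class1_all.append(c1)
    if not ber:
        raise RuntimeError("every simulation failed")
    return BERReport(
        ber=np.asarray(ber),
        threshold=np.asarray(threshold),
        mean_voltage=np.asarray(mean_voltage),
        power=np.asarray(power),
        class0=np.concatenate(class0_all),
        class1=np.concatenate(class1_all),
        failures=failures,
        config=config,
    )
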