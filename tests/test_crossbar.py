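"""Kirchhoff oracle, sneak-parameter calibration and the parametric model."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from dnarom.crossbar import (
    CrossbarSpec,
    LinearCells,
    SEED_VOLTAGE,
    estimate_sneak_parameters,
    iterate_parametric,
    readout_map,
    solve_kirchhoff,
    voltage_distribution,
)
from conftest import linear_iv_table


def netlist_solution(m, n, g, G, driven, v_in):
    """Independent dense/sparse netlist oracle (scipy SuperLU)."""
    mn = m * n
    iw = np.arange(mn).reshape(m, n)
    ib = iw + mn
    rows, cols, vals = [], [], []
    diag = np.zeros(2 * mn)

    def add(a, b, v):
        rows.extend(np.ravel(a))
        cols.extend(np.ravel(b))
        vals.extend(np.broadcast_to(v, np.shape(a)).ravel())

    a, b = iw[:, :-1], iw[:, 1:]
    add(a, b, -g)
    add(b, a, -g)
    np.add.at(diag, a.ravel(), g)
    np.add.at(diag, b.ravel(), g)
    diag[iw[driven, 0]] += g  # lead
    a, b = ib[:-1, :], ib[1:, :]
    add(a, b, -g)
    add(b, a, -g)
    np.add.at(diag, a.ravel(), g)
    np.add.at(diag, b.ravel(), g)
    diag[ib[-1, :]] += g  # grounding segments
    add(iw, ib, -G)
    add(ib, iw, -G)
    np.add.at(diag, iw.ravel(), G.ravel())
    np.add.at(diag, ib.ravel(), G.ravel())
    k = np.arange(2 * mn)
    rows.extend(k)
    cols.extend(k)
    vals.extend(diag)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(2 * mn, 2 * mn))
    rhs = np.zeros(2 * mn)
    rhs[iw[driven, 0]] = g * v_in
    x = spla.spsolve(A, rhs)
    return x[:mn].reshape(m, n), x[mn:].reshape(m, n)


def linear_spec(G, r_int, v_in=1.0):
    iv = linear_iv_table(1.0)  # placeholder tables; cells passed explicitly
    spec = CrossbarSpec(
        bits=np.zeros(G.shape, dtype=int), iv0=iv, iv1=iv, r_int=r_int, v_in=v_in
    )
    return spec, LinearCells(G)


class TestKirchhoff:
    def test_single_cell_hand_formula(self):
        """1x1 array: one wordline + one bitline segment in series with the cell."""
        r_cell, r_int = 1e6, 2e4
        spec, cells = linear_spec(np.array([[1.0 / r_cell]]), r_int)
        st = solve_kirchhoff(spec, 0, cells=cells)
        assert st.V[0, 0] == pytest.approx(r_cell / (r_cell + 2 * r_int), rel=1e-12)
        assert st.i_bitline[0] == pytest.approx(st.V[0, 0] / r_cell, rel=1e-10)

    def test_vanishing_interconnect_gives_full_bias(self):
        """R_int -> 0: every driven cell sees the full read bias."""
        spec, cells = linear_spec(np.full((3, 4), 1e-6), 1e-3)
        rm = readout_map(spec, cells=cells)
        np.testing.assert_allclose(rm.V_read, 1.0, atol=1e-6)

    @pytest.mark.parametrize("shape,driven", [((2, 2), 0), ((5, 7), 2)])
    def test_matches_netlist_oracle(self, shape, driven, rng):
        G = rng.uniform(2e-9, 5e-8, shape)
        spec, cells = linear_spec(G, 1e5)
        st = solve_kirchhoff(spec, driven, cells=cells)
        Vw_o, Vb_o = netlist_solution(*shape, 1e-5, G, driven, 1.0)
        Vw, Vb = st.node_voltages
        assert np.abs(Vw - Vw_o).max() < 1e-10
        assert np.abs(Vb - Vb_o).max() < 1e-10

    def test_kcl_residual_and_energy_balance(self, iv_tables, rng):
        """Converged solves satisfy KCL to 1e-9 relative and conserve energy."""
        iv0, iv1 = iv_tables
        bits = (rng.random((16, 16)) < 0.5).astype(int)
        for r_int in (1e4, 1e6):
            spec = CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=r_int)
            st = solve_kirchhoff(spec, 3)
            assert st.max_residual <= 1e-9 * spec.v_in / r_int
            source_power = spec.v_in * st.i_source
            assert st.power == pytest.approx(source_power, rel=1e-9)

    def test_nonlinear_cells_match_netlist_oracle_after_convergence(
        self, iv_tables, rng
    ):
        """Linearize at the converged secants: the node voltages must solve
        that linear netlist exactly (dual-route check)."""
        iv0, iv1 = iv_tables
        bits = (rng.random((6, 5)) < 0.5).astype(int)
        spec = CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=1e5)
        st = solve_kirchhoff(spec, 0)
        G = spec.cells().secant_conductance(st.V)
        Vw_o, Vb_o = netlist_solution(6, 5, 1e-5, G, 0, 1.0)
        Vw, Vb = st.node_voltages
        assert np.abs(Vw - Vw_o).max() < 1e-8
        assert np.abs(Vb - Vb_o).max() < 1e-8

    def test_linear_cells_converge_fast(self):
        """Linear cells: one exact solve plus brief residual polish."""
        spec, cells = linear_spec(np.full((4, 4), 1e-8), 1e4)
        st = solve_kirchhoff(spec, 0, cells=cells)
        assert st.iterations <= 4
        Vw_o, Vb_o = netlist_solution(4, 4, 1e-4, cells.G, 0, 1.0)
        assert np.abs(st.node_voltages[0] - Vw_o).max() < 1e-10

    def test_driven_row_out_of_range(self):
        spec, cells = linear_spec(np.full((2, 2), 1e-8), 1e4)
        with pytest.raises(ValueError):
            solve_kirchhoff(spec, 5, cells=cells)


class TestSneakParameters:
    def test_ideal_interconnect_gives_unity_factors(self):
        sp_ = estimate_sneak_parameters(4, 4, 1e-3, 1e-6)
        np.testing.assert_allclose(sp_.alpha, 1.0, atol=1e-6)
        np.testing.assert_allclose(sp_.beta, 1.0, atol=1e-6)

    def test_bias_independence(self):
        a = estimate_sneak_parameters(8, 8, 1e5, 2e-8, v_in=1.0)
        b = estimate_sneak_parameters(8, 8, 1e5, 2e-8, v_in=0.5)
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-9)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-9)

    def test_shapes_and_bounds(self):
        """alpha in (0,1], degrading away from the grounded edge; beta > 0."""
        sp_ = estimate_sneak_parameters(16, 16, 1e6, 2e-8)
        assert np.all((sp_.alpha > 0) & (sp_.alpha <= 1))
        assert np.all(np.diff(sp_.alpha) >= 0)  # rows near ground degrade least
        assert np.all(sp_.beta > 0)


class TestVoltageDistribution:
    def test_open_cells_give_alpha_scaled_bias(self):
        v = voltage_distribution(np.zeros(5), 1e-4, 0.8, 1.0)
        np.testing.assert_allclose(v, 0.8, atol=1e-15)

    def test_literal_variant_collapses(self, rng):
        """As printed, the denominator's inner sums empty out for k <= j and
        the fraction cancels to one for every column."""
        G = rng.uniform(1e-9, 1e-7, 6)
        v = voltage_distribution(G, 1e-5, 0.9, 1.0, variant="literal")
        np.testing.assert_allclose(v, 0.9, atol=1e-15)

    def test_full_variant_last_column_reduction(self, rng):
        """At j = n the numerator is empty (=1): V = V_in alpha / denominator."""
        G = rng.uniform(1e-9, 1e-7, 4)
        r = 1.0 / 1e-5
        v = voltage_distribution(G, 1e-5, 1.0, 1.0, variant="full")
        denom = 1.0 + sum(G[k] * (k + 1) * r for k in range(4))
        assert v[-1] == pytest.approx(1.0 / denom, rel=1e-12)

    def test_monotone_degradation_along_wordline(self):
        v = voltage_distribution(np.full(16, 2e-8), 1e-5, 1.0, 1.0, variant="full")
        assert np.all(np.diff(v) < 0)


class TestParametric:
    def test_linear_cells_converge_in_two_iterations(self, rng):
        iv = linear_iv_table(5e7)
        bits = np.zeros((4, 4), dtype=int)
        spec = CrossbarSpec(bits=bits, iv0=iv, iv1=iv, r_int=1e4)
        sneak = estimate_sneak_parameters(4, 4, 1e4, 2e-8)
        st = iterate_parametric(spec, 0, sneak)
        assert st.iterations <= 2

    def test_seed_robust_fixed_point(self, iv_tables, rng):
        """The converged read is independent of the seed voltage."""
        iv0, iv1 = iv_tables
        bits = (rng.random((16, 16)) < 0.5).astype(int)
        spec = CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=1e5)
        sneak = estimate_sneak_parameters(16, 16, 1e5, 2e-8)
        st_a = iterate_parametric(spec, 2, sneak)
        import dnarom.crossbar as cb

        old = cb.SEED_VOLTAGE
        try:
            cb.SEED_VOLTAGE = 0.01
            st_b = iterate_parametric(spec, 2, sneak)
        finally:
            cb.SEED_VOLTAGE = old
        assert np.abs(st_a.V[2] - st_b.V[2]).max() < 1e-6

    def test_agrees_with_kirchhoff_oracle_moderate_interconnect(self, iv_tables):
        """Calibrated alpha/beta track the exact solve within 5% RMS."""
        iv0, iv1 = iv_tables
        bits = np.ones((16, 16), dtype=int)
        spec = CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=1e4)
        g_avg = float(iv1.interpolate(SEED_VOLTAGE, 0.0) / SEED_VOLTAGE)
        sneak = estimate_sneak_parameters(16, 16, 1e4, g_avg)
        rk = readout_map(spec, solver="kirchhoff")
        rp = readout_map(spec, solver="parametric", sneak=sneak)
        rms = np.sqrt(np.mean(((rp.I_out - rk.I_out) / rk.I_out) ** 2))
        assert rms < 0.05

    def test_worst_distortion_at_far_corner(self, iv_tables):
        """Parametric read map: weakest current at the first row's last
        column (the far corner), as the alpha/beta picture predicts."""
        iv0, iv1 = iv_tables
        bits = np.ones((16, 16), dtype=int)
        spec = CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=1e6)
        rp = readout_map(spec, solver="parametric")
        assert np.unravel_index(np.argmin(rp.I_out), rp.I_out.shape) == (0, 15)
        # the exact solve also puts the weakest read in the far column
        rk = readout_map(spec, solver="kirchhoff")
        assert np.argmin(rk.I_out) % 16 == 15


class TestReadoutAndPower:
    def test_single_cell_readout_current(self):
        r_cell = 1e6
        iv = linear_iv_table(r_cell)
        spec = CrossbarSpec(
            bits=np.zeros((1, 1), dtype=int), iv0=iv, iv1=iv, r_int=1e3
        )
        rm = readout_map(spec)
        v = r_cell / (r_cell + 2e3)
        assert rm.I_out[0, 0] == pytest.approx(v / r_cell, rel=1e-9)

    def test_single_cell_power_ideal_interconnect(self):
        r_cell = 1e6
        iv = linear_iv_table(r_cell)
        spec = CrossbarSpec(
            bits=np.zeros((1, 1), dtype=int), iv0=iv, iv1=iv, r_int=1e-3
        )
        from dnarom.crossbar import array_power

        assert array_power(spec) == pytest.approx(1.0 / r_cell, rel=1e-6)

    def test_power_decreases_with_interconnect_resistance(self, iv_tables, rng):
        from dnarom.crossbar import array_power

        iv0, iv1 = iv_tables
        bits = (rng.random((12, 12)) < 0.5).astype(int)
        powers = [
            array_power(CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=r))
            for r in (1e4, 1e5, 1e6)
        ]
        assert powers[0] > powers[1] > powers[2]

    def test_homogeneous_voltage_degrades_toward_far_column(self, iv_tables):
        iv0, iv1 = iv_tables
        bits = np.ones((12, 12), dtype=int)
        spec = CrossbarSpec(bits=bits, iv0=iv0, iv1=iv1, r_int=1e5)
        st = solve_kirchhoff(spec, 0)
        assert np.all(np.diff(st.V[0]) < 0)
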