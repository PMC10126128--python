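"""Green's functions, probe elimination, Landauer currents and peaks."""

import numpy as np
import pytest

from dnarom.basis import BlockHamiltonian, apply_bias_ramp
from dnarom.fixtures import SurrogateSpec, surrogate_hamiltonian
from dnarom.transport import (
    CONDUCTANCE_QUANTUM,
    TransportParams,
    build_self_energies,
    effective_transmission,
    find_transmission_peaks,
    iv_sweep,
    probe_balance_residual,
    retarded_green,
    terminal_current,
    terminal_currents_lr,
    transmission_matrix,
    transmission_spectrum,
)


def chain_hamiltonian(onsites, hoppings, contacts=None):
    """Single-orbital-per-site chain as a BlockHamiltonian."""
    n = len(onsites)
    H = np.diag(np.asarray(onsites, float))
    for i, t in enumerate(hoppings):
        H[i, i + 1] = H[i + 1, i] = t
    if contacts is None:
        contacts = (0, n - 1)
    pairs = [(i, i) for i in range(n)]  # placeholder; ramp not used in these tests
    return BlockHamiltonian(
        H=H,
        U=np.eye(n),
        blocks=[(i, i + 1) for i in range(n)],
        contact_sites=contacts,
        basepair_groups=[],
    )


@pytest.fixture(scope="module")
def fixture_hb():
    return surrogate_hamiltonian(SurrogateSpec(seed=0))


class TestGreensFunction:
    def test_single_site_closed_form(self):
        eps, gamma = -0.3, 0.5
        hb = chain_hamiltonian([eps], [], contacts=(0, 0))
        se = build_self_energies(hb, gamma_contact=gamma, gamma_probe=0.0)
        # both contacts on the same site: total broadening 2*gamma
        for E in (-1.0, -0.3, 0.2):
            got = retarded_green(E, hb, se)[0, 0]
            want = 1.0 / (E - eps + 1j * gamma)
            assert got == pytest.approx(want, rel=1e-12)

    def test_closed_system_real_resolvent(self):
        hb = chain_hamiltonian([0.0, 0.2], [0.1])
        se = build_self_energies(hb, gamma_contact=0.0, gamma_probe=0.0)
        E = 5.0
        G = retarded_green(E, hb, se)
        want = np.linalg.inv(E * np.eye(2) - hb.H)
        np.testing.assert_allclose(G.real, want, atol=1e-12)
        assert np.abs(G.imag).max() < 1e-12

    def test_resolvent_identity(self, fixture_hb):
        """G^r - G^a = G^r (Sigma - Sigma^dag) G^a for the open system."""
        se = build_self_energies(fixture_hb)
        G = retarded_green(-5.1, fixture_hb, se)
        Ga = G.conj().T
        sigma_diff = -1j * np.diag(se.total_gamma)  # Sigma - Sigma^dag
        lhs = G - Ga
        rhs = G @ sigma_diff @ Ga
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestTransmission:
    def test_symmetric_single_site_resonance_is_unity(self):
        hb = chain_hamiltonian([-0.2], [], contacts=(0, 0))
        se = build_self_energies(hb, gamma_contact=0.3, gamma_probe=0.0)
        T = transmission_matrix(retarded_green(-0.2, hb, se), se)
        assert T[0, -1] == pytest.approx(1.0, abs=1e-12)

    def test_two_site_chain_matches_hand_formula(self):
        """Independent oracle: explicit 2x2 inversion done by hand algebra."""
        eps1, eps2, t, gL, gR = 0.1, -0.2, 0.15, 0.8, 0.5
        hb = chain_hamiltonian([eps1, eps2], [t])
        se = build_self_energies(hb, gamma_contact=None or 0.0, gamma_probe=0.0)
        se.coupling[0, 0] = gL
        se.coupling[-1, 1] = gR
        for E in (-0.5, 0.0, 0.3):
            a = E - eps1 + 0.5j * gL
            b = E - eps2 + 0.5j * gR
            g12 = t / (a * b - t * t)  # hand-inverted 2x2 resolvent
            want = gL * gR * abs(g12) ** 2
            T = transmission_matrix(retarded_green(E, hb, se), se)
            assert T[0, -1] == pytest.approx(want, rel=1e-12)

    def test_reciprocity_and_positivity(self, fixture_hb):
        se = build_self_energies(fixture_hb)
        E = np.linspace(-5.5, -4.9, 11)
        T = transmission_matrix(retarded_green(E, fixture_hb, se), se)
        np.testing.assert_allclose(T, np.swapaxes(T, 1, 2), atol=1e-9)
        assert T.min() >= -1e-12


class TestEffectiveTransmission:
    def test_no_probes_reduces_to_coherent(self):
        hb = chain_hamiltonian([0.0, 0.1, 0.0], [0.2, 0.2])
        se = build_self_energies(hb, gamma_probe=0.0)
        res = transmission_spectrum(hb, se, np.linspace(-0.5, 0.5, 21))
        np.testing.assert_array_equal(res.T_eff, res.T_LR)

    def test_single_probe_algebraic_oracle(self):
        """One probe: eliminating it gives T_LR + T_LP T_PR / (T_PL + T_PR)."""
        hb = chain_hamiltonian([0.0, 0.05, -0.05], [0.2, 0.25])
        se = build_self_energies(hb, gamma_contact=0.6, gamma_probe=0.08)
        assert se.n_probes == 1
        E = np.array([0.12])
        T = transmission_matrix(retarded_green(E, hb, se), se)
        t_eff = effective_transmission(T)[0]
        T = T[0]
        want = T[0, 2] + T[0, 1] * T[1, 2] / (T[1, 0] + T[1, 2])
        assert t_eff == pytest.approx(want, rel=1e-12)
        assert t_eff >= T[0, 2] - 1e-12

    def test_coherent_limit_on_duplex_fixture(self, fixture_hb):
        """Gamma_k -> 0 drives T_eff to T_LR across the HOMO window.

        The deviation is linear in Gamma_k (the narrow HOMO resonance and
        its antiresonances are the most decoherence-sensitive points); by
        Gamma_k = 1e-11 eV it is everywhere below 1e-3.
        """
        E = np.linspace(-5.45, -4.95, 201)
        devs = []
        for gk in (1e-9, 1e-11):
            se = build_self_energies(fixture_hb, gamma_probe=gk)
            res = transmission_spectrum(fixture_hb, se, E)
            devs.append(np.max(np.abs(res.T_eff - res.T_LR) / res.T_LR))
        assert devs[1] < 1e-3
        assert devs[1] < 0.05 * devs[0]  # ~linear vanishing with Gamma_k


class TestTerminalCurrent:
    def test_zero_bias_zero_current(self, fixture_hb):
        params = TransportParams(e_f_left=-5.2, v_bias=0.0)
        assert terminal_current(fixture_hb, params) == 0.0

    def test_lorentzian_matches_arctan_integral(self):
        """Single site, wide-band: I = (2e^2/h) Gamma [arctan] at kT -> 0."""
        eps, gamma, v = 0.0, 0.4, 0.5
        hb = chain_hamiltonian([eps], [], contacts=(0, 0))
        params = TransportParams(
            gamma_contact=gamma,
            gamma_probe=0.0,
            kT=2e-4,
            e_f_left=-0.2,
            v_bias=v,
            energy_step=4e-5,
        )
        got = terminal_current(hb, params)
        # T(E) = gamma^2 / ((E-eps)^2 + gamma^2); integral = gamma*arctan(...)
        lo, hi = params.e_f_left, params.e_f_right
        integral = gamma * (np.arctan((hi - eps) / gamma) - np.arctan((lo - eps) / gamma))
        want = CONDUCTANCE_QUANTUM * integral
        assert got == pytest.approx(want, rel=1e-3)

    def test_grid_refinement_converged(self, fixture_hb):
        ramped = apply_bias_ramp(fixture_hb, 1.0)
        base = TransportParams(e_f_left=-5.2, v_bias=1.0, energy_step=1e-3)
        fine = TransportParams(e_f_left=-5.2, v_bias=1.0, energy_step=5e-4)
        i1 = terminal_current(ramped, base)
        i2 = terminal_current(ramped, fine)
        assert abs(i1 - i2) / abs(i2) < 1e-4

    def test_probe_currents_vanish_after_elimination(self, fixture_hb):
        ramped = apply_bias_ramp(fixture_hb, 0.6)
        params = TransportParams(e_f_left=-5.2, v_bias=0.6)
        assert probe_balance_residual(ramped, params) < 1e-9

    def test_terminal_current_conservation(self, fixture_hb):
        ramped = apply_bias_ramp(fixture_hb, 0.8)
        params = TransportParams(e_f_left=-5.2, v_bias=0.8)
        i_l, i_r = terminal_currents_lr(ramped, params)
        assert i_l > 0
        assert abs(i_l + i_r) < 1e-9 * abs(i_l)
        # and the eliminated-probe route gives the same current
        assert terminal_current(ramped, params) == pytest.approx(i_l, rel=1e-9)


class TestIVSweep:
    def test_zero_bias_row_is_zero_and_delta_decay(self, iv_tables):
        for iv in iv_tables:
            np.testing.assert_array_equal(iv.current[0], 0.0)
            assert np.all(np.diff(iv.current[-1, :]) < 0)

    def test_megaohm_resistance_scale(self, iv_tables):
        for iv in iv_tables:
            assert 1e6 <= iv.zero_bias_resistance() <= 1e9

    def test_monotone_in_bias(self, iv_tables):
        for iv in iv_tables:
            assert np.all(np.diff(iv.current[:, 0]) > 0)

    def test_interpolation_matches_scipy_oracle(self, iv_tables, rng):
        from scipy.interpolate import RegularGridInterpolator

        iv = iv_tables[1]
        oracle = RegularGridInterpolator(
            (iv.bias_grid, iv.delta_grid), iv.current
        )
        v = rng.uniform(0, 1, 50)
        d = rng.uniform(0, 0.25, 50)
        np.testing.assert_allclose(
            iv.interpolate(v, d), oracle(np.column_stack([v, d])), rtol=1e-12
        )

    def test_interpolation_rejects_out_of_range(self, iv_tables):
        with pytest.raises(ValueError):
            iv_tables[0].interpolate(1.5, 0.0)


class TestPeaks:
    def test_single_lorentzian(self):
        E = np.linspace(-1, 1, 2001)
        t = 1.0 / ((E - 0.2) ** 2 + 0.01)
        peaks = find_transmission_peaks(E, t)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(0.2, abs=1e-3)

    def test_double_lorentzian_centers_recovered(self):
        E = np.linspace(-1, 1, 4001)
        t = 0.02 / ((E + 0.4) ** 2 + 0.004) + 0.01 / ((E - 0.3) ** 2 + 0.0025)
        peaks = find_transmission_peaks(E, t)
        assert len(peaks) == 2
        np.testing.assert_allclose(peaks, [-0.4, 0.3], atol=2e-3)

    def test_flat_signal_gives_no_peaks(self):
        assert find_transmission_peaks(np.linspace(0, 1, 10), np.zeros(10)).size == 0

    def test_bias_shifts_homo_peak(self, fixture_hb):
        """Positive bias shifts the HOMO peak up in energy, negative down."""
        E = np.linspace(-6.3, -3.9, 2401)

        def top_peak(v):
            hb = apply_bias_ramp(fixture_hb, v) if v else fixture_hb
            se = build_self_energies(hb)
            res = transmission_spectrum(hb, se, E)
            return find_transmission_peaks(E, res.T_eff, 0.05)[-1]

        p0 = top_peak(0.0)
        assert top_peak(1.0) > p0 + 0.1
        assert top_peak(-1.0) < p0 - 0.1
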