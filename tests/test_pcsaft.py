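"""PC-SAFT core: density roots, Helmholtz contributions, association,
fugacity/activity coefficients, and independent numerical oracles."""

import math

import numpy as np
import pytest

from asdphase.pcsaft import KB, ETA_MAX, HelmholtzBreakdown, MixtureState, PcSaft

T = 310.15
P = 1.013e5


def x_of(model, **kw):
    x = np.zeros(len(model.names))
    for name, v in kw.items():
        x[model.names.index(name)] = v
    return x / x.sum()


class TestDensity:
    def test_water_liquid_density_near_reference(self, model):
        rho = model.mass_density(T, P, x_of(model, water=1.0))
        assert rho == pytest.approx(1000.0, rel=0.05)

    def test_pressure_consistency_at_solved_root(self, model):
        x = x_of(model, ritonavir=0.1, PVPVA64=0.01, water=0.89)
        res = model.solve_density(T, P, x)
        ws = model.workspace(T, x)
        assert ws.pressure(res.eta) == pytest.approx(P, rel=1e-6)

    def test_vapor_root_below_liquid_root(self, model):
        x = x_of(model, water=1.0)
        liq = model.solve_density(T, P, x, branch="liquid")
        vap = model.solve_density(T, P, x, branch="vapor")
        assert vap.eta < liq.eta
        assert vap.n_roots >= 2

    def test_warm_start_reproduces_cold_solution(self, model):
        x = x_of(model, ritonavir=0.13, PVPVA64=0.002, water=0.868)
        cold = model.solve_density(T, P, x)
        warm = model.solve_density(T, P, x, eta_guess=cold.eta + 0.01)
        assert warm.eta == pytest.approx(cold.eta, abs=1e-12)


class TestHelmholtz:
    def test_breakdown_sums_to_residual(self, model):
        ws = model.workspace(T, x_of(model, water=0.7, ritonavir=0.2, PVPVA64=0.1))
        br = ws.a_res(0.4)
        assert br.a_res == br.a_hc + br.a_disp + br.a_assoc

    def test_water_liquid_residual_is_negative(self, model):
        x = x_of(model, water=1.0)
        res = model.solve_density(T, P, x)
        br = model.residual_helmholtz(MixtureState(T=T, P=P, x=x, eta=res.eta))
        assert br.a_res < 0.0

    def test_ideal_gas_limit(self, model):
        ws = model.workspace(T, x_of(model, water=1.0))
        assert abs(ws.a_res(1e-9).a_res) < 1e-6

    def test_no_association_term_without_sites(self, toy_params):
        m = PcSaft(toy_params)
        ws = m.workspace(T, np.array([0.5, 0.3, 0.2]))
        assert ws.a_res(0.4).a_assoc == 0.0

    def test_unsolved_state_rejected(self, model):
        st = MixtureState(T=T, P=P, x=x_of(model, water=1.0), eta=None)
        with pytest.raises(ValueError):
            model.residual_helmholtz(st)

    def test_packing_bound_enforced(self, model):
        with pytest.raises(ValueError):
            MixtureState(T=T, P=P, x=x_of(model, water=1.0), eta=0.9)


class TestAnalyticCompressibility:
    @pytest.mark.parametrize("eta", [0.1, 0.3, 0.45, 0.6])
    def test_matches_numeric_derivative(self, model, eta):
        ws = model.workspace(T, x_of(model, ritonavir=0.2, PVPVA64=0.05, water=0.75))
        assert ws.Z(eta) == pytest.approx(ws.Z_numeric(eta), abs=5e-6, rel=1e-6)


class TestDispersionOracle:
    def test_single_component_against_textbook_series(self, toy_params):
        # independent re-implementation of the first-order/second-order
        # perturbation integrals with their universal constants
        A = {
            0: (0.9105631445, -0.3084016918, -0.0906148351),
            1: (0.6361281449, 0.1860531159, 0.4527842806),
            2: (2.6861347891, -2.5030047259, 0.5962700728),
            3: (-26.547362491, 21.419793629, -1.7241829131),
            4: (97.759208784, -65.255885330, -4.1302112531),
            5: (-159.59154087, 83.318680481, 13.776631870),
            6: (91.297774084, -33.746922930, -8.6728470368),
        }
        B = {
            0: (0.7240946941, -0.5755498075, 0.0976883116),
            1: (2.2382791861, 0.6995095521, -0.2557574982),
            2: (-4.0025849485, 3.8925673390, -9.1558561530),
            3: (-21.003576815, -17.215471648, 20.642075974),
            4: (26.855641363, 192.67226447, -38.804430052),
            5: (206.55133841, -161.82646165, 93.626774077),
            6: (-355.60235612, -165.20769346, -29.666905585),
        }
        comp = toy_params["A"]
        m = comp.m_seg
        sig = comp.sigma
        u = comp.u_over_kB
        Tt, eta = 300.0, 0.42

        def coeff(tbl, i):
            c0, c1, c2 = tbl[i]
            return c0 + (m - 1) / m * c1 + (m - 1) / m * (m - 2) / m * c2

        I1 = sum(coeff(A, i) * eta**i for i in range(7))
        I2 = sum(coeff(B, i) * eta**i for i in range(7))
        C1 = 1.0 / (
            1.0
            + m * (8 * eta - 2 * eta**2) / (1 - eta) ** 4
            + (1 - m) * (20 * eta - 27 * eta**2 + 12 * eta**3 - 2 * eta**4)
            / ((1 - eta) * (2 - eta)) ** 2
        )
        d = sig * (1 - 0.12 * math.exp(-3 * u / Tt))
        rho = 6.0 * eta / (math.pi * m * d**3)
        expected = (
            -2 * math.pi * rho * I1 * m**2 * (u / Tt) * sig**3
            - math.pi * rho * m * C1 * I2 * m**2 * (u / Tt) ** 2 * sig**3
        )

        mdl = PcSaft(toy_params)
        ws = mdl.workspace(Tt, np.array([1.0, 0.0, 0.0]))
        assert ws.a_disp(ws.rho_of_eta(eta), eta) == pytest.approx(expected, rel=1e-12)


class TestAssociation:
    def test_all_ones_when_cross_energy_zero(self, toy_params):
        m = PcSaft(toy_params)
        st = MixtureState(T=T, P=P, x=np.array([0.4, 0.3, 0.3]), eta=0.4)
        sf = m.solve_site_fractions(st)
        assert np.all(sf.X_donor == 1.0) and np.all(sf.X_acceptor == 1.0)

    def test_pure_water_strongly_bonded(self, model):
        x = x_of(model, water=1.0)
        res = model.solve_density(T, P, x)
        sf = model.solve_site_fractions(MixtureState(T=T, P=P, x=x, eta=res.eta))
        i = model.names.index("water")
        assert sf.X_donor[i] < 0.3  # most sites bonded in liquid water

    def test_dilute_water_in_polymer_cross_associates(self, model):
        x = x_of(model, PVPVA64=0.95, water=0.05)
        res = model.solve_density(T, P, x)
        sf = model.solve_site_fractions(MixtureState(T=T, P=P, x=x, eta=res.eta))
        i = model.names.index("water")
        assert sf.X_donor[i] < 1.0 - 1e-4

    def test_against_brute_force_fixed_point(self, toy_assoc_params):
        # dense undamped substitution, many iterations, as the oracle
        m = PcSaft(toy_assoc_params)
        x = np.array([0.6, 0.4])
        ws = m.workspace(T, x)
        eta = 0.42
        rho = ws.rho_of_eta(eta)
        XD, XA = ws.site_fractions(rho, eta)

        z = ws._zetas(rho)
        delta = ws.delta_pref * ws.g_contact(z[2], z[3])
        A = rho * delta * (x * m.NA)[None, :]
        B = rho * delta * (x * m.ND)[None, :]
        xd = np.ones(2)
        xa = np.ones(2)
        for _ in range(100000):
            xd, xa = 1.0 / (1.0 + A @ xa), 1.0 / (1.0 + B @ xd)
        np.testing.assert_allclose(XD, xd, atol=1e-10)
        np.testing.assert_allclose(XA, xa, atol=1e-10)


class TestFugacityActivity:
    def test_ideal_gas_fugacity_coefficients_vanish(self, model):
        x = x_of(model, water=1.0)
        lnphi = model.lnphi(T, 1.0, x, branch="vapor")  # 1 Pa: essentially ideal
        assert abs(lnphi[model.names.index("water")]) < 1e-5

    def test_euler_consistency_of_derivative_scheme(self, model):
        # sum_i x_i ln phi_i must equal a_res + (Z-1) - ln Z exactly;
        # checks the finite-difference chemical potentials against the
        # closed-form Euler sum (integrated Gibbs-Duhem)
        rng = np.random.default_rng(7)
        for _ in range(4):
            x = rng.dirichlet([2.0, 1.0, 3.0])
            res = model.solve_density(T, P, x)
            ws = model.workspace(T, x)
            lhs = float(x @ model.lnphi(T, P, x))
            rhs = ws.a_res(res.eta).a_res + (res.Z - 1.0) - math.log(res.Z)
            # |ln phi| reaches O(1e3) for the polymer, so the meaningful
            # tolerance is relative
            assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-6)

    def test_activity_coefficients_unity_at_pure_corners(self, model):
        for i in range(len(model.names)):
            x = np.zeros(3)
            x[i] = 1.0
            assert model.gamma(T, P, x)[i] == pytest.approx(1.0, abs=1e-8)

    def test_dilute_drug_in_water_is_hydrophobic(self, model):
        x = x_of(model, ritonavir=1e-4, water=1.0 - 1e-4)
        g = model.gamma(T, P, x)
        assert g[model.names.index("ritonavir")] > 100.0
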