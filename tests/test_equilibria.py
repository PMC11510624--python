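"""Equilibria: SLE closed forms, flash invariants, stability, brute-force
Gibbs oracle on a toy ternary, and the binodal/spinodal geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asdphase.equilibria import (
    R_GAS,
    EquilibriumSolver,
    mass_to_mole,
    mole_to_mass,
)

T = 310.15


class TestComposition:
    @given(
        a=st.floats(min_value=1e-6, max_value=1.0),
        b=st.floats(min_value=1e-6, max_value=1.0),
        c=st.floats(min_value=1e-6, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_mole_conversion_is_a_bijection(self, a, b, c, params):
        M = np.array([params[n].M for n in params.names])
        w = np.array([a, b, c])
        w /= w.sum()
        back = mole_to_mass(mass_to_mole(w, M), M)
        np.testing.assert_allclose(back, w, atol=1e-14)

    def test_invalid_mass_fractions_rejected(self, eq):
        with pytest.raises(ValueError):
            eq.composition_from_mass(np.array([0.5, 0.6, 0.1]))


class TestSLE:
    def test_ideal_limit_matches_closed_form(self, eq, params):
        melt = params["ritonavir"].melting
        x_id = math.exp(
            -melt.dh_SL * 1e3 / (R_GAS * T) * (1 - T / melt.T_SL)
            - melt.dcp_SL / R_GAS * (math.log(melt.T_SL / T) - melt.T_SL / T + 1)
        )
        assert eq.ideal_solubility(T) == pytest.approx(x_id, rel=1e-14)
        # ideal mass fraction in pure water follows by exact conversion
        w = eq.sle_solubility(T, polymer_ratio=0.0, ideal=True)
        Md, Mw = params["ritonavir"].M, params["water"].M
        x_back = (w / Md) / (w / Md + (1 - w) / Mw)
        assert x_back == pytest.approx(x_id, rel=1e-12)

    def test_unity_at_melting_point_ideal(self, eq, params):
        assert eq.sle_solubility(params["ritonavir"].melting.T_SL, 0.5, ideal=True) == 1.0

    def test_polymer_boosts_drug_solubility(self, eq):
        in_water = eq.sle_solubility(T, polymer_ratio=0.0)
        in_polymer = eq.sle_solubility(T, polymer_ratio=1.0)
        assert in_water < 1e-4          # essentially insoluble in water
        assert in_polymer > 100 * in_water

    def test_polymer_ratio_bounds_checked(self, eq):
        with pytest.raises(ValueError):
            eq.sle_solubility(T, polymer_ratio=1.2)


class TestFlashInvariants:
    """Run once on the 40 wt% drug-load split and assert every contract."""

    @pytest.fixture(scope="class")
    def flash40(self, dl_sweep):
        _, reports = dl_sweep
        return reports[0.40].flash

    def test_phase_fractions_close(self, flash40):
        assert flash40.frac_L1 + flash40.frac_L2 == pytest.approx(1.0, abs=1e-10)

    def test_mass_balance(self, flash40):
        assert flash40.mass_balance_residual() < 1e-8

    def test_isoactivity(self, flash40):
        assert float(flash40.tie.isoactivity_residual.max()) < 1e-8

    def test_phases_distinct(self, flash40):
        assert flash40.tie.length > 1e-3

    def test_polymer_rich_labeling(self, flash40, eq):
        t = flash40.tie
        assert t.phase_L1.w_of(eq.polymer) > t.phase_L2.w_of(eq.polymer)

    def test_flash_is_idempotent_on_phases(self, flash40, eq):
        # each converged phase lies on the binodal: re-flashing it must
        # not find a further split
        for phase in (flash40.tie.phase_L1, flash40.tie.phase_L2):
            res = eq.lle_flash(T, phase, use_stability=False)
            if not res.stable:
                assert res.tie.length < 5e-3  # at most a numerical sliver

    def test_midpoint_splits_evenly(self, flash40, eq):
        t = flash40.tie
        mid = 0.5 * (t.phase_L1.w + t.phase_L2.w)
        res = eq.lle_flash(T, mid / mid.sum(), use_stability=False)
        assert not res.stable
        assert res.frac_L1 == pytest.approx(0.5, abs=1e-3)


class TestStability:
    def test_pure_water_is_stable(self, eq):
        w = np.zeros(3)
        w[eq.i_water] = 1.0
        assert eq.stability_test(T, w).stable

    def test_point_inside_spinodal_has_negative_hessian(self, eq):
        # well inside the demixing region (hydrated 40 wt% drug load)
        w = np.zeros(3)
        w[eq.i_drug], w[eq.i_poly], w[eq.i_water] = 0.36, 0.54, 0.10
        x = mass_to_mole(w / w.sum(), eq.M)
        assert eq.gibbs_hessian_det(T, x) < 0.0


class TestToyGibbsOracle:
    """Flash against exhaustive two-phase splits on a composition grid.

    The overall composition is a grid node, so conjugate grid pairs
    collinear with it exist along every lattice direction; the flash
    result must beat or match every such split within 1e-6 RT/mol.
    """

    @pytest.fixture(scope="class")
    def toy_eq(self, toy_params):
        return EquilibriumSolver(
            toy_params, drug="A", polymer="B", water="C"
        )

    def test_flash_matches_brute_force_on_grid(self, toy_eq):
        Tt = 310.15
        step = 0.02
        z = np.array([0.40, 0.40, 0.20])  # grid node in mole fractions

        pts = []
        for i in range(int(1 / step) + 1):
            for j in range(int(1 / step) + 1 - i):
                a, b = i * step, j * step
                pts.append((a, b, 1.0 - a - b))
        pts = np.array(pts)
        g = np.array(
            [toy_eq.gibbs_mix_unreferenced(Tt, p) for p in np.clip(pts, 1e-12, None)]
        )

        # exhaustive pairs through z with exact collinearity
        best = np.inf
        for i in range(len(pts)):
            d1 = pts[i] - z
            n1 = np.abs(d1).max()
            if n1 < 1e-12:
                continue
            d2 = pts - z
            # q must be on the opposite ray: d2 = -t*d1, t>0
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(np.abs(d1) > 1e-15, -d2 / d1, np.nan)
            tt = np.nanmax(t, axis=1)
            ok = np.all(np.abs(d2 + tt[:, None] * d1) < 1e-9, axis=1) & (tt > 1e-9)
            if not np.any(ok):
                continue
            f = tt[ok] / (1.0 + tt[ok])  # lever fraction of phase i
            Gs = f * g[i] + (1.0 - f) * g[ok]
            m = float(Gs.min())
            if m < best:
                best = m

        res = toy_eq.lle_flash(Tt, toy_eq.composition_from_mole(z).w)
        g_single = toy_eq.gibbs_mix_unreferenced(Tt, z)
        if res.stable:
            G_flash = g_single
        else:
            t1 = res.tie.phase_L1.x
            t2 = res.tie.phase_L2.x
            # mole-based lever
            d = t2 - t1
            j = int(np.argmax(np.abs(d)))
            b = (z[j] - t1[j]) / d[j]
            G_flash = (1 - b) * toy_eq.gibbs_mix_unreferenced(Tt, t1) + b * toy_eq.gibbs_mix_unreferenced(Tt, t2)
        assert G_flash <= best + 1e-6
        # classification agreement: grid split materially below the
        # single phase implies the flash must also have split
        if best < g_single - 1e-4:
            assert not res.stable


class TestBinodalSpinodal:
    @pytest.fixture(scope="class")
    def short_binodal(self, eq):
        return eq.binodal_trace(T, max_ties=5, polymer_step=0.03)

    def test_ties_satisfy_isoactivity(self, short_binodal):
        assert len(short_binodal) >= 3
        for t in short_binodal:
            assert float(t.isoactivity_residual.max()) < 1e-8

    def test_tie_length_shrinks_toward_plait(self, short_binodal):
        lengths = [t.length for t in short_binodal]
        assert lengths[-1] < lengths[0]

    def test_spinodal_inside_binodal_on_a_ray(self, eq, analyzer):
        # on the 40 wt% drug-load ray the one-phase region ends at the
        # binodal before local instability (spinodal) sets in
        DL = 0.40
        bino = analyzer.binodal_crossing_water(DL, w_lo=0.01)
        spin = None
        for lo, hi in [(0.02, 0.20)]:
            grid = np.linspace(lo, hi, 20)
            path = analyzer.hydration_pathway(DL)
            vals = [
                eq.gibbs_hessian_det(T, mass_to_mole(path.composition(w), eq.M))
                for w in grid
            ]
            for k in range(len(grid) - 1):
                if vals[k] > 0 >= vals[k + 1]:
                    spin = 0.5 * (grid[k] + grid[k + 1])
                    break
        assert bino is not None and spin is not None
        assert bino < spin
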