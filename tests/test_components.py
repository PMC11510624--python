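"""Parameter registry: temperature rules, combining rules, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asdphase.components import (
    BinaryInteraction,
    Melting,
    ParameterSet,
    PureComponent,
    sigma_water,
)


class TestSigmaWater:
    def test_matches_direct_arithmetic_at_body_temperature(self):
        T = 310.15
        expected = (
            2.7927 + 10.11 * math.exp(-0.01755 * T) - 1.417 * math.exp(-0.01146 * T)
        )
        assert sigma_water(T) == pytest.approx(expected, abs=0.0)

    def test_high_temperature_asymptote(self):
        assert sigma_water(1e6) == pytest.approx(2.7927, abs=1e-12)

    def test_decreases_between_room_and_body_temperature(self):
        assert sigma_water(298.15) > sigma_water(310.15)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            sigma_water(0.0)


class TestBinaryLookup:
    def test_kij_temperature_line(self, params):
        # slope*T + intercept from the shipped coefficients
        assert params.kij("ritonavir", "water", 310.15) == pytest.approx(
            0.00006 * 310.15 - 0.059, abs=1e-12
        )
        assert params.kij("PVPVA64", "water", 280.0) == pytest.approx(-0.156)
        assert params.kij("PVPVA64", "water", 350.0) == pytest.approx(-0.156)
        assert params.kij("ritonavir", "PVPVA64", 320.0) == pytest.approx(0.019)

    def test_lookup_is_symmetric(self, params):
        assert params.binary("water", "ritonavir") is params.binary("ritonavir", "water")

    def test_unregistered_pair_raises(self, params):
        with pytest.raises(KeyError):
            params.binary("ritonavir", "benzene")


class TestCombiningRules:
    def test_cross_sigma_is_arithmetic_mean(self, params):
        # constant-sigma pair: drug with polymer
        assert params.combine_sigma("ritonavir", "PVPVA64", 310.15) == pytest.approx(
            0.5 * (3.900 + 2.947), abs=1e-12
        )

    def test_self_combination_identities(self, params):
        T = 310.15
        for name in params.names:
            c = params[name]
            assert params.combine_sigma(name, name, T) == pytest.approx(c.sigma_at(T))
            assert params.combine_u(name, name, T) == pytest.approx(c.u_over_kB)
            eps, kap = params.combine_assoc(name, name, T)
            assert eps == pytest.approx(c.eps_assoc_over_kB)
            assert kap == pytest.approx(c.kappa_assoc)

    def test_symmetry(self, params):
        T = 310.15
        for i in params.names:
            for j in params.names:
                assert params.combine_sigma(i, j, T) == params.combine_sigma(j, i, T)
                assert params.combine_u(i, j, T) == params.combine_u(j, i, T)
                assert params.combine_assoc(i, j, T) == params.combine_assoc(j, i, T)

    def test_cross_dispersion_with_kij_correction(self, params):
        got = params.combine_u("ritonavir", "water", 310.15)
        kij = 0.00006 * 310.15 - 0.059
        assert got == pytest.approx(math.sqrt(305.787 * 353.950) * (1.0 - kij), rel=1e-12)

    def test_induced_association_energy_is_arithmetic_mean(self, params):
        eps, kap = params.combine_assoc("PVPVA64", "water", 310.15)
        assert eps == pytest.approx(0.5 * (0.0 + 2425.7), abs=1e-12)
        assert kap > 0.0  # induced sites are active in the cross term

    @given(
        s1=st.floats(min_value=2.0, max_value=5.0),
        s2=st.floats(min_value=2.0, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_cross_kappa_bounded_by_geometric_mean(self, s1, s2):
        # the sigma factor is <= 1 by AM-GM, equality iff sigma_1 == sigma_2
        a = PureComponent(name="a", M=50, m_seg_per_M=0.03, sigma=s1, u_over_kB=250,
                          kappa_assoc=0.04, eps_assoc_over_kB=1500, n_sites=(1, 1))
        b = PureComponent(name="b", M=60, m_seg_per_M=0.03, sigma=s2, u_over_kB=260,
                          kappa_assoc=0.02, eps_assoc_over_kB=1200, n_sites=(1, 1))
        ps = ParameterSet([a, b])
        _, kap = ps.combine_assoc("a", "b", 300.0)
        geo = math.sqrt(0.04 * 0.02)
        assert kap <= geo + 1e-15
        if abs(s1 - s2) > 1e-9:
            assert kap < geo


class TestValidation:
    def test_rejects_nonpositive_molar_mass(self):
        with pytest.raises(ValueError):
            PureComponent(name="x", M=-1.0, m_seg_per_M=0.03, sigma=3.0, u_over_kB=200.0)

    def test_rejects_negative_association_volume(self):
        with pytest.raises(ValueError):
            PureComponent(name="x", M=10.0, m_seg_per_M=0.03, sigma=3.0,
                          u_over_kB=200.0, kappa_assoc=-0.1)

    def test_rejects_invalid_melting(self):
        with pytest.raises(ValueError):
            Melting(T_SL=-5.0, dh_SL=10.0, dcp_SL=100.0)

    def test_rejects_binary_with_unknown_member(self):
        a = PureComponent(name="a", M=50, m_seg_per_M=0.03, sigma=3.0, u_over_kB=250)
        with pytest.raises(ValueError):
            ParameterSet([a], [BinaryInteraction(frozenset(("a", "ghost")), k_b=0.1)])


class TestSerialization:
    def test_ini_round_trip_is_bit_exact(self, params):
        text = params.to_ini()
        again = ParameterSet.from_ini(text)
        assert again.to_ini() == text

    def test_round_trip_preserves_every_field(self, params):
        again = ParameterSet.from_ini(params.to_ini())
        for name in params.names:
            assert again[name] == params[name]
        for b in params.binaries():
            b2 = again.binary(*sorted(b.pair))
            assert (b2.k_m, b2.k_b, b2.q) == (b.k_m, b.k_b, b.q)
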