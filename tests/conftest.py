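"""Shared fixtures: the real ritonavir/PVPVA64/water system (session-scoped,
expensive pieces computed once) and small fast toy systems for solver tests."""

from __future__ import annotations

import numpy as np
import pytest

from asdphase.components import (
    BinaryInteraction,
    ParameterSet,
    PureComponent,
    default_parameter_set,
)
from asdphase.equilibria import EquilibriumSolver
from asdphase.glass import GlassModel
from asdphase.pathway import PathwayAnalyzer
from asdphase.pcsaft import PcSaft

T_BODY = 310.15       # dissolution-medium temperature, K
P_ATM = 1.013e5       # Pa


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return default_parameter_set()


@pytest.fixture(scope="session")
def analyzer(params) -> PathwayAnalyzer:
    return PathwayAnalyzer(params, T_medium=T_BODY, P=P_ATM)


@pytest.fixture(scope="session")
def eq(analyzer) -> EquilibriumSolver:
    return analyzer.eq


@pytest.fixture(scope="session")
def glass(analyzer) -> GlassModel:
    return analyzer.glass


@pytest.fixture(scope="session")
def model(eq) -> PcSaft:
    return eq.model


@pytest.fixture(scope="session")
def dl_sweep(analyzer):
    """The full drug-load sweep (the expensive pipeline), computed once."""
    df, reports = analyzer.table_report((0.01, 0.05, 0.15, 0.20, 0.40))
    return df, {round(r.DL, 4): r for r in reports}


@pytest.fixture(scope="session")
def dl1_report(dl_sweep):
    """Release analysis of the very dilute 1 wt% drug-load pathway."""
    _, reports = dl_sweep
    return reports[0.01]


@pytest.fixture(scope="session")
def toy_params() -> ParameterSet:
    """Three small non-associating species; the A/B pair demixes at 310 K."""
    a = PureComponent(name="A", M=100.0, m_seg_per_M=0.03, sigma=3.6, u_over_kB=250.0)
    b = PureComponent(name="B", M=120.0, m_seg_per_M=0.025, sigma=3.2, u_over_kB=330.0)
    c = PureComponent(name="C", M=80.0, m_seg_per_M=0.028, sigma=3.4, u_over_kB=285.0)
    return ParameterSet(
        [a, b, c],
        [
            BinaryInteraction(frozenset(("A", "B")), k_b=0.09),
            BinaryInteraction(frozenset(("A", "C")), k_b=0.0),
            BinaryInteraction(frozenset(("B", "C")), k_b=0.0),
        ],
    )


@pytest.fixture(scope="session")
def toy_assoc_params() -> ParameterSet:
    """Two-component associating toy: D self-associates (1/1 sites),
    E carries zero-energy (induced) sites."""
    d = PureComponent(
        name="D", M=60.0, m_seg_per_M=0.04, sigma=3.0, u_over_kB=300.0,
        eps_assoc_over_kB=2000.0, kappa_assoc=0.05, n_sites=(1, 1),
    )
    e = PureComponent(
        name="E", M=90.0, m_seg_per_M=0.03, sigma=3.3, u_over_kB=260.0,
        eps_assoc_over_kB=0.0, kappa_assoc=0.03, n_sites=(2, 2),
    )
    return ParameterSet([d, e], [BinaryInteraction(frozenset(("D", "E")), k_b=0.0)])
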