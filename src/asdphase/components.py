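"""Pure-component and binary-interaction parameter registry for PC-SAFT.

Holds the complete parameter record for each species in a
drug/polymer/water system (PC-SAFT segment parameters, association
parameters, melting properties, true density and glass-transition
temperature) together with the pairwise interaction coefficients
``kij(T) = kij_m * T + kij_b`` and the Kwei ``q_ij`` parameters, and
implements the mixture combining rules:

* Lorentz:           sigma_ij = (sigma_i + sigma_j) / 2
* Berthelot:         u_ij = sqrt(u_i * u_j) * (1 - kij(T))
* Wolbach–Sandler:   eps_ij = (eps_i + eps_j) / 2
                     kappa_ij = sqrt(kappa_i * kappa_j)
                                * (sqrt(sigma_i sigma_j) / ((sigma_i+sigma_j)/2))**3

Units follow the published tables: Å for sigma, K for energies divided
by k_B, g/mol, kg/m³, kJ/mol, J/(mol·K).  The loader never converts
units silently.
"""

from __future__ import annotations

import configparser
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Melting",
    "PureComponent",
    "BinaryInteraction",
    "ParameterSet",
    "sigma_water",
    "WATER_SIGMA_COEFFS",
    "default_parameter_set",
]

#: Coefficients (c0, c1, c2, c3, c4) of the temperature-dependent water
#: segment diameter  sigma(T) = c0 + c1*exp(c2*T) + c3*exp(c4*T)  [Å, T in K].
WATER_SIGMA_COEFFS = (2.7927, 10.11, -0.01755, -1.417, -0.01146)


def sigma_water(T: float) -> float:
    """Temperature-dependent water segment diameter in Å.

    sigma(T) = 2.7927 + 10.11 exp(-0.01755 T) - 1.417 exp(-0.01146 T),
    with T in kelvin.  Decays monotonically to 2.7927 Å at high T.
    """
    if T <= 0.0:
        raise ValueError(f"temperature must be positive, got {T} K")
    c0, c1, c2, c3, c4 = WATER_SIGMA_COEFFS
    return c0 + c1 * math.exp(c2 * T) + c3 * math.exp(c4 * T)


@dataclass(frozen=True)
class Melting:
    """Melting properties of a crystallizable component.

    T_SL : melting temperature, K
    dh_SL : melting enthalpy, kJ/mol
    dcp_SL : liquid-minus-solid heat-capacity difference, J/(mol K)
    """

    T_SL: float
    dh_SL: float
    dcp_SL: float

    def __post_init__(self) -> None:
        if self.T_SL <= 0.0:
            raise ValueError("melting temperature must be positive")
        if self.dh_SL <= 0.0:
            raise ValueError("melting enthalpy must be positive")


@dataclass(frozen=True)
class PureComponent:
    """Full PC-SAFT + thermal parameter record of one species.

    ``sigma_coeffs`` switches the segment diameter to the exponential
    temperature rule used for water; when ``None`` the constant
    ``sigma`` is used at every temperature.  ``n_sites`` is the
    (electron-donor, electron-acceptor) association-site count;
    donor sites bond only to acceptor sites.
    """

    name: str
    M: float                      # molar mass, g/mol
    m_seg_per_M: float            # segment number per molar mass, mol/g
    sigma: float                  # segment diameter, Å (ignored if sigma_coeffs)
    u_over_kB: float              # dispersion energy, K
    eps_assoc_over_kB: float = 0.0  # association energy eps^AiBi / kB, K
    kappa_assoc: float = 0.0      # association volume kappa^AiBi, -
    n_sites: tuple[int, int] = (0, 0)
    rho: float = float("nan")     # true density, kg/m³
    Tg: float = float("nan")      # glass-transition temperature, K
    melting: Melting | None = None
    sigma_coeffs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.M <= 0.0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.m_seg_per_M <= 0.0:
            raise ValueError(f"{self.name}: segment number must be positive")
        if self.u_over_kB <= 0.0:
            raise ValueError(f"{self.name}: dispersion energy must be positive")
        if self.eps_assoc_over_kB < 0.0 or self.kappa_assoc < 0.0:
            raise ValueError(f"{self.name}: association parameters must be >= 0")
        nd, na = self.n_sites
        if nd < 0 or na < 0 or nd != int(nd) or na != int(na):
            raise ValueError(f"{self.name}: site counts must be non-negative integers")
        for T in (273.0, 450.0):
            if self.sigma_at(T) <= 0.0:
                raise ValueError(f"{self.name}: sigma({T} K) must be positive")

    @property
    def m_seg(self) -> float:
        """Segment number m_i = (m_i/M_i) * M_i, dimensionless."""
        return self.m_seg_per_M * self.M

    def sigma_at(self, T: float) -> float:
        """Segment diameter at temperature T (K), in Å."""
        if self.sigma_coeffs is None:
            return self.sigma
        if T <= 0.0:
            raise ValueError(f"temperature must be positive, got {T} K")
        c0, c1, c2, c3, c4 = self.sigma_coeffs
        return c0 + c1 * math.exp(c2 * T) + c3 * math.exp(c4 * T)


@dataclass(frozen=True)
class BinaryInteraction:
    """Pairwise PC-SAFT kij(T) coefficients and Kwei q_ij for one pair.

    kij(T) = k_m * T + k_b, with k_m in 1/K.  q is the Kwei
    glass-transition interaction parameter in K.
    """

    pair: frozenset[str]
    k_m: float = 0.0
    k_b: float = 0.0
    q: float = 0.0

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise ValueError("pair members must be two distinct components")

    def kij_at(self, T: float) -> float:
        """Temperature-dependent binary dispersion correction kij(T)."""
        return self.k_m * T + self.k_b


class ParameterSet:
    """Ordered registry of pure components and binary interactions.

    Component order is preserved and defines the composition-vector
    ordering used throughout the package.  Binary lookup is symmetric;
    an unregistered pair raises ``KeyError``.
    """

    def __init__(
        self,
        components: Iterable[PureComponent],
        binaries: Iterable[BinaryInteraction] = (),
    ) -> None:
        self._components: dict[str, PureComponent] = {}
        for comp in components:
            if comp.name in self._components:
                raise ValueError(f"duplicate component {comp.name!r}")
            self._components[comp.name] = comp
        self._binaries: dict[frozenset[str], BinaryInteraction] = {}
        for b in binaries:
            for name in b.pair:
                if name not in self._components:
                    raise ValueError(f"binary refers to unregistered component {name!r}")
            if b.pair in self._binaries:
                raise ValueError(f"duplicate binary {sorted(b.pair)}")
            self._binaries[b.pair] = b

    # -- access ---------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._components)

    def __getitem__(self, name: str) -> PureComponent:
        return self._components[name]

    def __contains__(self, name: str) -> bool:
        return name in self._components

    def __len__(self) -> int:
        return len(self._components)

    def components(self) -> tuple[PureComponent, ...]:
        return tuple(self._components.values())

    def binary(self, i: str, j: str) -> BinaryInteraction:
        """Symmetric binary-record lookup; KeyError if unregistered."""
        key = frozenset((i, j))
        if key not in self._binaries:
            raise KeyError(f"no binary interaction registered for {sorted((i, j))}")
        return self._binaries[key]

    def binaries(self) -> tuple[BinaryInteraction, ...]:
        return tuple(self._binaries.values())

    # -- combining rules ------------------------------------------------

    def kij(self, i: str, j: str, T: float) -> float:
        """kij(T) for the (i, j) pair; zero for i == j or unregistered pairs."""
        if i == j:
            return 0.0
        key = frozenset((i, j))
        b = self._binaries.get(key)
        return 0.0 if b is None else b.kij_at(T)

    def combine_sigma(self, i: str, j: str, T: float) -> float:
        """Lorentz cross segment diameter (arithmetic mean), Å."""
        return 0.5 * (self[i].sigma_at(T) + self[j].sigma_at(T))

    def combine_u(self, i: str, j: str, T: float) -> float:
        """Berthelot cross dispersion energy with kij(T) correction, K."""
        prod = self[i].u_over_kB * self[j].u_over_kB
        if prod < 0.0:
            raise ValueError("dispersion-energy product must be non-negative")
        return math.sqrt(prod) * (1.0 - self.kij(i, j, T))

    def combine_assoc(self, i: str, j: str, T: float) -> tuple[float, float]:
        """Wolbach–Sandler cross association (energy K, volume -)."""
        ci, cj = self[i], self[j]
        eps = 0.5 * (ci.eps_assoc_over_kB + cj.eps_assoc_over_kB)
        si, sj = ci.sigma_at(T), cj.sigma_at(T)
        ratio = math.sqrt(si * sj) / (0.5 * (si + sj))
        kappa = math.sqrt(ci.kappa_assoc * cj.kappa_assoc) * ratio**3
        return eps, kappa

    # -- serialization --------------------------------------------------

    def to_ini(self) -> str:
        """Serialize to the key/value parameter-file format (bit-exact floats)."""
        cp = configparser.ConfigParser()
        cp.optionxform = str  # preserve key case
        for comp in self.components():
            sec = f"component:{comp.name}"
            cp.add_section(sec)
            cp[sec]["M"] = repr(comp.M)
            cp[sec]["m_seg_per_M"] = repr(comp.m_seg_per_M)
            if comp.sigma_coeffs is not None:
                cp[sec]["sigma_coeffs"] = " ".join(repr(c) for c in comp.sigma_coeffs)
            else:
                cp[sec]["sigma"] = repr(comp.sigma)
            cp[sec]["u_over_kB"] = repr(comp.u_over_kB)
            cp[sec]["eps_assoc_over_kB"] = repr(comp.eps_assoc_over_kB)
            cp[sec]["kappa_assoc"] = repr(comp.kappa_assoc)
            cp[sec]["n_sites"] = f"{comp.n_sites[0]}/{comp.n_sites[1]}"
            cp[sec]["rho"] = repr(comp.rho)
            cp[sec]["Tg"] = repr(comp.Tg)
            if comp.melting is not None:
                cp[sec]["T_SL"] = repr(comp.melting.T_SL)
                cp[sec]["dh_SL"] = repr(comp.melting.dh_SL)
                cp[sec]["dcp_SL"] = repr(comp.melting.dcp_SL)
        for b in self.binaries():
            a, c = sorted(b.pair)
            sec = f"binary:{a}/{c}"
            cp.add_section(sec)
            cp[sec]["k_m"] = repr(b.k_m)
            cp[sec]["k_b"] = repr(b.k_b)
            cp[sec]["q"] = repr(b.q)
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "ParameterSet":
        cp = configparser.ConfigParser()
        cp.optionxform = str
        cp.read_string(text)
        comps: list[PureComponent] = []
        bins: list[BinaryInteraction] = []
        for sec in cp.sections():
            kind, _, label = sec.partition(":")
            d: Mapping[str, str] = cp[sec]
            if kind == "component":
                nd, _, na = d["n_sites"].partition("/")
                melting = None
                if "T_SL" in d:
                    melting = Melting(float(d["T_SL"]), float(d["dh_SL"]), float(d["dcp_SL"]))
                coeffs = None
                sigma = 0.0
                if "sigma_coeffs" in d:
                    coeffs = tuple(float(v) for v in d["sigma_coeffs"].split())
                else:
                    sigma = float(d["sigma"])
                comps.append(
                    PureComponent(
                        name=label,
                        M=float(d["M"]),
                        m_seg_per_M=float(d["m_seg_per_M"]),
                        sigma=sigma,
                        u_over_kB=float(d["u_over_kB"]),
                        eps_assoc_over_kB=float(d["eps_assoc_over_kB"]),
                        kappa_assoc=float(d["kappa_assoc"]),
                        n_sites=(int(nd), int(na)),
                        rho=float(d["rho"]),
                        Tg=float(d["Tg"]),
                        melting=melting,
                        sigma_coeffs=coeffs,
                    )
                )
            elif kind == "binary":
                a, _, c = label.partition("/")
                bins.append(
                    BinaryInteraction(
                        pair=frozenset((a, c)),
                        k_m=float(d["k_m"]),
                        k_b=float(d["k_b"]),
                        q=float(d["q"]),
                    )
                )
            else:
                raise ValueError(f"unknown section {sec!r}")
        return cls(comps, bins)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_ini())

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_ini(fh.read())


def default_parameter_set() -> ParameterSet:
    """The ritonavir / PVPVA64 / water parameter set.

    Loaded from the versioned data asset shipped with the package and
    validated against the registry invariants: literature PC-SAFT
    parameters, densities, glass-transition temperatures, melting
    properties, kij(T) coefficients and Kwei q_ij values for the
    ternary system.  PVPVA64 is one pseudo-component (M = 65 kg/mol)
    carrying zero-energy association sites: alone they are inert, but
    they enable induced cross association with water and ritonavir
    through the Wolbach–Sandler arithmetic-mean energy.
    """
    from importlib import resources

    path = resources.files("asdphase").joinpath("data/ritonavir_pvpva64_water.ini")
    return ParameterSet.from_ini(path.read_text())


def _builtin_parameter_set() -> ParameterSet:
    """In-code twin of the shipped data asset (used to regenerate it)."""
    ritonavir = PureComponent(
        name="ritonavir",
        M=721.0,
        m_seg_per_M=0.0220,
        sigma=3.900,
        u_over_kB=305.787,
        eps_assoc_over_kB=1041.0,
        kappa_assoc=0.02,
        n_sites=(4, 4),
        rho=1151.0,
        Tg=323.5,
        melting=Melting(T_SL=398.15, dh_SL=63.15, dcp_SL=224.0),
    )
    pvpva64 = PureComponent(
        name="PVPVA64",
        M=65000.0,
        m_seg_per_M=0.0372,
        sigma=2.947,
        u_over_kB=205.271,
        eps_assoc_over_kB=0.0,
        kappa_assoc=0.02,
        n_sites=(653, 653),
        rho=1190.0,
        Tg=384.15,
    )
    water = PureComponent(
        name="water",
        M=18.015,
        m_seg_per_M=0.0669,
        sigma=0.0,
        u_over_kB=353.950,
        eps_assoc_over_kB=2425.7,
        kappa_assoc=0.0451,
        n_sites=(1, 1),
        rho=1000.0,
        Tg=138.00,
        sigma_coeffs=WATER_SIGMA_COEFFS,
    )
    binaries = [
        BinaryInteraction(frozenset(("ritonavir", "PVPVA64")), k_m=0.0, k_b=0.019, q=-18.83),
        BinaryInteraction(frozenset(("ritonavir", "water")), k_m=0.00006, k_b=-0.059, q=-304.87),
        BinaryInteraction(frozenset(("PVPVA64", "water")), k_m=0.0, k_b=-0.156, q=34.82),
    ]
    return ParameterSet([ritonavir, pvpva64, water], binaries)
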