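"""PC-SAFT residual Helmholtz energy, density solver, and activity coefficients.

The residual Helmholtz energy per mole, in units of RT, is the sum of a
hard-chain reference, a dispersion (attraction) perturbation, and an
association (hydrogen-bonding) contribution:

    a_res = a_hc + a_disp + a_assoc

* Hard chain: Boublík–Mansoori hard-sphere mixture term chained with the
  radial distribution function at contact; temperature-dependent segment
  diameters d_i = sigma_i (1 - 0.12 exp(-3 u_i / T)).
* Dispersion: second-order perturbation with the universal model
  constants (a_0i..a_2i, b_0i..b_2i) defining the I1/I2 power series in
  the packing fraction, and the C1 compressibility correction.
* Association: donor/acceptor site classes per component (a donor bonds
  only to an acceptor).  Site multiplicities enter as class counts, so a
  polymer carrying hundreds of identical sites costs the same as one
  carrying two.  Association strength
  Delta_ij = sigma_ij^3 g_ij^hs kappa_ij (exp(eps_ij/T) - 1).

Cross parameters come from the components registry (Lorentz/Berthelot
with kij(T); Wolbach–Sandler for association).

All equilibrium calculations in the package run in the liquid branch at
fixed pressure; the density solver returns the packing fraction eta
(reduced density) whose PC-SAFT pressure matches the requested value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .components import ParameterSet

__all__ = [
    "KB",
    "N_AV",
    "MixtureState",
    "HelmholtzBreakdown",
    "SiteFractionSet",
    "DensityResult",
    "PcSaft",
]

KB = 1.380649e-23      # Boltzmann constant, J/K
N_AV = 6.02214076e23   # Avogadro number, 1/mol

ETA_MIN = 1e-10
ETA_MAX = 0.7405       # close-packing bound for the reduced density

# Universal dispersion model constants (rows: a_0i, a_1i, a_2i / b_0i, b_1i, b_2i).
_A_UNIV = np.array(
    [
        [0.9105631445, -0.3084016918, -0.0906148351],
        [0.6361281449, 0.1860531159, 0.4527842806],
        [2.6861347891, -2.5030047259, 0.5962700728],
        [-26.547362491, 21.419793629, -1.7241829131],
        [97.759208784, -65.255885330, -4.1302112531],
        [-159.59154087, 83.318680481, 13.776631870],
        [91.297774084, -33.746922930, -8.6728470368],
    ]
)
_B_UNIV = np.array(
    [
        [0.7240946941, -0.5755498075, 0.0976883116],
        [2.2382791861, 0.6995095521, -0.2557574982],
        [-4.0025849485, 3.8925673390, -9.1558561530],
        [-21.003576815, -17.215471648, 20.642075974],
        [26.855641363, 192.67226447, -38.804430052],
        [206.55133841, -161.82646165, 93.626774077],
        [-355.60235612, -165.20769346, -29.666905585],
    ]
)


@dataclass
class MixtureState:
    """A (T, P, x) state with the solved packing fraction attached."""

    T: float                 # K
    P: float                 # Pa
    x: np.ndarray            # mole fractions, ordered per ParameterSet
    eta: float | None = None  # packing fraction once solved

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if abs(float(self.x.sum()) - 1.0) > 1e-12:
            raise ValueError("mole fractions must sum to 1 within 1e-12")
        if np.any(self.x < -1e-15):
            raise ValueError("mole fractions must be non-negative")
        if self.eta is not None and not (0.0 < self.eta < ETA_MAX):
            raise ValueError("packing fraction out of physical bounds")


@dataclass(frozen=True)
class HelmholtzBreakdown:
    """Residual Helmholtz energy contributions, per mole in units of RT."""

    a_hc: float
    a_disp: float
    a_assoc: float

    @property
    def a_res(self) -> float:
        return self.a_hc + self.a_disp + self.a_assoc


@dataclass(frozen=True)
class SiteFractionSet:
    """Fraction of non-bonded sites per component and site class."""

    X_donor: np.ndarray
    X_acceptor: np.ndarray


@dataclass(frozen=True)
class DensityResult:
    """Solved density root at fixed (T, P, x)."""

    eta: float               # packing fraction
    rho_number: float        # number density, molecules/Å³
    rho_molar: float         # mol/m³
    Z: float                 # compressibility factor at the root
    n_roots: int             # density roots found on the isotherm
    gibbs_selected: bool     # True if min-Gibbs tie-break was needed


class _Workspace:
    """Everything about (T, x) that does not depend on density.

    Precomputing the combining-rule matrices and dispersion sums makes
    repeated density/association evaluations along an isotherm cheap.
    """

    def __init__(self, model: "PcSaft", T: float, x: np.ndarray) -> None:
        self.T = T
        self.x = np.asarray(x, dtype=float)
        self.m = model.m          # segment numbers
        self.ND = model.ND
        self.NA = model.NA
        n = len(self.m)

        sig = np.array([c.sigma_at(T) for c in model.comps])
        u = model.u
        self.d = sig * (1.0 - 0.12 * np.exp(-3.0 * u / T))
        self.mbar = float(self.x @ self.m)
        self.md3 = float(np.sum(self.x * self.m * self.d**3))

        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        u_ij = np.sqrt(np.outer(u, u)) * (1.0 - model.kij_matrix(T))
        # dispersion sums divided by T and T^2
        xm = self.x * self.m
        w_ij = np.outer(xm, xm) * sig_ij**3
        self.m2es3 = float(np.sum(w_ij * (u_ij / T)))
        self.m2e2s3 = float(np.sum(w_ij * (u_ij / T) ** 2))

        frac = (self.mbar - 1.0) / self.mbar if self.mbar != 0 else 0.0
        frac2 = frac * (self.mbar - 2.0) / self.mbar if self.mbar != 0 else 0.0
        self.ai = _A_UNIV[:, 0] + frac * _A_UNIV[:, 1] + frac2 * _A_UNIV[:, 2]
        self.bi = _B_UNIV[:, 0] + frac * _B_UNIV[:, 1] + frac2 * _B_UNIV[:, 2]

        # association strength prefactor: Delta_ij = pref_ij * g_ij(eta)
        eps_ij = 0.5 * (model.eps[:, None] + model.eps[None, :])
        ratio = np.sqrt(np.outer(sig, sig)) / sig_ij
        kap_ij = np.sqrt(np.outer(model.kap, model.kap)) * ratio**3
        self.delta_pref = sig_ij**3 * kap_ij * np.expm1(eps_ij / T)
        self.has_assoc = bool(np.any(self.delta_pref > 0.0) and np.any(self.ND + self.NA))

        self.dmat = np.outer(self.d, self.d) / (self.d[:, None] + self.d[None, :])
        self._X_warm: tuple[np.ndarray, np.ndarray] | None = None

    # -- density mapping ------------------------------------------------

    def rho_of_eta(self, eta: float) -> float:
        return 6.0 * eta / (math.pi * self.md3)

    # -- contributions --------------------------------------------------

    def _zetas(self, rho: float) -> np.ndarray:
        pref = math.pi / 6.0 * rho
        xm = self.x * self.m
        return np.array(
            [
                pref * float(np.sum(xm)),
                pref * float(np.sum(xm * self.d)),
                pref * float(np.sum(xm * self.d**2)),
                pref * float(np.sum(xm * self.d**3)),
            ]
        )

    def g_contact(self, z2: float, z3: float) -> np.ndarray:
        """Hard-sphere radial distribution function at contact, pair matrix."""
        om = 1.0 - z3
        dm = self.dmat
        return 1.0 / om + dm * 3.0 * z2 / om**2 + dm**2 * 2.0 * z2**2 / om**3

    def a_hc(self, rho: float) -> float:
        z0, z1, z2, z3 = self._zetas(rho)
        om = 1.0 - z3
        a_hs = (
            3.0 * z1 * z2 / om + z2**3 / (z3 * om**2) + (z2**3 / z3**2 - z0) * math.log(om)
        ) / z0
        g = self.g_contact(z2, z3)
        gii = np.diag(g)
        return self.mbar * a_hs - float(np.sum(self.x * (self.m - 1.0) * np.log(gii)))

    def a_disp(self, rho: float, eta: float) -> float:
        powers = eta ** np.arange(7)
        I1 = float(self.ai @ powers)
        I2 = float(self.bi @ powers)
        m = self.mbar
        om = 1.0 - eta
        C1 = 1.0 / (
            1.0
            + m * (8.0 * eta - 2.0 * eta**2) / om**4
            + (1.0 - m)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (om * (2.0 - eta)) ** 2
        )
        return -2.0 * math.pi * rho * I1 * self.m2es3 - math.pi * rho * m * C1 * I2 * self.m2e2s3

    def site_fractions(self, rho: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
        """Self-consistent non-bonded site fractions (donor, acceptor).

        Damped successive substitution warm-up followed by Newton
        iterations on the residual X - 1/(1 + sum); tolerance 1e-13 on
        the maximum absolute update.
        """
        n = len(self.x)
        if not self.has_assoc:
            ones = np.ones(n)
            return ones, ones
        z = self._zetas(rho)
        delta = self.delta_pref * self.g_contact(z[2], z[3])
        # A[i, j] = rho * x_j * N_j^acc * Delta_ij  (bonds a donor on i)
        A = rho * delta * (self.x * self.NA)[None, :]
        B = rho * delta * (self.x * self.ND)[None, :]

        if self._X_warm is not None:
            XD, XA = (v.copy() for v in self._X_warm)
        else:
            XD = np.full(n, 0.5)
            XA = np.full(n, 0.5)

        def residual(XD, XA):
            cD = 1.0 / (1.0 + A @ XA)
            cA = 1.0 / (1.0 + B @ XD)
            return cD, cA

        # damped substitution pre-conditioner, then Newton to machine
        # precision: the site fractions feed finite-difference chemical
        # potentials, so sloppy X would poison the derivatives
        damp = 0.5
        for _ in range(30):
            cD, cA = residual(XD, XA)
            move = max(np.max(np.abs(cD - XD)), np.max(np.abs(cA - XA)))
            XD = damp * cD + (1.0 - damp) * XD
            XA = damp * cA + (1.0 - damp) * XA
            if move < 1e-10:
                break
        converged = False
        X = np.concatenate([XD, XA])
        eye = np.eye(2 * n)
        for _ in range(80):
            XD, XA = X[:n], X[n:]
            cD, cA = residual(XD, XA)
            R = np.concatenate([XD - cD, XA - cA])
            if np.max(np.abs(R)) < 1e-15:
                converged = True
                break
            J = eye.copy()
            J[:n, n:] += A * (cD**2)[:, None]
            J[n:, :n] += B * (cA**2)[:, None]
            try:
                step = np.linalg.solve(J, R)
            except np.linalg.LinAlgError:
                break
            X = np.clip(X - step, 1e-14, 1.0)
            if np.max(np.abs(step)) < 1e-15:
                converged = True
                XD, XA = X[:n], X[n:]
                break
        XD, XA = X[:n], X[n:]
        if not converged:
            # heavily damped substitution: slow but globally convergent
            damp = 0.15
            for _ in range(200000):
                cD, cA = residual(XD, XA)
                move = max(np.max(np.abs(cD - XD)), np.max(np.abs(cA - XA)))
                XD = damp * cD + (1.0 - damp) * XD
                XA = damp * cA + (1.0 - damp) * XA
                if move < 1e-13:
                    converged = True
                    break
            if not converged:
                raise RuntimeError(
                    "association site-fraction solver did not converge: "
                    f"T={self.T}, x={self.x}, rho={rho}, eta={eta}, "
                    f"|A|max={np.max(np.abs(A))}, |B|max={np.max(np.abs(B))}"
                )
        self._X_warm = (XD.copy(), XA.copy())
        return XD, XA

    def a_assoc(self, rho: float, eta: float) -> float:
        if not self.has_assoc:
            return 0.0
        XD, XA = self.site_fractions(rho, eta)
        termD = self.ND * (np.log(XD) - 0.5 * XD + 0.5)
        termA = self.NA * (np.log(XA) - 0.5 * XA + 0.5)
        return float(np.sum(self.x * (termD + termA)))

    def a_res(self, eta: float) -> HelmholtzBreakdown:
        rho = self.rho_of_eta(eta)
        return HelmholtzBreakdown(
            a_hc=self.a_hc(rho),
            a_disp=self.a_disp(rho, eta),
            a_assoc=self.a_assoc(rho, eta),
        )

    def Z_numeric(self, eta: float) -> float:
        """1 + eta * d(a_res)/d(eta) by central differences (cross-check)."""
        h = 1e-6 * max(eta, 1e-4)
        lo = max(eta - h, ETA_MIN / 10)
        hi = eta + h
        a_hi = self.a_res(hi).a_res
        a_lo = self.a_res(lo).a_res
        return 1.0 + eta * (a_hi - a_lo) / (hi - lo)

    def _g_and_deriv(self, eta: float):
        """Contact rdf pair matrix and its eta-derivative (analytic)."""
        om = 1.0 - eta
        k2 = (float(np.sum(self.x * self.m * self.d**2)) / self.md3) if self.md3 else 0.0
        dm = self.dmat
        g = 1.0 / om + 3.0 * dm * k2 * eta / om**2 + 2.0 * dm**2 * k2**2 * eta**2 / om**3
        gp = (
            1.0 / om**2
            + 3.0 * dm * k2 * (1.0 / om**2 + 2.0 * eta / om**3)
            + 2.0 * dm**2 * k2**2 * (2.0 * eta / om**3 + 3.0 * eta**2 / om**4)
        )
        return g, gp

    def Z(self, eta: float) -> float:
        """Analytic compressibility factor at fixed T, x.

        Hard-chain and dispersion terms use the standard closed-form
        derivatives; the association term uses the envelope theorem on
        the bonding free-energy functional (site fractions held at
        their converged values), which avoids differentiating the
        site-fraction solution.
        """
        rho = self.rho_of_eta(eta)
        z0, z1, z2, z3 = self._zetas(rho)
        om = 1.0 - eta
        Z_hs = z3 / om + 3.0 * z1 * z2 / (z0 * om**2) + z2**3 * (3.0 - z3) / (z0 * om**3)
        g, gp = self._g_and_deriv(eta)
        gii = np.diag(g)
        gpii = np.diag(gp)
        Z_hc = self.mbar * Z_hs - float(
            np.sum(self.x * (self.m - 1.0) * eta * gpii / gii)
        )

        powers = eta ** np.arange(7)
        I2 = float(self.bi @ powers)
        detaI1 = float(self.ai @ (np.arange(1, 8) * powers))
        detaI2 = float(self.bi @ (np.arange(1, 8) * powers))
        m = self.mbar
        C1 = 1.0 / (
            1.0
            + m * (8.0 * eta - 2.0 * eta**2) / om**4
            + (1.0 - m)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (om * (2.0 - eta)) ** 2
        )
        C2 = -C1**2 * (
            m * (-4.0 * eta**2 + 20.0 * eta + 8.0) / om**5
            + (1.0 - m)
            * (2.0 * eta**3 + 12.0 * eta**2 - 48.0 * eta + 40.0)
            / (om * (2.0 - eta)) ** 3
        )
        Z_disp = (
            -2.0 * math.pi * rho * detaI1 * self.m2es3
            - math.pi * rho * m * (C1 * detaI2 + C2 * eta * I2) * self.m2e2s3
        )

        Z_assoc = 0.0
        if self.has_assoc:
            XD, XA = self.site_fractions(rho, eta)
            c = 6.0 / (math.pi * self.md3)
            w = np.outer(self.x * self.ND * XD, self.x * self.NA * XA)
            Z_assoc = -eta * float(np.sum(w * self.delta_pref * (g + eta * gp))) * c

        return 1.0 + Z_hc + Z_disp + Z_assoc

    def pressure(self, eta: float) -> float:
        """PC-SAFT pressure in Pa at the given packing fraction."""
        rho = self.rho_of_eta(eta)  # molecules / Å³
        return self.Z(eta) * rho * 1e30 * KB * self.T


class PcSaft:
    """PC-SAFT model for the components of a :class:`ParameterSet`.

    Parameters
    ----------
    params : ParameterSet
        Registry holding pure-component and binary parameters.
    names : sequence of str, optional
        Component ordering for composition vectors; defaults to the
        registry order.
    """

    def __init__(self, params: ParameterSet, names=None) -> None:
        self.params = params
        self.names = tuple(names) if names is not None else params.names
        self.comps = tuple(params[n] for n in self.names)
        self.M = np.array([c.M for c in self.comps])
        self.m = np.array([c.m_seg for c in self.comps])
        self.u = np.array([c.u_over_kB for c in self.comps])
        self.eps = np.array([c.eps_assoc_over_kB for c in self.comps])
        self.kap = np.array([c.kappa_assoc for c in self.comps])
        self.ND = np.array([c.n_sites[0] for c in self.comps], dtype=float)
        self.NA = np.array([c.n_sites[1] for c in self.comps], dtype=float)
        self._pure_lnphi_cache: dict[tuple[float, float, int], float] = {}

    def kij_matrix(self, T: float) -> np.ndarray:
        n = len(self.names)
        K = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                K[i, j] = K[j, i] = self.params.kij(self.names[i], self.names[j], T)
        return K

    def workspace(self, T: float, x) -> _Workspace:
        return _Workspace(self, T, np.asarray(x, dtype=float))

    # -- public evaluation ----------------------------------------------

    def residual_helmholtz(self, state: MixtureState) -> HelmholtzBreakdown:
        """Residual Helmholtz breakdown at a state with solved density."""
        if state.eta is None:
            raise ValueError("state has no solved packing fraction")
        if not (0.0 < state.eta < ETA_MAX):
            raise ValueError("packing fraction out of bounds")
        return self.workspace(state.T, state.x).a_res(state.eta)

    def solve_site_fractions(self, state: MixtureState) -> SiteFractionSet:
        if state.eta is None:
            raise ValueError("state has no solved packing fraction")
        ws = self.workspace(state.T, state.x)
        XD, XA = ws.site_fractions(ws.rho_of_eta(state.eta), state.eta)
        return SiteFractionSet(X_donor=XD, X_acceptor=XA)

    def solve_density(
        self, T: float, P: float, x, branch: str = "liquid", eta_guess: float | None = None
    ) -> DensityResult:
        """Packing fraction whose PC-SAFT pressure equals P.

        ``branch='liquid'`` returns the largest-eta root,
        ``branch='vapor'`` the smallest.  If three roots exist the
        returned result flags whether a lower-Gibbs alternative exists.
        """
        from scipy.optimize import brentq

        ws = self.workspace(T, np.asarray(x, dtype=float))
        f = lambda eta: ws.pressure(eta) - P
        roots: list[float] = []
        n_roots = -1  # unknown unless a full scan ran
        gibbs_selected = False
        if branch == "liquid":
            eta = None
            if eta_guess is not None and ETA_MIN < eta_guess < ETA_MAX:
                # warm start: try a narrow bracket around the guess
                lo = max(eta_guess - 0.02, ETA_MIN)
                hi = min(eta_guess + 0.02, ETA_MAX)
                flo, fhi = f(lo), f(hi)
                if flo < 0.0 < fhi:
                    eta = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
            if eta is None:
                # walk down from close packing to bracket the largest root
                step = 0.05
                hi = ETA_MAX
                fhi = f(hi)
                while hi - step > ETA_MIN:
                    lo = hi - step
                    flo = f(lo)
                    if fhi > 0.0 >= flo:
                        eta = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
                        break
                    hi, fhi = lo, flo
            if eta is None:
                raise RuntimeError(
                    f"no liquid density root in ({ETA_MIN}, {ETA_MAX}) "
                    f"at T={T} K, P={P} Pa"
                )
        else:
            grid = np.concatenate(
                [np.geomspace(ETA_MIN, 1e-3, 8), np.linspace(2e-3, ETA_MAX, 56)]
            )
            vals = np.array([f(g) for g in grid])
            for k in range(len(grid) - 1):
                if vals[k] == 0.0:
                    roots.append(float(grid[k]))
                elif vals[k] * vals[k + 1] < 0.0:
                    roots.append(brentq(f, grid[k], grid[k + 1], xtol=1e-14, rtol=8.9e-16))
            if not roots:
                raise RuntimeError(
                    f"no density root in ({ETA_MIN}, {ETA_MAX}) at T={T} K, P={P} Pa; "
                    f"pressure range [{vals.min():.3e}, {vals.max():.3e}] Pa"
                )
            n_roots = len(roots)
            eta = min(roots)
            if len(roots) > 1:
                # tie-break flag: compare residual Gibbs energy among roots
                g_vals = []
                for r in roots:
                    a = ws.a_res(r).a_res
                    Zr = ws.Z(r)
                    g_vals.append(a + (Zr - 1.0) - math.log(Zr))
                best = roots[int(np.argmin(g_vals))]
                gibbs_selected = abs(best - eta) > 1e-12
        rho = ws.rho_of_eta(eta)
        rho_molar = rho * 1e30 / N_AV
        return DensityResult(
            eta=float(eta),
            rho_number=float(rho),
            rho_molar=float(rho_molar),
            Z=float(ws.Z(eta)),
            n_roots=n_roots if n_roots > 0 else 1,
            gibbs_selected=gibbs_selected,
        )

    def mass_density(self, T: float, P: float, x, branch: str = "liquid") -> float:
        """Mass density in kg/m³ at (T, P, x)."""
        res = self.solve_density(T, P, x, branch)
        Mbar = float(np.asarray(x) @ self.M)  # g/mol
        return res.rho_molar * Mbar / 1000.0

    def lnphi(
        self,
        T: float,
        P: float,
        x,
        branch: str = "liquid",
        eta_guess: float | None = None,
        return_eta: bool = False,
    ):
        """ln of fugacity coefficients at (T, P, x), liquid branch by default.

        Residual chemical potentials are obtained from central
        finite differences of n·a_res in mole numbers at constant
        total volume (this derivative already carries the Z-1
        density-change term), then ln phi_i = mu_i^res/RT - ln Z.  With
        ``return_eta`` the solved packing fraction is returned too
        (useful to warm-start the next density solve).
        """
        x = np.asarray(x, dtype=float)
        n = len(x)
        res = self.solve_density(T, P, x, branch, eta_guess=eta_guess)
        rho0 = res.rho_number
        def F(dn: np.ndarray) -> float:
            # n·a_res at constant volume for mole numbers x + dn
            ni = x + dn
            ntot = 1.0 + float(dn.sum())
            ws = self.workspace(T, ni / ntot)
            eta = rho0 * ntot * math.pi / 6.0 * ws.md3
            return ntot * ws.a_res(eta).a_res

        F0 = None
        mu = np.zeros(n)
        for i in range(n):
            # step scaled to the mole number: balances truncation against
            # roundoff in the strongly curved small-fraction directions
            h = 1e-4 * max(x[i], 2e-3)
            e = np.zeros(n)
            e[i] = h
            if x[i] >= h:
                mu[i] = (F(e) - F(-e)) / (2.0 * h)
            else:
                # second-order forward difference keeps mole numbers non-negative
                if F0 is None:
                    F0 = F(np.zeros(n))
                mu[i] = (-3.0 * F0 + 4.0 * F(e) - F(2.0 * e)) / (2.0 * h)
        out = mu - math.log(res.Z)
        if return_eta:
            return out, res.eta
        return out

    def _lnphi_pure(self, T: float, P: float, i: int) -> float:
        key = (T, P, i)
        if key not in self._pure_lnphi_cache:
            x = np.zeros(len(self.names))
            x[i] = 1.0
            self._pure_lnphi_cache[key] = float(self.lnphi(T, P, x)[i])
        return self._pure_lnphi_cache[key]

    def gamma(self, T: float, P: float, x) -> np.ndarray:
        """Mole-fraction activity coefficients, pure-liquid reference.

        gamma_i = phi_i(T, P, x) / phi_i^pure(T, P), both on the
        liquid branch, so gamma_i -> 1 as x_i -> 1.
        """
        ln_mix = self.lnphi(T, P, x)
        ln_pure = np.array([self._lnphi_pure(T, P, i) for i in range(len(self.names))])
        return np.exp(ln_mix - ln_pure)
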