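"""Solid–liquid and liquid–liquid equilibria for drug/polymer/water ternaries.

Solid–liquid equilibrium (drug solubility) solves

    x_drug = (1/gamma_drug) * exp[ -dh_SL/(R T) (1 - T/T_SL)
                                   - dcp_SL/R (ln(T_SL/T) - T_SL/T + 1) ]

as a damped fixed point, the activity coefficient coming from PC-SAFT at
the saturated composition.

Liquid–liquid equilibrium enforces isoactivity for every component,

    x_i^L1 gamma_i^L1 = x_i^L2 gamma_i^L2,

solved as a two-phase flash: bounded Gibbs-energy minimization over the
phase allocation (logit parametrization, gradient = chemical-potential
difference) followed by an active-set Newton corrector on the
isoactivity equations, seeded from fixed corner-biased allocations or
tangent-plane-distance trial phases.  Compositions are solved in mole
fractions (the natural variable of the isoactivity condition) and
converted to mass fractions for reporting.  All multi-start
initializations are fixed, documented lists — the pipeline is fully
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .components import ParameterSet
from .pcsaft import PcSaft

__all__ = [
    "R_GAS",
    "TernaryComposition",
    "TieLine",
    "TwoPhaseResult",
    "StabilityResult",
    "EquilibriumSolver",
    "mass_to_mole",
    "mole_to_mass",
]

logger = logging.getLogger(__name__)

R_GAS = 8.31446261815324  # J/(mol K)


def mass_to_mole(w: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Convert mass fractions to mole fractions (exact bijection)."""
    n = np.asarray(w, dtype=float) / np.asarray(M, dtype=float)
    return n / n.sum()


def mole_to_mass(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Convert mole fractions to mass fractions (exact bijection)."""
    g = np.asarray(x, dtype=float) * np.asarray(M, dtype=float)
    return g / g.sum()


@dataclass(frozen=True)
class TernaryComposition:
    """A point in composition space, carried in both mass and mole basis.

    Vectors are ordered like the parameter registry.  The two bases are
    kept consistent by construction; use :meth:`from_mass` /
    :meth:`from_mole`.
    """

    names: tuple[str, ...]
    w: np.ndarray  # mass fractions
    x: np.ndarray  # mole fractions

    @classmethod
    def from_mass(cls, w, names, M) -> "TernaryComposition":
        w = np.asarray(w, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12 or np.any(w < -1e-15):
            raise ValueError("mass fractions must be non-negative and sum to 1")
        return cls(tuple(names), w, mass_to_mole(w, M))

    @classmethod
    def from_mole(cls, x, names, M) -> "TernaryComposition":
        x = np.asarray(x, dtype=float)
        if abs(x.sum() - 1.0) > 1e-12 or np.any(x < -1e-15):
            raise ValueError("mole fractions must be non-negative and sum to 1")
        return cls(tuple(names), mole_to_mass(x, M), x)

    def w_of(self, name: str) -> float:
        return float(self.w[self.names.index(name)])

    def x_of(self, name: str) -> float:
        return float(self.x[self.names.index(name)])


@dataclass(frozen=True)
class TieLine:
    """Conjugate phase compositions of one LLE tie line.

    ``phase_L1`` is the polymer-rich side, ``phase_L2`` the drug-rich
    side.  ``isoactivity_residual`` holds |x gamma (L1) - x gamma (L2)|
    per component.
    """

    phase_L1: TernaryComposition
    phase_L2: TernaryComposition
    isoactivity_residual: np.ndarray

    @property
    def length(self) -> float:
        """Euclidean tie-line length in mass-fraction space."""
        return float(np.linalg.norm(self.phase_L1.w - self.phase_L2.w))


@dataclass(frozen=True)
class TwoPhaseResult:
    """Outcome of an LLE flash: a split with lever-rule fractions, or a
    single stable phase."""

    overall: TernaryComposition
    stable: bool
    tie: TieLine | None = None
    frac_L1: float = 1.0   # mass fraction of polymer-rich phase
    frac_L2: float = 0.0   # mass fraction of drug-rich phase
    iterations: int = 0

    def mass_balance_residual(self) -> float:
        if self.tie is None:
            return 0.0
        recon = self.frac_L1 * self.tie.phase_L1.w + self.frac_L2 * self.tie.phase_L2.w
        return float(np.max(np.abs(recon - self.overall.w)))


@dataclass(frozen=True)
class StabilityResult:
    stable: bool
    tpd: float                        # most negative tangent-plane distance found
    trial: TernaryComposition | None  # minimizing trial phase if unstable


class EquilibriumSolver:
    """Phase-equilibrium engine bound to a parameter registry.

    Parameters
    ----------
    params : ParameterSet
        Component registry (drug with melting record, polymer, water).
    P : float
        Pressure in Pa for all liquid-state evaluations (default 1 atm).
    drug, polymer, water : str, optional
        Role assignment; by default water is the component named
        ``water``, the polymer has the largest molar mass, and the drug
        is the remaining one.
    """

    def __init__(
        self,
        params: ParameterSet,
        P: float = 1.013e5,
        drug: str | None = None,
        polymer: str | None = None,
        water: str | None = None,
    ) -> None:
        self.params = params
        self.model = PcSaft(params)
        self.P = P
        self.names = self.model.names
        self.M = self.model.M
        comps = {c.name: c for c in params.components()}
        if water is None:
            water = "water" if "water" in comps else min(comps.values(), key=lambda c: c.M).name
        if polymer is None:
            polymer = max((c for c in comps.values() if c.name != water), key=lambda c: c.M).name
        if drug is None:
            rest = [n for n in comps if n not in (water, polymer)]
            if len(rest) != 1:
                raise ValueError("cannot infer the drug component")
            drug = rest[0]
        self.drug, self.polymer, self.water = drug, polymer, water
        self.i_drug = self.names.index(drug)
        self.i_poly = self.names.index(polymer)
        self.i_water = self.names.index(water)

    # -- helpers --------------------------------------------------------

    def composition_from_mass(self, w) -> TernaryComposition:
        return TernaryComposition.from_mass(w, self.names, self.M)

    def composition_from_mole(self, x) -> TernaryComposition:
        return TernaryComposition.from_mole(x, self.names, self.M)

    def gamma_mass(self, T: float, w) -> np.ndarray:
        """Activity coefficients (mole basis) at a mass-fraction point."""
        return self.model.gamma(T, self.P, mass_to_mole(np.asarray(w, float), self.M))

    # -- solid–liquid equilibrium --------------------------------------

    def ideal_solubility(self, T: float) -> float:
        """Ideal (gamma = 1) drug solubility as a mole fraction."""
        melt = self.params[self.drug].melting
        if melt is None:
            raise ValueError(f"{self.drug} has no melting record")
        arg = -melt.dh_SL * 1000.0 / (R_GAS * T) * (1.0 - T / melt.T_SL) - (
            melt.dcp_SL / R_GAS
        ) * (math.log(melt.T_SL / T) - melt.T_SL / T + 1.0)
        return math.exp(arg)

    def sle_solubility(
        self,
        T: float,
        polymer_ratio: float,
        ideal: bool = False,
        tol: float = 1e-10,
        max_iter: int = 200,
    ) -> float:
        """Saturated drug mass fraction in a polymer/water solvent.

        ``polymer_ratio`` is the polymer mass fraction of the drug-free
        solvent (0 = pure water, 1 = pure polymer).  With ``ideal=True``
        the activity coefficient is forced to one and the closed-form
        ideal solubility is returned.
        """
        if not 0.0 <= polymer_ratio <= 1.0:
            raise ValueError("polymer_ratio must lie in [0, 1]")
        x_ideal = self.ideal_solubility(T)
        s = polymer_ratio / self.M[self.i_poly] + (1.0 - polymer_ratio) / self.M[self.i_water]

        def w_drug_from_x(x_d: float) -> float:
            A = s * self.M[self.i_drug]
            return x_d * A / (1.0 - x_d + x_d * A)

        if ideal:
            return 1.0 if x_ideal >= 1.0 else w_drug_from_x(x_ideal)

        def gamma_at(x_d: float) -> float:
            w = np.zeros(3)
            w[self.i_drug] = w_drug_from_x(x_d)
            rest = 1.0 - w[self.i_drug]
            w[self.i_poly] = rest * polymer_ratio
            w[self.i_water] = rest * (1.0 - polymer_ratio)
            return float(self.gamma_mass(T, w)[self.i_drug])

        x_d = min(x_ideal, 0.5)
        converged = False
        for _ in range(max_iter):
            x_new = min(x_ideal / gamma_at(x_d), 0.999999)
            if abs(x_new - x_d) < tol:
                x_d = x_new
                converged = True
                break
            x_d = 0.5 * (x_d + x_new)
        if not converged:
            # strongly composition-dependent gamma can make the damped
            # fixed point cycle; solve ln(x gamma) = ln(x_ideal) bracketed
            from scipy.optimize import brentq

            g = lambda xd: math.log(xd * gamma_at(xd)) - math.log(x_ideal)
            grid = np.geomspace(1e-10, 0.999, 40)
            vals = [g(v) for v in grid]
            for k in range(len(grid) - 1):
                if vals[k] < 0.0 <= vals[k + 1]:
                    x_d = brentq(g, grid[k], grid[k + 1], xtol=1e-14)
                    converged = True
                    break
            if not converged:
                raise RuntimeError("SLE solver found no saturation point")
        if x_d >= 0.999999:
            logger.warning("solubility at or above the melting limit")
        return w_drug_from_x(x_d)

    def solubility_curve(self, T: float, n: int = 21) -> np.ndarray:
        """Drug-saturation line across polymer:water ratios.

        Returns mass-fraction rows in registry order, one per ratio on a
        uniform [0, 1] grid.
        """
        rows = []
        for r in np.linspace(0.0, 1.0, n):
            wd = self.sle_solubility(T, r)
            w = np.zeros(3)
            w[self.i_drug] = wd
            w[self.i_poly] = (1.0 - wd) * r
            w[self.i_water] = (1.0 - wd) * (1.0 - r)
            rows.append(w)
        return np.array(rows)

    # -- stability (tangent-plane distance) -----------------------------

    def _trial_mass_list(self) -> list[np.ndarray]:
        """Fixed corner-biased trial phases (mass fractions)."""
        trials = []
        for wd, wp, ww in [
            (0.90, 0.05, 0.05),   # drug corner
            (0.05, 0.05, 0.90),   # water corner
            (0.05, 0.90, 0.05),   # polymer corner
            (0.50, 0.02, 0.48),   # drug/water edge
            (0.30, 0.50, 0.20),   # interior
        ]:
            w = np.zeros(3)
            w[self.i_drug], w[self.i_poly], w[self.i_water] = wd, wp, ww
            trials.append(w)
        return trials

    def _tpd(self, T: float, y: np.ndarray, d: np.ndarray) -> float:
        lnphi_y = self.model.lnphi(T, self.P, y)
        yy = np.clip(y, 1e-300, None)
        return float(np.sum(y * (np.log(yy) + lnphi_y - d)))

    def stability_test(self, T: float, w) -> StabilityResult:
        """Tangent-plane stability analysis at a mass-fraction point.

        Michelsen successive substitution from the fixed corner-biased
        start list; a converged trial with a negative tangent-plane
        distance certifies instability and provides the flash
        initialization.
        """
        w = np.asarray(w, dtype=float)
        z = mass_to_mole(w, self.M)
        if np.max(z) > 1.0 - 1e-12:
            return StabilityResult(stable=True, tpd=0.0, trial=None)
        lnphi_z = self.model.lnphi(T, self.P, z)
        zz = np.clip(z, 1e-300, None)
        d = np.log(zz) + lnphi_z
        best_tpd = 0.0
        best_y: np.ndarray | None = None
        for w_try in self._trial_mass_list():
            # iterate in log space: |ln phi| is O(1000) for a long polymer
            lnY = np.log(mass_to_mole(w_try, self.M))
            for _ in range(80):
                y = np.exp(lnY - lnY.max())
                y /= y.sum()
                lnphi_y = self.model.lnphi(T, self.P, y)
                lnY_new = d - lnphi_y
                if np.max(np.abs(lnY_new - lnY)) < 1e-9:
                    lnY = lnY_new
                    break
                lnY = lnY_new
            y = np.exp(lnY - lnY.max())
            y /= y.sum()
            tpd = self._tpd(T, y, d)
            if tpd < best_tpd - 1e-12:
                best_tpd = tpd
                best_y = y
        if best_y is None or best_tpd > -1e-10:
            return StabilityResult(stable=True, tpd=best_tpd, trial=None)
        return StabilityResult(
            stable=False, tpd=best_tpd, trial=self.composition_from_mole(best_y)
        )

    # -- liquid–liquid flash --------------------------------------------

    def _chemical_potentials(self, T: float, x: np.ndarray, eta_guess=None):
        """mu_i/RT up to the ideal-gas reference (ln x + ln phi), plus eta."""
        lnphi, eta = self.model.lnphi(T, self.P, x, eta_guess=eta_guess, return_eta=True)
        return np.log(np.clip(x, 1e-300, None)) + lnphi, eta

    def _gibbs_flash(self, T: float, z: np.ndarray, split0: np.ndarray):
        """Two-phase Gibbs-energy minimization.

        Variables are the logits t_i of the phase-2 allocation
        n2_i = z_i * sigmoid(t_i); the gradient is the chemical-potential
        difference between the phases, so a converged minimum satisfies
        isoactivity.  Returns (x1, x2, beta, n_evals) or None when the
        minimizer collapses to a single phase.
        """
        from scipy.optimize import minimize
        from scipy.special import expit, logit

        eta_cache = {"L1": None, "L2": None}
        evals = [0]

        def fg(t: np.ndarray):
            evals[0] += 1
            frac = expit(t)
            n2 = z * frac
            n1 = z - n2
            b2 = n2.sum()
            b1 = n1.sum()
            x1 = n1 / b1
            x2 = n2 / b2
            mu1, eta_cache["L1"] = self._chemical_potentials(T, x1, eta_cache["L1"])
            mu2, eta_cache["L2"] = self._chemical_potentials(T, x2, eta_cache["L2"])
            G = float(n1 @ mu1 + n2 @ mu2)
            grad = (mu2 - mu1) * z * frac * (1.0 - frac)
            return G, grad

        t0 = logit(np.clip(split0, 1e-12, 1.0 - 1e-12))
        res = minimize(
            fg, t0, jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-17, "gtol": 1e-12},
        )
        frac = expit(res.x)
        n2 = z * frac
        beta = float(n2.sum())
        if not (1e-8 < beta < 1.0 - 1e-8):
            return None
        n2, n_newton = self._newton_polish(T, z, n2, eta_cache)
        beta = float(n2.sum())
        if not (1e-8 < beta < 1.0 - 1e-8):
            return None
        n1 = z - n2
        x1 = n1 / n1.sum()
        x2 = n2 / beta
        return x1, x2, beta, evals[0] + n_newton

    def _newton_polish(self, T: float, z: np.ndarray, n2: np.ndarray, eta_cache):
        """Newton iteration on the isoactivity conditions mu2 - mu1 = 0.

        The unknowns are logits of the phase-2 allocation fractions
        v_i = logit(n2_i/z_i): in that space the ln x singularity of a
        nearly fully partitioned component cancels against the
        vanishing allocation derivative, so the Jacobian stays O(1)
        even when a minimizer start arrives pinned near a bound.
        Finite-difference Jacobian, damped steps, trust-region
        least-squares fallback near the plait point.
        """
        from scipy.special import expit, logit

        V_MAX = 34.0  # |v| bound: allocation fractions within ~1e-15 of 0/1

        def F(v: np.ndarray) -> np.ndarray:
            n2v = z * expit(v)
            n1v = z - n2v
            mu1, eta_cache["L1"] = self._chemical_potentials(
                T, n1v / n1v.sum(), eta_cache["L1"]
            )
            mu2, eta_cache["L2"] = self._chemical_potentials(
                T, n2v / n2v.sum(), eta_cache["L2"]
            )
            return mu2 - mu1

        def active_set(v: np.ndarray, f: np.ndarray) -> np.ndarray:
            # a component pinned at a bound with an outward-pushing
            # residual is effectively absent from one phase: its
            # equation has no solution in representable arithmetic and
            # is dropped from the Newton system
            pinned = ((v <= -V_MAX + 1e-6) & (f > 0.0)) | (
                (v >= V_MAX - 1e-6) & (f < 0.0)
            )
            return ~pinned

        v = logit(np.clip(n2 / z, 1e-14, 1.0 - 1e-14))
        v = np.clip(v, -V_MAX, V_MAX)
        f0 = F(v)
        n_eval = 1
        free = active_set(v, f0)
        for _ in range(60):
            free = active_set(v, f0)
            if not np.any(free):
                break
            norm0 = float(np.max(np.abs(f0[free])))
            if norm0 < 1e-10:
                break
            idx = np.where(free)[0]
            J = np.empty((len(idx), len(idx)))
            for col, j in enumerate(idx):
                pert = v.copy()
                dh = 1e-4
                pert[j] = pert[j] - dh if pert[j] + dh > V_MAX else pert[j] + dh
                J[:, col] = (F(pert) - f0)[idx] / (pert[j] - v[j])
                n_eval += 1
            if not np.all(np.isfinite(J)):
                break
            try:
                step_free = np.linalg.solve(J, -f0[idx])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step_free)):
                break
            step = np.zeros_like(v)
            step[idx] = step_free
            lam = 1.0
            improved = False
            for _ in range(12):
                cand = np.clip(v + lam * step, -V_MAX, V_MAX)
                f_cand = F(cand)
                n_eval += 1
                if float(np.max(np.abs(f_cand[idx]))) < norm0:
                    v, f0 = cand, f_cand
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                break
        free = active_set(v, f0)
        if np.any(free) and float(np.max(np.abs(f0[free]))) > 1e-8:
            # near-plait tie lines have an almost singular Jacobian;
            # a trust-region least-squares pass handles those
            from scipy.optimize import least_squares

            idx = np.where(free)[0]

            def F_free(vf: np.ndarray) -> np.ndarray:
                vv = v.copy()
                vv[idx] = vf
                return F(vv)[idx]

            sol = least_squares(
                F_free, v[idx], bounds=(-V_MAX, V_MAX),
                xtol=3e-16, ftol=3e-16, gtol=3e-16,
                max_nfev=150, diff_step=1e-5,
            )
            n_eval += sol.nfev
            if float(np.max(np.abs(sol.fun))) < float(np.max(np.abs(f0[idx]))):
                v[idx] = sol.x
        return z * expit(v), n_eval

    def lle_flash(
        self,
        T: float,
        overall,
        use_stability: bool = True,
        init_split: np.ndarray | None = None,
        single_start: bool = False,
    ) -> TwoPhaseResult:
        """Isoactivity flash of an overall composition.

        ``overall`` may be a :class:`TernaryComposition` or a
        mass-fraction vector.  Starting allocations come from a fixed
        corner-biased list (or ``init_split``, the per-component
        fraction sent to the drug-rich phase — used for continuation
        along a hydration pathway); if all fail and ``use_stability`` is
        set, tangent-plane trial phases are used.  A converged split
        closer than 1e-3 (mass-fraction ∞-norm) to the trivial solution
        is rejected.
        """
        if not isinstance(overall, TernaryComposition):
            overall = self.composition_from_mass(np.asarray(overall, dtype=float))
        z = overall.x

        # fixed corner-biased starting allocations: fraction of each
        # component sent to the drug-rich phase L2 (drug, polymer, water)
        splits = [
            (0.90, 0.10, 0.20),
            (0.99, 0.02, 0.05),
            (0.60, 0.30, 0.40),
            (0.50, 0.005, 0.01),   # thin drug-rich phase (low drug loads)
        ]
        inits: list[np.ndarray] = []
        if init_split is not None:
            inits.append(np.clip(np.asarray(init_split, dtype=float), 1e-10, 1 - 1e-10))
        if not (single_start and inits):
            for sd, sp, sw in splits:
                s = np.zeros(3)
                s[self.i_drug], s[self.i_poly], s[self.i_water] = sd, sp, sw
                inits.append(s)

        best: TwoPhaseResult | None = None
        best_resid = np.inf

        def consider(attempt):
            nonlocal best, best_resid
            if attempt is None or not self._nontrivial(attempt, self.M):
                return None
            result = self._build_result(T, overall, attempt[0], attempt[1], attempt[3])
            r = float(result.tie.isoactivity_residual.max())
            if r < best_resid:
                best, best_resid = result, r
            return result if r < 1e-8 else None

        for s0 in inits:
            hit = consider(self._gibbs_flash(T, z, s0))
            if hit is not None:
                return hit
        if best is None and use_stability:
            stab = self.stability_test(T, overall.w)
            if stab.stable:
                return TwoPhaseResult(overall=overall, stable=True)
            # allocate each component toward the unstable trial direction
            y = stab.trial.x
            s0 = np.clip(0.5 * y / np.clip(z, 1e-30, None), 0.02, 0.98)
            hit = consider(self._gibbs_flash(T, z, s0))
            if hit is not None:
                return hit
        if best is not None and best_resid < 1e-6:
            # near-plait results legitimately stall above the tight gate
            return best
        return TwoPhaseResult(overall=overall, stable=True)

    def flash_from_allocation(
        self, T: float, overall, split: np.ndarray
    ) -> TwoPhaseResult:
        """Corrector flash: Newton on isoactivity from a known allocation.

        ``split`` is the per-component fraction of the overall moles in
        the drug-rich phase (a predictor from a neighbouring converged
        tie line).  No Gibbs minimization is run — this is the corrector
        step of a continuation along a composition path, robust where a
        cold flash is ill-conditioned.
        """
        if not isinstance(overall, TernaryComposition):
            overall = self.composition_from_mass(np.asarray(overall, dtype=float))
        z = overall.x
        n2 = z * np.clip(np.asarray(split, dtype=float), 1e-12, 1.0 - 1e-12)
        eta_cache = {"L1": None, "L2": None}
        n2, n_eval = self._newton_polish(T, z, n2, eta_cache)
        beta = float(n2.sum())
        if not (1e-9 < beta < 1.0 - 1e-9):
            return TwoPhaseResult(overall=overall, stable=True)
        n1 = z - n2
        attempt = (n1 / n1.sum(), n2 / beta, beta, n_eval)
        if not self._nontrivial(attempt, self.M):
            return TwoPhaseResult(overall=overall, stable=True)
        return self._build_result(T, overall, attempt[0], attempt[1], n_eval)

    def _build_result(
        self, T: float, overall: TernaryComposition, x1, x2, it: int
    ) -> TwoPhaseResult:
        c1 = self.composition_from_mole(x1)
        c2 = self.composition_from_mole(x2)
        # label: L1 = polymer-rich (higher polymer mass fraction)
        if c2.w[self.i_poly] > c1.w[self.i_poly]:
            c1, c2 = c2, c1
        # lever rule from overall mass balance on the widest component
        dw = c2.w - c1.w
        j = int(np.argmax(np.abs(dw)))
        frac_L2 = float((overall.w[j] - c1.w[j]) / dw[j])
        frac_L2 = min(max(frac_L2, 0.0), 1.0)
        frac_L1 = 1.0 - frac_L2

        gam1 = self.model.gamma(T, self.P, c1.x)
        gam2 = self.model.gamma(T, self.P, c2.x)
        resid = np.abs(c1.x * gam1 - c2.x * gam2)
        tie = TieLine(phase_L1=c1, phase_L2=c2, isoactivity_residual=resid)
        logger.info(
            "flash converged in %d evaluations; tie length %.4f; residual %.2e",
            it, tie.length, float(resid.max()),
        )
        return TwoPhaseResult(
            overall=overall, stable=False, tie=tie,
            frac_L1=frac_L1, frac_L2=frac_L2, iterations=it,
        )

    @staticmethod
    def _nontrivial(attempt, M) -> bool:
        x1, x2, beta, _ = attempt
        w1 = mole_to_mass(x1, M)
        w2 = mole_to_mass(x2, M)
        return bool(np.max(np.abs(w1 - w2)) > 1e-3)

    # -- binodal / spinodal ---------------------------------------------

    def binodal_trace(
        self,
        T: float,
        start_mass: np.ndarray | None = None,
        polymer_step: float = 0.02,
        max_ties: int = 60,
        min_tie_length: float = 1e-3,
    ) -> list[TieLine]:
        """Continuation of the binodal from the drug/water edge.

        Starts from the widest-gap tie line near the drug/water binary
        and steps the overall composition toward the polymer apex along
        tie-line midpoints; stops at plait-point proximity (tie length
        below ``min_tie_length``), a stable flash, or the step floor.
        """
        if start_mass is None:
            start_mass = np.zeros(3)
            start_mass[self.i_drug] = 0.44
            start_mass[self.i_poly] = 0.02
            start_mass[self.i_water] = 0.54
        ties: list[TieLine] = []
        overall = np.asarray(start_mass, dtype=float)
        step = polymer_step
        while len(ties) < max_ties:
            res = self.lle_flash(T, overall, use_stability=False)
            if res.stable or res.tie is None:
                if step > 1e-5 and ties:
                    step *= 0.5
                    mid = 0.5 * (ties[-1].phase_L1.w + ties[-1].phase_L2.w)
                    overall = self._step_toward_polymer(mid, step)
                    continue
                logger.warning("binodal continuation stalled after %d ties", len(ties))
                break
            tie = res.tie
            if tie.length < min_tie_length:
                break
            ties.append(tie)
            mid = 0.5 * (tie.phase_L1.w + tie.phase_L2.w)
            overall = self._step_toward_polymer(mid, step)
            if overall[self.i_poly] > 0.97:
                break
        return ties

    def _step_toward_polymer(self, w: np.ndarray, step: float) -> np.ndarray:
        apex = np.zeros(3)
        apex[self.i_poly] = 1.0
        out = w + step * (apex - w)
        out = np.clip(out, 0.0, 1.0)
        return out / out.sum()

    # -- spinodal -------------------------------------------------------

    def gibbs_mix_unreferenced(self, T: float, x: np.ndarray) -> float:
        """sum x_i (ln x_i + ln phi_i): the molar mixing Gibbs energy up
        to a term linear in composition (pure-liquid references drop out
        of second derivatives)."""
        lnphi = self.model.lnphi(T, self.P, x)
        xx = np.clip(x, 1e-300, None)
        return float(np.sum(x * (np.log(xx) + lnphi)))

    def gibbs_hessian_det(self, T: float, x: np.ndarray, h: float = 1e-4) -> float:
        """Determinant of the Gibbs-energy Hessian in (x_drug, x_poly).

        Negative inside the spinodal (locally unstable), positive in
        locally stable regions; its zero locus is the spinodal.
        """
        idx = (self.i_drug, self.i_poly)

        def q(dd: float, dp: float) -> float:
            xv = x.copy()
            xv[idx[0]] += dd
            xv[idx[1]] += dp
            xv[self.i_water] -= dd + dp
            return self.gibbs_mix_unreferenced(T, xv)

        q0 = q(0.0, 0.0)
        h11 = (q(h, 0) - 2 * q0 + q(-h, 0)) / h**2
        h22 = (q(0, h) - 2 * q0 + q(0, -h)) / h**2
        h12 = (q(h, h) - q(h, -h) - q(-h, h) + q(-h, -h)) / (4 * h**2)
        return h11 * h22 - h12**2

    def spinodal_trace(
        self, T: float, n_rays: int = 9, drug_frac_range=(0.35, 0.995)
    ) -> list[np.ndarray]:
        """Locus where the Gibbs Hessian determinant vanishes.

        Traced along rays of fixed drug:(drug+polymer) mass ratio by
        bisection on the water coordinate; rays without a sign change
        are skipped with a warning.  Returns mass-fraction rows ordered
        by dry drug fraction.
        """
        rows: list[np.ndarray] = []
        for fd in np.linspace(*drug_frac_range, n_rays):
            scan = np.linspace(0.05, 0.95, 19)
            vals = []
            for ww in scan:
                try:
                    vals.append(
                        self.gibbs_hessian_det(T, mass_to_mole(self._ray_mass(fd, ww), self.M))
                    )
                except RuntimeError:
                    vals.append(np.nan)
            found = False
            for k in range(len(scan) - 1):
                a, b = vals[k], vals[k + 1]
                if np.isnan(a) or np.isnan(b) or not (a > 0.0 >= b or a <= 0.0 < b):
                    continue
                lo, hi, fa = scan[k], scan[k + 1], a
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    fm = self.gibbs_hessian_det(
                        T, mass_to_mole(self._ray_mass(fd, mid), self.M)
                    )
                    if (fa > 0) == (fm > 0):
                        lo, fa = mid, fm
                    else:
                        hi = mid
                    if hi - lo < 1e-6:
                        break
                rows.append(self._ray_mass(fd, 0.5 * (lo + hi)))
                found = True
                break
            if not found:
                logger.warning("no spinodal bracket on ray drug-fraction %.3f", fd)
        return rows

    def _ray_mass(self, dry_drug_frac: float, w_water: float) -> np.ndarray:
        w = np.zeros(3)
        w[self.i_water] = w_water
        w[self.i_drug] = (1.0 - w_water) * dry_drug_frac
        w[self.i_poly] = (1.0 - w_water) * (1.0 - dry_drug_frac)
        return w
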