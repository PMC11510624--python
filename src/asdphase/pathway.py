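"""Hydration-pathway analysis and release-mechanism classification.

During dissolution the surface of a dry amorphous solid dispersion
(ASD) absorbs water at a fixed drug:polymer ratio — a straight
"hydration pathway" from the dry composition toward the water apex of
the ternary diagram.  Water plasticizes the gel layer until its Kwei
glass-transition temperature falls to the dissolution-medium
temperature; that crossing is the escape glass transition (eGT), the
point where the gel becomes fluid enough to release material.

If the pathway has already crossed the liquid–liquid binodal at eGT,
the interfacial layer demixes into a polymer-rich phase (L1) and a
hydrophobic drug-rich phase (L2).  The lever rule gives their relative
amounts, and the phase that dominates controls the release mechanism:

* ``bulk_LLPS``                — the binodal is crossed only above eGT;
                                 demixing happens out in the bulk medium
                                 and the interface releases freely.
* ``polymer_controlled_release`` — L2 is the minor phase; the
                                 hydrophilic polymer-rich phase controls
                                 the interface.
* ``drug_barrier_LoR``         — L2 is the major phase; a hydrophobic
                                 amorphous drug barrier passivates the
                                 interface (Type II loss of release).

Near the plait point the drug-rich phase shrinks to nothing and a cold
flash becomes ill-conditioned; the analyzer therefore seeds eGT flashes
by continuation from a slightly wetter composition where the split is
wide, walking back down the pathway.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import ParameterSet, default_parameter_set
from .equilibria import EquilibriumSolver, TernaryComposition, TwoPhaseResult
from .glass import GlassModel

__all__ = ["HydrationPathway", "ReleaseReport", "PathwayAnalyzer"]

logger = logging.getLogger(__name__)

BULK_LLPS = "bulk_LLPS"
POLYMER_CONTROLLED = "polymer_controlled_release"
DRUG_BARRIER = "drug_barrier_LoR"


@dataclass(frozen=True)
class HydrationPathway:
    """Straight dilution line from a dry ASD toward the water apex.

    The drug:polymer mass ratio DL/(1-DL) is constant along the path;
    the path parameter is the water mass fraction.
    """

    DL: float                     # drug mass fraction in the dry ASD
    names: tuple[str, ...]
    i_drug: int
    i_poly: int
    i_water: int

    def __post_init__(self) -> None:
        if not 0.0 < self.DL < 1.0:
            raise ValueError("drug load must lie strictly between 0 and 1")

    def composition(self, w_water: float) -> np.ndarray:
        """Mass fractions at the given water content (registry order)."""
        if not 0.0 <= w_water < 1.0:
            raise ValueError("water mass fraction must lie in [0, 1)")
        w = np.zeros(len(self.names))
        w[self.i_water] = w_water
        w[self.i_drug] = (1.0 - w_water) * self.DL
        w[self.i_poly] = (1.0 - w_water) * (1.0 - self.DL)
        return w

    def points(self, n: int = 50, w_water_max: float = 0.99) -> np.ndarray:
        """Sampled compositions with strictly increasing water content."""
        return np.array([self.composition(t) for t in np.linspace(0.0, w_water_max, n)])


@dataclass(frozen=True)
class ReleaseReport:
    """Per-drug-load record of the LLPS analysis at the eGT point."""

    DL: float
    egt_composition: TernaryComposition
    flash: TwoPhaseResult
    classification: str
    tg_L1: float | None = None          # °C, polymer-rich phase
    tg_L2: float | None = None          # °C, drug-rich phase
    binodal_crossing_water: float | None = None

    @property
    def split(self) -> bool:
        return not self.flash.stable

    @property
    def major_phase(self) -> str:
        if not self.split:
            return "polymer_rich"
        return "drug_rich" if self.flash.frac_L2 > 0.5 else "polymer_rich"

    def to_dict(self) -> dict:
        names = self.egt_composition.names
        d: dict = {
            "DL": float(self.DL),
            "classification": self.classification,
            "major_phase": self.major_phase,
            "egt_composition": {n: float(self.egt_composition.w_of(n)) for n in names},
            "binodal_crossing_water": (
                None
                if self.binodal_crossing_water is None
                else float(self.binodal_crossing_water)
            ),
        }
        if self.split:
            t = self.flash.tie
            d.update(
                frac_polymer_rich=float(self.flash.frac_L1),
                frac_drug_rich=float(self.flash.frac_L2),
                phase_polymer_rich={n: float(t.phase_L1.w_of(n)) for n in names},
                phase_drug_rich={n: float(t.phase_L2.w_of(n)) for n in names},
                tg_polymer_rich_C=float(self.tg_L1),
                tg_drug_rich_C=float(self.tg_L2),
            )
        return d


class PathwayAnalyzer:
    """Ties glass-transition and LLE modeling into the release analysis.

    Parameters
    ----------
    params : ParameterSet, optional
        Component registry; defaults to the built-in
        ritonavir/PVPVA64/water set.
    T_medium : float
        Dissolution-medium temperature in K (default 310.15 K, 37 °C).
    P : float
        Pressure in Pa for the PC-SAFT liquid states.
    """

    #: flash acceptance thresholds on the isoactivity residual:
    #: direct flashes must be tight; continuation results near the plait
    #: point are accepted at a looser level (flat Gibbs surface).
    RESID_DIRECT = 1e-6
    RESID_CONTINUATION = 1e-4

    def __init__(
        self,
        params: ParameterSet | None = None,
        T_medium: float = 310.15,
        P: float = 1.013e5,
    ) -> None:
        self.params = params if params is not None else default_parameter_set()
        self.T = T_medium
        self.eq = EquilibriumSolver(self.params, P=P)
        self.glass = GlassModel(self.params, polymer=self.eq.polymer)

    # -- geometry -------------------------------------------------------

    def hydration_pathway(self, DL: float) -> HydrationPathway:
        return HydrationPathway(
            DL=DL,
            names=self.eq.names,
            i_drug=self.eq.i_drug,
            i_poly=self.eq.i_poly,
            i_water=self.eq.i_water,
        )

    def egt_water(self, DL: float) -> float:
        """Water mass fraction of the eGT point on the DL pathway."""
        return self.glass.water_at_tg(DL / (1.0 - DL), self.T)

    def egt_point(self, DL: float) -> TernaryComposition:
        """Composition on the pathway where the Kwei Tg equals T_medium."""
        path = self.hydration_pathway(DL)
        w = path.composition(self.egt_water(DL))
        return self.eq.composition_from_mass(w / w.sum())

    # -- flash with pathway continuation --------------------------------

    def _flash_converged(self, res: TwoPhaseResult, tol: float) -> bool:
        return (
            not res.stable
            and res.tie is not None
            and float(res.tie.isoactivity_residual.max()) < tol
        )

    def _allocation_split(self, res: TwoPhaseResult) -> np.ndarray:
        """Per-component fraction allocated to the drug-rich phase."""
        t = res.tie
        M1 = float(t.phase_L1.x @ self.eq.M)
        M2 = float(t.phase_L2.x @ self.eq.M)
        b2 = res.frac_L2 / M2
        beta = b2 / (b2 + res.frac_L1 / M1)  # mole fraction of L2
        n2 = beta * t.phase_L2.x
        n1 = (1.0 - beta) * t.phase_L1.x
        return np.clip(n2 / (n1 + n2), 1e-12, 1.0 - 1e-12)

    def flash_on_pathway(self, DL: float, w_water: float) -> TwoPhaseResult:
        """Flash a pathway composition, with continuation fallback.

        A direct flash is accepted when its isoactivity residual is
        tight.  Otherwise the flash is re-seeded by walking down from
        wetter pathway points where the two-phase split is wide — the
        reliable way to resolve a vanishing drug-rich phase just inside
        the binodal.
        """
        path = self.hydration_pathway(DL)
        overall = path.composition(w_water)
        res = self.eq.lle_flash(self.T, overall, use_stability=False)
        if self._flash_converged(res, self.RESID_DIRECT):
            return res
        # continuation ladder from wetter compositions
        for dw in (0.02, 0.05, 0.10):
            ww_hi = w_water + dw
            if ww_hi >= 0.99:
                break
            seed_res = self.eq.lle_flash(
                self.T, path.composition(ww_hi), use_stability=False
            )
            if not self._flash_converged(seed_res, self.RESID_DIRECT):
                continue
            steps = np.linspace(ww_hi, w_water, 5)[1:]
            cur = seed_res
            ok = True
            for ww in steps:
                cur = self.eq.flash_from_allocation(
                    self.T, path.composition(ww), self._allocation_split(cur)
                )
                if cur.stable:
                    ok = False
                    break
            if ok and self._flash_converged(cur, self.RESID_CONTINUATION):
                logger.info(
                    "continuation flash at DL=%.2f, w_water=%.4f (seed %.4f)",
                    DL, w_water, ww_hi,
                )
                return cur
            if not ok:
                # continuation collapsed walking down: the point lies
                # outside the binodal; an unconverged direct "split"
                # is a flat-valley artifact and is discarded
                return TwoPhaseResult(overall=overall, stable=True)
        return TwoPhaseResult(overall=overall, stable=True)

    def binodal_crossing_water(
        self, DL: float, w_lo: float | None = None, w_hi: float = 0.6, tol: float = 2e-3
    ) -> float | None:
        """Water content where the DL pathway enters the two-phase region.

        Bisection on the pathway between ``w_lo`` (default: the eGT
        water content) and ``w_hi``; returns None when no split exists
        anywhere on the scanned stretch.
        """
        if w_lo is None:
            w_lo = self.egt_water(DL)
        path = self.hydration_pathway(DL)

        def flash_at(ww: float, seed) -> TwoPhaseResult:
            if seed is not None:
                return self.eq.flash_from_allocation(
                    self.T, path.composition(ww), self._allocation_split(seed)
                )
            return self.eq.lle_flash(self.T, path.composition(ww), use_stability=False)

        res_lo = self.flash_on_pathway(DL, w_lo)
        if self._flash_converged(res_lo, self.RESID_CONTINUATION):
            return w_lo  # already inside at the lower end
        res_hi = flash_at(w_hi, None)
        if not self._flash_converged(res_hi, self.RESID_DIRECT):
            found = None
            for ww in np.linspace(w_lo, w_hi, 13)[1:]:
                r = flash_at(ww, None)
                if self._flash_converged(r, self.RESID_DIRECT):
                    found = (ww, r)
                    break
            if found is None:
                return None
            w_hi, res_hi = found
        lo, hi = w_lo, w_hi
        seed = res_hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            r = flash_at(mid, seed)
            if self._flash_converged(r, self.RESID_CONTINUATION):
                hi, seed = mid, r
            else:
                lo = mid
        return hi

    # -- release classification ----------------------------------------

    def llps_at_egt(self, DL: float) -> ReleaseReport:
        """Flash the eGT composition and classify the release mechanism."""
        egt = self.egt_point(DL)
        ww_egt = egt.w_of(self.eq.water)
        res = self.flash_on_pathway(DL, ww_egt)
        if res.stable or res.tie is None:
            crossing = self.binodal_crossing_water(DL)
            return ReleaseReport(
                DL=DL,
                egt_composition=egt,
                flash=res,
                classification=BULK_LLPS,
                binodal_crossing_water=crossing,
            )
        tg1 = self.glass.tg_celsius(res.tie.phase_L1.w)
        tg2 = self.glass.tg_celsius(res.tie.phase_L2.w)
        cls = DRUG_BARRIER if res.frac_L2 > 0.5 else POLYMER_CONTROLLED
        return ReleaseReport(
            DL=DL,
            egt_composition=egt,
            flash=res,
            classification=cls,
            tg_L1=tg1,
            tg_L2=tg2,
            binodal_crossing_water=ww_egt,
        )

    # -- reporting ------------------------------------------------------

    def table_report(
        self, DLs=(0.05, 0.15, 0.20, 0.40)
    ) -> tuple[pd.DataFrame, list[ReleaseReport]]:
        """Phase-split summary for a list of drug loads.

        Returns a tidy DataFrame (one row per phase per splitting DL,
        full precision) plus the underlying reports.  Drug loads whose
        pathways demix only above eGT produce a report but no table
        rows.
        """
        reports = [self.llps_at_egt(DL) for DL in DLs]
        rows = []
        for rep in reports:
            if not rep.split:
                continue
            t = rep.flash.tie
            for phase, comp, frac, tg in (
                ("polymer-rich", t.phase_L1, rep.flash.frac_L1, rep.tg_L1),
                ("drug-rich", t.phase_L2, rep.flash.frac_L2, rep.tg_L2),
            ):
                rows.append(
                    {
                        "DL": rep.DL,
                        "phase": phase,
                        "phase_mass_fraction": frac,
                        "w_water": comp.w_of(self.eq.water),
                        "w_drug": comp.w_of(self.eq.drug),
                        "w_polymer": comp.w_of(self.eq.polymer),
                        "Tg_C": tg,
                        "classification": rep.classification,
                    }
                )
        return pd.DataFrame(rows), reports

    @staticmethod
    def render_table(df: pd.DataFrame) -> str:
        """Two-decimal display rendering of the phase-split table."""
        show = df.copy()
        for c in ("phase_mass_fraction", "w_water", "w_drug", "w_polymer", "Tg_C"):
            show[c] = show[c].map(lambda v: f"{v:.2f}")
        return show.to_string(index=False)

    @staticmethod
    def reports_to_json(reports: list[ReleaseReport]) -> str:
        return json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True)
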