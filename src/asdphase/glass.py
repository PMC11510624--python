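"""Glass-transition modeling of drug/polymer/water mixtures.

The mixture glass-transition temperature follows the Kwei equation

    Tg(w) = sum_i K_i w_i Tg_i / sum_i K_i w_i  +  sum_{i<j} w_i w_j q_ij

with mass fractions w, pure-component glass transitions Tg_i, pairwise
interaction parameters q_ij (K), and Gordon–Taylor-type weights K_i
estimated from the Simha–Boyer rule relative to the polymer:

    K_i = (rho_polymer Tg_polymer) / (rho_i Tg_i)

The pair sum runs over unordered pairs (each pair counted once).  The
water q terms dominate the plasticization behaviour: water both pulls
the ideal-mixing term down (low Tg_water, large K_water) and shifts it
through q_drug,water < 0.

Temperatures are kept in kelvin internally; reporting layers convert
to °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .components import ParameterSet

__all__ = ["KweiParameters", "GlassModel"]


@dataclass(frozen=True)
class KweiParameters:
    """Simha–Boyer weights K_i and pairwise q_ij (K) for a component ordering."""

    K: np.ndarray        # per component, polymer entry is exactly 1
    q: np.ndarray        # symmetric pair matrix, K

    def __post_init__(self) -> None:
        if np.any(self.K <= 0.0):
            raise ValueError("Simha–Boyer K_i must be positive")


def simha_boyer_K(rho_i: float, Tg_i: float, rho_ref: float, Tg_ref: float) -> float:
    """K_i = (rho_ref Tg_ref)/(rho_i Tg_i) with the polymer as reference."""
    if rho_i <= 0.0 or Tg_i <= 0.0 or rho_ref <= 0.0 or Tg_ref <= 0.0:
        raise ValueError("densities and glass-transition temperatures must be positive")
    return (rho_ref * Tg_ref) / (rho_i * Tg_i)


class GlassModel:
    """Kwei glass-transition model bound to a component registry.

    Parameters
    ----------
    params : ParameterSet
        Registry with densities, Tg and q_ij values.
    names : sequence of str, optional
        Component ordering for mass-fraction vectors (default: registry order).
    polymer : str, optional
        Reference component of the Simha–Boyer rule; defaults to the
        component with the largest molar mass.
    """

    def __init__(self, params: ParameterSet, names=None, polymer: str | None = None) -> None:
        self.params = params
        self.names = tuple(names) if names is not None else params.names
        comps = [params[n] for n in self.names]
        if polymer is None:
            polymer = max(comps, key=lambda c: c.M).name
        self.polymer = polymer
        ref = params[polymer]
        self.Tg = np.array([c.Tg for c in comps])
        K = np.array(
            [simha_boyer_K(c.rho, c.Tg, ref.rho, ref.Tg) for c in comps]
        )
        n = len(comps)
        q = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    q[i, j] = q[j, i] = params.binary(self.names[i], self.names[j]).q
                except KeyError:
                    pass
        self.kwei = KweiParameters(K=K, q=q)

    def tg(self, w, pair_convention: str = "unordered") -> float:
        """Mixture glass-transition temperature in K for mass fractions w.

        ``pair_convention`` selects whether the q sum counts each pair
        once ("unordered", the default) or twice ("ordered"); the
        ordered variant exists only for the convention regression test.
        """
        w = np.asarray(w, dtype=float)
        if abs(float(w.sum()) - 1.0) > 1e-9 or np.any(w < -1e-12):
            raise ValueError("mass fractions must be non-negative and sum to 1")
        Kw = self.kwei.K * w
        base = float(Kw @ self.Tg) / float(Kw.sum())
        pair = 0.5 * float(w @ self.kwei.q @ w)  # q has zero diagonal
        if pair_convention == "ordered":
            pair *= 2.0
        elif pair_convention != "unordered":
            raise ValueError("pair_convention must be 'unordered' or 'ordered'")
        return base + pair

    def tg_celsius(self, w, **kw) -> float:
        return self.tg(w, **kw) - 273.15

    def water_at_tg(
        self,
        drug_polymer_ratio: float,
        T_target: float,
        w_max: float = 1.0 - 1e-9,
    ) -> float:
        """Water mass fraction where Tg of a hydrated mixture hits T_target.

        The dry drug:polymer ratio is held fixed while water is added;
        the first crossing from above is located by bisection to 1e-12.
        Raises ``ValueError`` when the dry mixture is already below the
        target (no glassy barrier to cross).
        """
        r = drug_polymer_ratio

        def comp(w_water: float) -> np.ndarray:
            dry = 1.0 - w_water
            w = np.zeros(len(self.names))
            w[self.names.index("water") if "water" in self.names else -1] = w_water
            # remaining components keep the dry ratio drug:(polymer)
            drug_idx, poly_idx = self._drug_poly_indices()
            w[drug_idx] = dry * r / (1.0 + r)
            w[poly_idx] = dry / (1.0 + r)
            return w

        f = lambda ww: self.tg(comp(ww)) - T_target
        if f(0.0) <= 0.0:
            raise ValueError("dry-mixture Tg is already at or below the target temperature")
        lo, hi = 0.0, w_max
        if f(hi) > 0.0:
            # scan for a sign change before giving up
            grid = np.linspace(0.0, w_max, 200)
            vals = [f(g) for g in grid]
            for k in range(len(grid) - 1):
                if vals[k] > 0.0 >= vals[k + 1]:
                    lo, hi = grid[k], grid[k + 1]
                    break
            else:
                raise ValueError("no Tg crossing on this hydration ray")
        while hi - lo > 1e-12:
            mid = 0.5 * (lo + hi)
            if f(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def _drug_poly_indices(self) -> tuple[int, int]:
        poly_idx = self.names.index(self.polymer)
        others = [k for k, n in enumerate(self.names) if n != self.polymer and n != "water"]
        if len(others) != 1:
            raise ValueError("expected exactly one drug component")
        return others[0], poly_idx

    def glass_contour(self, T_target: float, n_rays: int = 41) -> np.ndarray:
        """Composition curve where the mixture Tg equals ``T_target``.

        Returns an array of mass-fraction rows ordered by the drug
        fraction of the dry basis, one point per drug:polymer ray
        (rays with no crossing are omitted).
        """
        Tg_min, Tg_max = float(self.Tg.min()), float(self.Tg.max())
        if not (Tg_min <= T_target <= Tg_max):
            raise ValueError("target temperature outside the pure-component Tg range")
        drug_idx, poly_idx = self._drug_poly_indices()
        water_idx = self.names.index("water")
        rows = []
        for fd in np.linspace(0.0, 1.0, n_rays):
            r = fd / (1.0 - fd) if fd < 1.0 else math.inf
            try:
                if math.isinf(r):
                    # pure-drug ray: degenerate ratio handled directly
                    ww = self._water_at_tg_pure_drug(T_target, drug_idx, water_idx)
                else:
                    ww = self.water_at_tg(r, T_target)
            except ValueError:
                continue
            w = np.zeros(len(self.names))
            w[water_idx] = ww
            w[drug_idx] = (1.0 - ww) * fd
            w[poly_idx] = (1.0 - ww) * (1.0 - fd)
            rows.append(w)
        return np.array(rows)

    def _water_at_tg_pure_drug(self, T_target, drug_idx, water_idx) -> float:
        def f(ww):
            w = np.zeros(len(self.names))
            w[water_idx] = ww
            w[drug_idx] = 1.0 - ww
            return self.tg(w) - T_target

        if f(0.0) <= 0.0:
            raise ValueError("dry-drug Tg already below target")
        lo, hi = 0.0, 1.0 - 1e-9
        if f(hi) > 0.0:
            raise ValueError("no Tg crossing on the drug/water edge")
        while hi - lo > 1e-12:
            mid = 0.5 * (lo + hi)
            if f(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)
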