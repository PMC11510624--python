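# asdphase

Thermodynamic modeling of amorphous-solid-dispersion (ASD) dissolution:
PC-SAFT phase equilibria and Kwei glass-transition analysis for
drug/polymer/water ternaries, with the ritonavir/PVPVA64/water system
built in.

## The problem

Amorphous solid dispersions release a poorly soluble drug from an
amorphous polymer matrix. As water penetrates the tablet surface, the
hydrated gel layer can undergo liquid–liquid phase separation (LLPS)
into a hydrophilic polymer-rich phase and a hydrophobic drug-rich
phase. Whether the drug-rich phase is the minor or the major product of
that demixing decides the release mechanism: at high drug loads it
forms an amorphous barrier that passivates the interface — the
drug-load-dependent **loss of release** (Type II LoR) that formulators
need to predict *before* making the tablet.

`asdphase` predicts this from pure-component and binary parameters
alone. It is written for formulation scientists and thermodynamic
modelers who want the full chain — equation of state, phase equilibria,
glass transitions, release classification — as an inspectable Python
library with a CLI.

## The model

* **PC-SAFT** residual Helmholtz energy
  `a_res = a_hc + a_disp + a_assoc` (hard chain, dispersion,
  association), with Lorentz–Berthelot combining rules,
  `k_ij(T) = k_ij,m·T + k_ij,b`, and Wolbach–Sandler cross-association
  rules. Activity coefficients use the pure-liquid reference,
  `γ_i = φ_i(T, P, x) / φ_i(T, P, pure)`.
* **Solid–liquid equilibrium** (crystalline drug solubility):
  `x_d = (1/γ_d) · exp[−Δh_SL/RT·(1 − T/T_SL) − Δcp_SL/R·(ln(T_SL/T) − T_SL/T + 1)]`.
* **Liquid–liquid equilibrium**: isoactivity
  `x_i^L1 γ_i^L1 = x_i^L2 γ_i^L2` for every component, solved as a
  bounded two-phase Gibbs minimization with a Newton corrector, plus
  lever-rule phase amounts.
* **Glass transition** (Kwei):
  `Tg = Σ K_i w_i Tg_i / Σ K_i w_i + Σ_{i<j} w_i w_j q_ij`, with
  Simha–Boyer weights `K_i = ρ_p Tg_p / (ρ_i Tg_i)`.
* **Hydration pathway analysis**: on the line from the dry ASD toward
  the water apex, find the *escape glass transition* (eGT) where
  `Tg = T_medium` (37 °C), flash that composition, and classify the
  release mechanism (`bulk_LLPS`, `polymer_controlled_release`, or
  `drug_barrier_LoR`).

## Worked example

```python
from asdphase import PathwayAnalyzer

analyzer = PathwayAnalyzer()           # ritonavir/PVPVA64/water, 37 °C
df, reports = analyzer.table_report((0.15, 0.20, 0.40))
print(analyzer.render_table(df))
```

```
  DL        phase phase_mass_fraction w_water w_drug w_polymer  Tg_C             classification
0.15 polymer-rich                0.60    0.13   0.03      0.84 32.28 polymer_controlled_release
0.15    drug-rich                0.40    0.05   0.29      0.66 49.67 polymer_controlled_release
0.20 polymer-rich                0.47    0.13   0.03      0.84 29.58           drug_barrier_LoR
0.20    drug-rich                0.53    0.05   0.32      0.63 49.11           drug_barrier_LoR
0.40 polymer-rich                0.17    0.16   0.01      0.82 17.34           drug_barrier_LoR
0.40    drug-rich                0.83    0.04   0.45      0.51 45.56           drug_barrier_LoR
```

Read: at 15 wt% drug load the drug-rich phase is minor (0.40) and the
polymer-rich phase controls release; from 20 wt% the drug-rich phase is
the major phase, and at 40 wt% it makes up 0.83 of the gel layer with
0.45 drug by mass — a hydrophobic barrier that shuts down release. The
`Tg_C` column is the Kwei glass transition of each phase; the
polymer-rich phase is plasticized far below 37 °C at high drug load
(17 °C) because it holds the most water.

The same analysis from the shell:

```bash
asdphase tg --w 0.1,0.2,0.7            # w_water, w_drug, w_polymer
asdphase flash --T 310.15 --w 0.0625,0.375,0.5625
asdphase report --config run.yaml
asdphase diagram --config run.yaml     # CSV curves for ternary plotting
```

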