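# Methods

## Scope and model chain

`asdphase` couples three models into one pipeline:

1. a PC-SAFT equation of state for the liquid (amorphous) mixture of a
   drug, a polymer, and water;
2. phase-equilibrium solvers on top of it (solid–liquid solubility,
   liquid–liquid flash with lever rule, binodal/spinodal tracing);
3. a Kwei glass-transition model with Simha–Boyer weights, which turns
   compositions into mobility statements (glassy vs. fluid).

The pipeline's deliverable is the hydration-pathway analysis: for a dry
ASD of drug load DL, water uptake at fixed drug:polymer ratio is traced
until the mixture's Tg falls to the dissolution-medium temperature (the
escape glass transition, eGT); the eGT composition is flashed, and the
lever-rule phase split classifies the release mechanism.

## PC-SAFT implementation

The residual Helmholtz energy per mole (units of RT) is
`a_res = a_hc + a_disp + a_assoc`:

* **Hard chain**: Boublík–Mansoori hard-sphere mixture term, chained
  with the pair contact value of the radial distribution function;
  temperature-dependent segment diameters
  `d_i = σ_i (1 − 0.12 exp(−3 u_i/T))`. Water's σ itself carries the
  two-exponential temperature rule from its parameter set.
* **Dispersion**: second-order perturbation with the universal model
  constants; the `I1`, `I2` power series in the packing fraction η and
  the `C1` compressibility correction.
* **Association**: donor/acceptor site classes per component, donors
  bonding only to acceptors. Site multiplicities enter as class counts
  with multiplicity N — mathematically identical to enumerating sites
  and the only viable option for a polymer carrying hundreds of them.
  Association strength
  `Δ_ij = σ_ij³ g_ij^hs κ_ij (exp(ε_ij/T) − 1)`; cross parameters from
  Wolbach–Sandler. A component with ε = 0 but κ > 0 (the copolymer) is
  inert alone and activates only through cross association — the
  standard "induced association" treatment. The drug's sites
  self-associate as well as cross-associate (the usual convention; no
  statement to the contrary exists for this parameter set).

**Site fractions** are solved by damped successive substitution
(damping 0.5, 30 sweeps) as a pre-conditioner, then Newton iterations
to a 1e−15 update tolerance, with a heavily damped substitution
fallback. The tight tolerance is not cosmetic: chemical potentials are
built from finite differences of `n·a_res`, and sloppy site fractions
would dominate the derivative noise.

**Compressibility factor / pressure** are analytic (closed-form hard
chain and dispersion derivatives; the association contribution by the
envelope theorem on the bonding functional, holding the converged site
fractions fixed). An early numeric-derivative version was the dominant
noise source of the whole pipeline: a liquid at 1 atm has Z ≈ 1e−3, so
the `−ln Z` term in `ln φ` amplifies any η error by 1/Z. A
finite-difference twin (`Z_numeric`) is kept for cross-checks.

**Density** is the packing-fraction root of `P(η) = P`, bracketed by
walking down from close packing (liquid branch = largest root) and
polished by Brent's method; a warm-start bracket is used inside flash
loops. The vapor branch scans the full η range and reports root
multiplicity and a minimum-Gibbs flag.

**Fugacity coefficients**: `ln φ_i = ∂(n a_res)/∂n_i |_{T,V} − ln Z`
with central differences in mole numbers at constant volume (step
`1e−4·max(x_i, 2e−3)`, a balance between truncation and roundoff in
the strongly curved small-fraction directions; one-sided second-order
at zero fractions). The scheme is gated by an exact Euler identity
test, `Σ x_i ln φ_i = a_res + (Z − 1) − ln Z`. Activity coefficients
use the pure-liquid reference at the same (T, P), so `γ_i → 1` at the
pure corners by construction.

**Reference pressure**: all equilibria run at 1.013e5 Pa and the
dissolution temperature 310.15 K. Liquid-phase activity coefficients
are insensitive to pressure at this level (liquid compressibilities are
tiny; doubling P moves ln γ by less than 1e−3), so the choice of
ambient pressure is immaterial to the phase diagram.

## Equilibria

**Solid–liquid (drug solubility)** is the standard melting-properties
expression solved as a damped fixed point in the saturation mole
fraction, with PC-SAFT supplying γ at the saturated composition
(tolerance 1e−10). The ideal-γ limit has a closed form used as an
exact oracle.

**Liquid–liquid flash.** The isoactivity conditions are solved as a
bounded two-phase Gibbs minimization: variables are logits of the
phase-2 allocation `n2_i = z_i·σ(t_i)`, the gradient is exactly the
chemical-potential difference, and L-BFGS-B runs from a fixed
corner-biased list of starting allocations (no randomness). A Newton
corrector on `μ^L2 − μ^L1 = 0` (finite-difference Jacobian, damped
steps, trust-region least-squares fallback near singular Jacobians)
then tightens the result to ~1e−9 isoactivity residual. The corrector
works in logit-allocation space, where the ln x singularity of a
nearly fully partitioned component cancels against its vanishing
allocation derivative; a component pinned at an allocation bound with
an outward-pushing residual (e.g. the polymer in a drug/water-edge
phase, where its equilibrium mole fraction is below representable
arithmetic) is treated as absent and its equation dropped from the
Newton system. A converged split closer than 1e−3 (mass-fraction
∞-norm) to the trivial identical-phase solution is rejected, and a
flash whose best residual exceeds 1e−6 is reported as single-phase
rather than returned half-converged. Direct successive substitution on
K-factors — the textbook flash loop — was tried first and diverges
violently here: the polymer's ln φ is O(1e3) and hyper-sensitive to
composition, so raw ln K updates overshoot into absurd compositions.
The Gibbs-minimization formulation cannot leave the simplex and is the
design of record.

**Stability** is Michelsen's tangent-plane test, iterated in log space
(again because |ln φ| is O(1e3) for the polymer) from a fixed
corner-biased trial list.

**Continuation on hydration pathways.** Just inside the binodal the
minor phase's amount vanishes and a cold flash is ill-conditioned. The
pathway analyzer therefore accepts a direct flash only when its
residual is tight (1e−6), and otherwise re-seeds by predictor–corrector
continuation from a wetter pathway point where the split is wide,
walking the allocation back down (corrector residual threshold 1e−4 to
admit the flat near-plait Gibbs surface). If the corrector collapses on
the way down, the target point is outside the binodal and any shallow
direct "split" is discarded as an artifact. The binodal crossing of a
pathway is then located by bisection with corrector-seeded flashes
(resolution 2e−3 in water mass fraction).

**Binodal/spinodal.** The binodal is traced by stepping tie-line
midpoints toward the polymer apex (adaptive step, halved on failure);
the spinodal is the zero locus of the determinant of the Gibbs-energy
Hessian in two independent mole fractions (finite differences, step
1e−4), bisected along fixed drug:polymer rays.

## Glass-transition model

Kwei equation with the pair sum over **unordered** pairs (each pair
once). The alternative ordered-pair reading doubles the q contribution;
against the eight published phase Tg values of this system the
unordered convention has clearly smaller aggregate error, and a
regression test locks that choice. Simha–Boyer weights are computed
relative to the polymer (K_polymer = 1 exactly). Temperatures are kept
in kelvin internally; reports convert to °C. The eGT on a pathway and
the 37 °C glass contour are located by bisection to 1e−10 in water mass
fraction.

The eGT phase split is obtained by flashing the eGT composition
directly, not by interpolating a pre-traced binodal — at convergence
both describe the same tie line, but the flash avoids interpolation
error exactly where the lever rule is most sensitive.

## Parameters

The shipped data asset carries the literature parameter set for
ritonavir (crystallizable drug with melting record), PVPVA64 (single
pseudo-component, M = 65 kg/mol, induced-association sites), and water
(2-site model, temperature-dependent σ), plus the three binary
`k_ij(T)` lines and Kwei q_ij values. Units are fixed (Å, K, g/mol,
kg/m³, kJ/mol, J/(mol·K)); the loader never rescales. The registry
validates all invariants on load, and serialization round-trips
bit-exactly.

## Verification strategy and what it shows

There is no synthetic-data generator here — the system's "inputs" are
the published parameter tables, and tests run against independent
oracles instead: a re-derived dispersion series, a brute-force
association fixed point, the Euler/Gibbs–Duhem identity, the
closed-form ideal solubility, exhaustive two-phase Gibbs search on
composition grids of a fast toy ternary, and the published phase-split
table itself. The toy systems (three non-associating species with one
demixing pair; a two-component induced-association pair) are synthetic
constructions chosen for speed and a wide miscibility gap; passing them
shows solver correctness, not chemical realism.

Problem sizes: the end-to-end sweep covers five drug loads (1–40 wt%)
at one temperature; the binodal trace in tests is limited to a handful
of tie lines and the toy grid oracle uses a 2%-step composition grid —
sizes chosen so the whole suite stays within a development-machine
coffee break while exercising every code path.

## Known limitations

* **Near-plait sensitivity.** The 5 wt% drug-load pathway reaches its
  eGT within ~0.004 water mass fraction of the binodal. In this
  implementation the crossing falls marginally *above* eGT, so the
  5 wt% case classifies as bulk demixing and yields no interfacial
  phase split, where the published analysis reports a thin (0.02 mass
  fraction) drug-rich phase already at eGT. Everything about that
  boundary — the tangent-plane distance at eGT is +8e−4 — is within
  the reimplementation sensitivity of a PC-SAFT phase boundary; the
  polymer-rich side (composition and Tg) agrees with the published
  values either way. Treat classifications of pathways that graze the
  binodal as boundary calls.
* No three-phase (SLE + LLE) coupling: the drug is a slow
  crystallizer and crystallization is computed (solubility line) but
  not coupled into the flash.
* The copolymer is one pseudo-component: no molar-mass distribution,
  no composition drift along the chain.
* No kinetics: water ingress, erosion, and nucleation rates are out of
  scope; the analysis is a thermodynamic endpoint statement.
* Fugacity derivatives are finite differences; isoactivity residuals
  floor around 1e−9. Analytic composition derivatives would push this
  to machine precision but are not implemented.
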