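# Methods

This note records the models, conventions, numerical choices and known
limitations of `sccosol`. Everything quantitative stated here is computed
by the test suite or the examples.

## Data model and units

A `SolubilityDataset` is an ordered table of isothermal measurements
(T in K, P in MPa, pure-CO₂ density ρ₁ in kg/m³, solute mole fraction y₂).
Densities are inputs (reference-EoS values at the state point), never
recomputed. Internally the EoS and cluster modules work in SI (Pa, m³,
mol); density models take P in MPa directly. Two fixed conventions that
fitted constants absorb:

* y₂P products (Bartle and MT forms) use P in MPa. The packaged published
  MT constants were regressed with P in bar — their H₃ is exactly ln 10
  above the MPa-convention value, with H₁ and H₂ identical — so
  evaluating them under the MPa convention misreproduces the data; refits
  are unaffected (the model family is invariant under the pressure unit,
  which only shifts H₃).
* The reformulated-Chrastil base RTρ₁/M is converted to Pa and divided by
  the 0.1 MPa reference fugacity, making it dimensionless.

Reduced variables use the CO₂ criticals Tc = 304.18 K, Pc = 7.38 MPa and
ρc = 467.6 kg/m³ (the standard critical density; the data source does not
state one — spot checks of the reduced-variable models' printed constants
are consistent with this value).

The vial-sampling conversion assumes a 600 µL saturated-fluid loop
depressurised into 5 mL of collected methanolic solution; this assignment
(rather than the swapped one) reproduces the packaged y₂/S pairs.
The solid molar volume 364.764 cm³/mol is read from a unit-garbled source
header; it implies a crystal density of ≈1.26 g/cm³, which is plausible
for a chlorinated organic salt.

## Density models and their fitting

All ten correlations are linear in their parameters after a log-type
transformation (directly linear for the reduced-state polynomial). Fits
therefore start from the exact least-squares solution in the transformed
space (relative-error-weighted for the linear-in-y model) and polish the
true L1-relative objective OF = Σ|y_exp − y_cal|/y_exp with bounded
Nelder–Mead from that start plus seeded random multistarts. This is
deterministic per seed, lands within ~1 percentage point of the published
AARD for every model on the reference data, and never does worse than the
published constants. For the MT model the refit is ~2 points *better* than
the published AARD; the published MT fit is demonstrably not at the
optimum of this objective.

## Peng–Robinson route

Standard PR-1976: α = [1 + m(1 − √Tr)]², m = 0.37464 + 1.54226ω −
0.26992ω², a = 0.45724 R²Tc²/Pc·α, b = 0.07780 RTc/Pc; vdW2 quadratic
mixing with corrections k₁₂ (energy) and l₁₂ (covolume); the standard
partial-fugacity-coefficient expression with dimensionless A = aP/(RT)²
and B = bP/RT. The cubic in Z is solved in closed form (vectorised
Cardano); among real roots above B the one with the lower pseudo-pure
ln(f/P) is taken (supercritical states have a single root in practice).
Validation: the analytic φ̂ᵢ agrees with a volume-integral
numerical-differentiation oracle to 10⁻⁴ on random binary states, and a
Gibbs–Duhem composition check holds to 10⁻⁶. PR underpredicts
near-critical CO₂ density by up to ~9% on the reference grid — a known
limitation of two-constant cubics, not of the implementation.

The solid-solubility condition is solved by fixed-point iteration on y
(start 10⁻⁸, relative tolerance 10⁻¹⁰, cap 60 iterations — convergence
takes ~5 at y ~ 10⁻⁶ because φ̂₂ depends only weakly on a trace
composition). φ_sat of the pure solid is unity. The sublimation pressure
is in Pa with reference temperature 298.15 K.

Regression:

* *t-dependent*: per isotherm, a coarse (k₁₂, l₁₂) grid followed by
  Nelder–Mead, sublimation pressures from the packaged table. On the
  reference data this reproduces the published per-isotherm (k₁₂, l₁₂) to
  ~10⁻⁴ and the per-isotherm AARDs to <0.02 points — the strongest
  end-to-end validation of the conventions above.
* *t-independent*: for any (k₁₂, l₁₂) the sublimation pressures that
  reproduce each point exactly are available in closed form, and their
  logarithms are projected onto the three-coefficient form by linear
  least squares; a grid over (k₁₂, l₁₂) with this inner solve, followed by
  full five-parameter Nelder–Mead polish, gives a seed-independent
  optimum. A seeded differential-evolution search was tried first and
  rejected: it was slower and fell into poor local optima for some seeds.
  The free optimum on the reference data is AARD 5.83%, notably below the
  published 8.25%; evaluating the published constants through this
  implementation reproduces their 8.25% to 0.02 points, so the difference
  is optimizer depth, not model or convention mismatch.

The three sublimation-form coefficients are nearly collinear over a 30 K
window, so only the van't Hoff slope of ln p_sub is identified by data.
`dhsub_eos` therefore exposes two readings: the bookkeeping convention
R(γ/R + Δ_subδ/R·T) used by the reference constant set, and the literal
van't Hoff form R(−γ/R + Δ_subδ/R·T) (`literal=True`), which is the one
that remains stable for freshly fitted coefficients and is used by the
`thermo` reporting path.

## Cluster (solvate-complex) models

The equilibrium A + κB ⇌ AB_κ with complex parameters from the combining
rules b_c = κ·b_B + b_A and a_c = [κ√(a_B b_B) + √(a_A b_A)]²/b_c. The
solubility is y = e^X / (1 + 2κ e^X) with

X = κ·ln[φ̂_B(T,P)·P / (φ_B(T,P_c)·P_c)] + v_s(P − P_c)/RT
  − ln[φ̂_AB(T,P)·P / (φ_AB(T,P_c)·P_c)] − ΔF(T)/RT,

P_c the solvent critical pressure. φ̂_B is evaluated at the solvent-rich
composition z_B = 1 − κ·z_AB iterated to self-consistency from the pure
solvent limit, and φ̂_AB at infinite dilution of the complex; references
are pure fluids at (T, P_c).

**Design choice — binary corrections.** The complex–solvent pair carries
the (k₁₂, l₁₂) calibrated by the temperature-independent EoS regression
on the same data (`fit_cluster` runs that regression itself when no
interaction is supplied). With the uncorrected geometric-mean attraction
(k₁₂ = 0) the complex inherits the solute's enormous energy parameter
(~34 Pa·m⁶·mol⁻²) and its infinite-dilution fugacity coefficient varies
so steeply with density that no reaction term ΔF(T) can recover the
observed isothermal pressure dependence: the best achievable AARD is ~28%
at any κ, and the published parameter sets evaluate to 57–76% through the
uncorrected chain. This mirrors the plain EoS route, which also fails
without its fitted corrections. With the inherited corrections the
four-parameter model correlates the reference data to ~5.8% and the
three-parameter variant to ~8.1%, reproducing the published ordering and
quality; the published evaluation composition could not be reconstructed
exactly and is documented here as this package's own convention.

Fitting exploits that at y ~ 10⁻⁶ the exponent is ≈ ln y, so for fixed κ
the optimal ΔF decomposes into independent per-isotherm one-dimensional
problems; a κ grid with per-isotherm solves and a least-squares projection
of ΔF(T) onto the variant's basis initialises a full Nelder–Mead polish.
The three-parameter solution, re-embedded with b″ = 0, seeds the
four-parameter polish, so the richer law never fits worse (verified
bit-for-bit reduction on random states). Gibbs–Helmholtz on ΔF gives the
reaction enthalpy and entropy: ΔH = a′ (linear law) or a″ − b″T, ΔS = b′
or −b″(ln T + 1) − c″.

## Property estimation

The chain for drug-like solutes with no measured criticals: Tb from the
inverted Klincewicz relation Tb = (Tc − 50.2 + 0.16M)/1.41; Lee–Kesler
vapor pressure ln(P/Pc) = f⁰(Tr) + ω f¹(Tr); ω from anchoring the
Lee–Kesler pressure to 1 atm at Tb. For the reference drug the chain
gives ω = 0.314 vs the tabulated 0.337 (within 7%) and a 11.19-fold
vapor-pressure increase from 308 to 338 K. Absolute Lee–Kesler pressures
sit ≈14× above the packaged tabulated values while the temperature ratio
matches; the tabulated values are therefore kept as the canonical input
for the EoS temperature-dependent mode and the discrepancy is surfaced
here rather than hidden.

Group contributions are a small formula engine over editable JSON tables
(`sum`, Joback Tb/Tc/Pc assemblers, the 535·log₁₀ Σ critical-temperature
form, Lydersen-style Pc, and crystal-volume sums in Å³). The Joback
tables ship with their published increments and are validated on a
benzene worked example (Tc within 0.1% of experiment, Pc within 3%); the
critical-temperature and crystal-volume starter tables are labelled
synthetic — illustrative increments for exercising the engine, to be
replaced from the original sources before production use. The reference
drug's properties are always taken from the packaged fixture, not
recomputed.

## Synthetic data

`generate_synthetic` emulates the measurement campaign's structure: the
packaged 4 × 6 (T, P, ρ₁) grid, model-generated mole fractions, and
multiplicative noise y₂ → y₂(1 + ε) with ε Gaussian (default relative
scale 3%, matching the 1–5% replicate standard deviations typical of
vial-sampling data; uniform noise selectable), clipped to (0, 1) and
deterministic per seed. It reproduces grid structure and noise scale only
— not drifts between replicates, pressure-correlated sampling errors, or
equation-of-state error in the tabulated densities — so recovery tests
certify the fitters, not the field accuracy of the correlations.

## Model selection

SSE is computed on raw mole fractions; AIC = N ln(SSE/N) + 2N_p and its
small-sample correction are implemented literally, and ranking is by
ascending AICc with ties broken by parsimony then AARD. The published
absolute AIC values for this system are internally inconsistent with
their own SSE column and are not reproduction targets; the AIC→AICc
offsets (1.2, 2.105, 3.33, 4.94 for N_p = 3…6 at N = 24) are exact and
verified.

## Known limitations

* Binary (solute + CO₂) systems only; no cosolvents, no multi-solute
  equilibria, no temperature-dependent κ.
* PR with vdW2 is the only EoS; near-critical density error (~9%) is
  inherited by everything built on it.
* The relative-deviation objective is non-convex; the multistart
  machinery is deterministic per seed but global optimality is only
  evidenced by the decomposition-based starts, not proven.
* Expanded-uncertainty propagation is out of scope; only the replicate
  sample standard deviation is handled.
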