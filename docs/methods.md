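# Methods

## The model

The availability of the alternative sigma factor σ^B (SigB) in
*Bacillus subtilis* is set by partner switching: the anti-sigma factor
RsbW acts as a homodimer W₂ that sequesters SigB in a W₂·SigB complex,
and the anti-anti-sigma factor RsbV, when dephosphorylated, binds W₂
and displaces SigB. RsbW is also a kinase that phosphorylates and
inactivates RsbV; the phosphatases RsbU (environmental stress) and RsbP
(energy stress) reactivate it. The reaction set is

| reaction | rate constants |
|---|---|
| W₂ + V ⇌ W₂V | k₁₊ = 6·10⁻⁵ y⁻¹min⁻¹, k₁₋ = 0.3 min⁻¹ |
| W₂V + V ⇌ W₂V₂ | k₂₊ = 6·10⁻⁵ y⁻¹min⁻¹, k₂₋ = 0.3 min⁻¹ |
| V →(W₂) V‑P | k₃₊ = 0.6 y⁻¹min⁻¹ |
| W₂V₂ → W₂V + V‑P | k₄₊ = 0.6 min⁻¹ |
| W₂ + SigB ⇌ W₂SigB | k₅₊ = 6·10⁻⁵ y⁻¹min⁻¹, k₅₋ = 0.3 min⁻¹ |
| W₂SigB + V ⇌ W₂V + SigB | k₆₊ = k₆₋ = 3·10⁻⁴ y⁻¹min⁻¹ |
| V‑P + RsbU/RsbP → V + RsbU/RsbP | k₇₊ = 3 y⁻¹min⁻¹ (shared) |

The dynamic state holds seven species: SigB_f, W₂_f, V_f, W₂SigB, W₂V,
W₂V₂ and VP ("f" = free). Mass-action kinetics govern the bound species
and VP. The free forms are closed not by synthesis/degradation terms but
by the *measured* totals

    S   = SigB_f + W₂SigB
    AS  = 2(W₂_f + W₂V + W₂V₂ + W₂SigB)
    AAS = V_f + W₂V + 2·W₂V₂ + VP

whose time derivatives (from the smoothed expression profiles) force the
free-form equations, e.g. d(SigB_f)/dt = dS/dt − d(W₂SigB)/dt. Measured
expression already contains synthesis and degradation, so neither needs a
separate term. RsbU and RsbP enter as time-varying measured profiles
(values only), not as dynamic states. Free phosphate is implicit. A
consequence of this construction is that the model totals track the
measured totals *identically* at the level of the equations — numerical
deviation from the measured curves measures solver error and nothing
else, which is the primary correctness surface of the test suite.

All abundances live on the dimensionless "y" scale: raw MS intensities
divided by 3.7·10⁴, the scale on which the rate constants above are
calibrated. The y scale has no absolute molarity anchor; results are
interpretable only relative to it. The kinase constant k₃₊ multiplies
two species and therefore carries y⁻¹min⁻¹ even though the published
table of constants lists it as min⁻¹; the numeric value is used as
printed.

## Driving profiles

Replicate intensities are averaged per time point (arithmetic mean),
divided by the global scale divisor, and fitted with a cubic
least-squares B-spline with a configurable number of evenly spaced
interior knots (default 6 over the 0–130 min window — flexible enough
for the sigmoid shapes of the measured series at 14 time points; the
original smoothing settings are unpublished, so this is a documented
stand-in). Values and the *analytic* spline derivative are reported on a
1-minute grid, and the integrator evaluates the underlying spline
continuously between grid points — finite differences of resampled
values would not provide the continuous dS/dt forcing the free-form
equations need. Negative spline excursions are clipped to zero in the
values (amounts are physical) and at continuous evaluation; derivatives
are left as fitted so the derivative remains the exact derivative of the
fitted spline and integrates back to its endpoint differences.
Evaluation outside the measured window is an error: the analysis never
extrapolates beyond the data.

## Initialization and the artifact probe

At time zero SigB_f = S(0), W₂_f = AS(0)/2, complexes are empty, and a
fraction `vp_fraction` of AAS(0) starts as VP. The default
`vp_fraction = 1` (all RsbV initially phosphorylated) is the only
initialization that both satisfies the mass balances with zero free V
and yields feasible solutions on measured data. `initial_state` offers
two placements of the remainder when `vp_fraction < 1`:
`free_v="complement"` puts (1−vp)·AAS(0) into free V (mass-consistent),
while `free_v="zero"` sets only the phosphorylated pool and leaves free
V at zero — the rule that takes the time-zero values verbatim. The
artifact probe `detect_init_artifact` uses the latter: for vp < 1 it
under-accounts the measured RsbV total by exactly (1−vp)·AAS(0), and the
integration then either violates conservation (the offset is preserved
by the dynamics), drives species negative, or fails outright. All three
channels are reported without privileging one; an empty report means the
initialization is sound. On the synthetic data (monotonically rising
totals) the conservation channel is the one that fires: negativity
additionally requires declining stretches in the fitted totals, because
every consumption flux vanishes at the zero boundary of its species.

## Numerical choices

* Integrator: LSODA (stiff-capable) by default; any `solve_ivp` method
  can be selected via config for cross-checking. rtol = 10⁻⁶.
* atol = 10⁻¹²: species magnitudes span ~10⁻⁸–3 y (the W₂V₂ pool is
  ~10⁻⁷ y at baseline), and the absolute tolerance must sit below the
  smallest of them for per-component relative accuracy to be meaningful.
* Scenario grids run at rtol = 10⁻¹⁰, atol = 10⁻¹⁴: between-scenario
  differences in final free SigB can be as small as ~3·10⁻⁸ y in the
  weak-binding regime, and the integration error must sit well below the
  differences being compared. Orderings at these settings were verified
  against Radau at rtol = 10⁻¹² (an independent integration method).
* Negative excursions are never clipped during integration; they are
  recorded as feasibility flags (threshold 10⁻⁸ y below zero). Clipping
  would silently destroy the conservation identities that the tests
  rely on, and negativity is itself the diagnostic the artifact probe
  reports.
* A second integration route — only the four bound species integrated,
  frees recovered algebraically from the mass balances — is maintained
  as a cross-check; the two routes agree to ~3·10⁻⁶ y on the synthetic
  baseline.
* The identity initialization check (`enforce_balance`) uses a relative
  tolerance of 10⁻⁶ against the time-zero totals; conservation along
  trajectories is judged against the driving profiles at every grid
  point, not against the initial totals.

## Perturbation scenarios

Amount perturbations rescale a protein's *entire* profile — values and
derivatives — modelling a proportional change in expression over the
whole window, not just a different starting amount. AAS scaling thereby
also rescales the initial VP pool, since initialization reads AAS(0)
from the scaled profile. Rate perturbations multiply individual
constants. The reference grid (15 scenarios: a shared baseline,
RsbU ÷ {2, 10, 20}, AAS ÷ {2, 3, 5}, k₇₊ ÷ {5, 10, 100},
AS × {½, 2, 5}, and k₅₊ × {10, 100} with k₅₋ divided by the same
factor) probes, in turn, the phosphatase supply, the anti-anti-sigma
reservoir, the dephosphorylation rate, the anti-sigma dose, and the
SigB–W₂ binding equilibrium. Summaries report final and window-mean
free SigB; trend assertions use the final value (responses separate most
clearly late in the window), with the mean reported alongside.

## The synthetic generator

The generator emulates the *structure* of the proteomic dataset the
pipeline targets: 5 proteins × 14 time points (0–130 min, 10-min
spacing) × 3 biological replicates, with mean-one multiplicative
lognormal noise (cv 0.1 — MS intensities are positive with
roughly proportional error). SigB, RsbW and RsbV rise as logistics
sharing a midpoint (60 min), reflecting their co-expression from one
operon; RsbU is a moderate level with a mild upward drift; RsbP is a
small constant capped at 1% of the SigB amplitude (the near-zero
energy-stress branch). Intensities are of order 10⁴–10⁵ so that the
global divisor yields order-1 y values. Noise-free generating curves are
returned with every draw, so smoothing accuracy is tested against known
truth rather than against other smoothers.

What the generator does *not* emulate: correlated noise between
replicates or proteins, missing values, declining or peaked expression
phases, and the absolute intensity calibration of any particular
instrument. Passing tests therefore demonstrate the correctness and
internal consistency of the machinery on data with the right shape and
noise structure — not that any specific biological conclusion transfers
to a particular measured dataset.

## Known limitations

* On order-1 y data the SigB–W₂ binding is weak (k₅₊·W₂_f ≪ k₅₋), so
  amount perturbations shift free SigB by small margins (10⁻⁸–10⁻³ y);
  the directions are robust and numerically resolved, but the dramatic
  sequestration regime requires abundances orders of magnitude larger
  on the y scale than this generator (or division by this divisor)
  produces.
* Under the mass-action equations with the calibrated constants, the
  coupled k₅ shift (×100/÷100) always sequesters more SigB than a
  5-fold anti-sigma overdose, at any abundance scale: the bound/free
  ratio scales as k₅₊·W₂_f/(k₅₋ + k₆₊·V_f) and the k₅ shift moves both
  numerator and denominator in its favour. A claim that the anti-sigma
  dose dominates every other perturbation is thus not reproducible
  within this model; the corresponding acceptance assertion documents
  this by failing.
* The smoothing spline is a stand-in for unpublished smoothing
  settings; fitted curves (and hence forcing derivatives) are not
  bit-comparable to any original analysis.
* No parameter estimation: the rate constants are fixed literature
  values; the pipeline propagates, it does not fit.
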