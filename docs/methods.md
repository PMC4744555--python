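# Methods

## Model

The package models the ATPase cycle of Dbp5 as a mass-action network
over the minimal four-state scheme: reversible ATP binding
(H + T ⇌ HT), reversible hydrolysis (HT ⇌ HD·Pi), reversible phosphate
release (HD·Pi ⇌ HD + Pi) and reversible ADP release (HD ⇌ H + D).
Product release is sequential with phosphate preceding ADP. Nucleotide
binding is treated as a single transition; isomerizations known to
accompany binding are absorbed into the effective on/off constants.

Units are µM for concentrations, s for time, and µM⁻¹s⁻¹ for
second-order constants throughout the core; conversions (mM, molar,
absorbance) happen at the I/O boundary. Equilibrium constants are
dissociation-style ratios (K_T = k−T/k+T, K_D = k−D/k+D,
K_H = k−H/k+H, K_Pi = k−Pi/k+Pi) and may be infinite when a denominator
rate is zero (phosphate rebinding is zero by default, making release
irreversible, consistent with the absence of phosphate product
inhibition up to 10 mM).

Two packaged presets carry the working parameter sets: `table1`
(transient-kinetics estimates: k+H 2.2 s⁻¹, k−H 2×10⁻⁴ s⁻¹, k−Pi
0.02 s⁻¹, K_T 6.4 mM with k−T 3670 s⁻¹, K_D 360 µM with k−D 64 s⁻¹) and
`table2_nadh` / `table2_pibip` (global-fit estimates from the
NADH-coupled and phosphate-sensor datasets respectively). The two
global-fit sets are reported separately and are not reconciled; the
steady-state (NADH) set is the one used for the closed-form headline
numbers.

## Observables

* `nadh_a340` — the NADH-coupled assay is modeled as a pseudo-first-
  order regeneration step D → T (default 100 s⁻¹, far above kcat so the
  coupling is never limiting) and the observable is the cumulative
  regenerated ADP converted to an A340 decrease with ε(NADH) =
  6220 M⁻¹cm⁻¹ over a 1 cm path.
* `pibip_pi` — the fluorescent phosphate sensor is modeled two ways.
  The default treats capture as instantaneous and irreversible: the
  observable is liberated phosphate clipped at the sensor capacity
  (appropriate because sensor binding, k_on ≈ 300 µM⁻¹s⁻¹ with
  K_d = 0.1 µM, is orders of magnitude faster and tighter than any
  cycle step). The explicit mode integrates sensor binding as a
  reaction and reports the sensor·Pi complex; it is the right choice
  when the burst of a sequential-mix experiment must be resolved as a
  bimolecular phase. The instantaneous mode assumes captured phosphate
  cannot rebind, so it should not be combined with a nonzero phosphate
  rebinding constant.
* `species` — raw populations; every simulated trace also carries the
  full species time courses as a DataFrame.

## Integration

The network is stiff (rate constants span ~7 decades; nucleotide
binding relaxes in sub-milliseconds while turnover takes tens of
seconds), so simulation uses LSODA with rtol 1e-8 and atol 1e-12 µM by
default, both configurable. Enzyme conservation is checked at every
output time against 10× the integrator tolerance and a violation raises
an error rather than returning silently degraded populations.
Oracle-grade comparisons in the tests tighten to rtol 1e-10; the noisy
recovery study relaxes to rtol 1e-7 since 2% measurement noise
dominates the error budget there.

Sequential (dual-mix) protocols integrate the first mix for the aging
time, divide all concentrations by the dilution factor (default 2,
equal-volume mixing), add the second-mix species at their final
concentrations, and re-integrate. Degenerate inputs (zero enzyme, zero
ATP, zero aging) are legal and give flat or single-mix-identical
traces.

## RNA-extended cycle

How RNA enters the cycle is not fully constrained by the data, so the
topology is a design choice. Here RNA engages the ATP-bound enzyme
through a rapid-equilibrium binding (K_d,RNA, default 3 mM nucleotide)
followed by a first-order isomerization (k_iso, default 5 s⁻¹); the
composite saturable step produces the observed hyperbolic RNA
dependence of the pre-steady-state lag. The RNA-bound branch uses
scaled hydrolysis/resynthesis (defaults: hydrolysis ×10 so it is not
limiting, resynthesis ×80 per the isotope-exchange comparison of the
two conditions) and its own phosphate release constant (default
5 s⁻¹). RNA dissociates together with ADP, so each steady-state cycle
re-engages RNA; with engagement and RNA-bound release both at 5 s⁻¹
the minimal enzyme·RNA interaction time per cycle is
1/k_iso + 1/k−RPi = 0.4 s.

Two consequences of this topology are worth stating plainly. First,
because the defaults keep RNA-bound release at 5 s⁻¹ while resynthesis
is 80-fold accelerated, the implied RNA-branch partition coefficient is
k−H·80/(k−H·80 + 5) ≈ 0.003, smaller than the measured RNA-condition
value (~0.04); reproducing that value would require slowing RNA-bound
release toward 0.4 s⁻¹, which would then conflict with the observed
4–6 s⁻¹ lag. The defaults favor the directly observed transient rates.
Second, since RNA binds only the ATP state, enzyme parked in the
ADP·Pi state by aging re-enters the RNA pathway only after intrinsic
phosphate release; the 4–6 s⁻¹ lag that the model produces in aged
sequential-mix simulations comes from the subpopulation still in the
ATP-bound state. Whether RNA also engages post-hydrolysis states is an
open mechanistic question deliberately left outside this scheme.

## Fitting models

All transient fits are nonlinear least squares (scipy) with analytic
model functions:

* Sums of exponentials use variable projection — rates are optimized in
  log space and amplitudes plus offset solved linearly at each step —
  with rates initialized log-spaced across the sampled time range.
  Rates are reported in decreasing order; a fit whose phases collapse
  onto one rate falls back to fewer phases and flags it.
* Non-pseudo-first-order binding uses the bimolecular progress term
  A₀(1 − e^(−k₀t))/(1 − r·e^(−k₀t)) with r ∈ [0, 1) enforced by bounds;
  below r = 10⁻⁶ the term is evaluated as a plain exponential for
  numerical continuity.
* The lag/linear model, its substrate hyperbola, and the kinetic
  competition hyperbola use 3-point log-spaced multi-start on the
  half-saturation (or lag) parameter to avoid local minima. When the
  fitted lag rate exceeds half the sampling rate (λ > 1/(2·median Δt))
  it is reported as a lower bound rather than an estimate.
* The lag decomposition is exact algebra: k+H = λ∞ − λ₀,
  k−H = Pc·λ₀, k−Pi = (1 − Pc)·λ₀, so the three components sum to λ∞
  identically.
* The burst + lag/linear model nests the plain lag/linear fit and
  reduces to it whenever the burst amplitude does not improve the fit.
  On traces with a saturable RNA lag the burst and lag terms can trade
  off (the model has two interchangeable relaxations); for such
  protocols the lag rate is taken from the lag/linear fit with the
  aged-phosphate step absorbed into the offset.

Noiseless round-trip tests assert recovery at 1e-6 relative; noisy
recovery is asserted at 3 standard errors.

## Isotope exchange

Each hydrolysis incorporates one water oxygen into the bound phosphate;
each reversal expels one of the n = 4 equivalent oxygens uniformly
(free-rotation assumption; n = 3 is available for sensitivity
analysis) and the next hydrolysis restores a water oxygen. The number
of water-derived oxygens at release therefore follows a Markov chain
whose release-time distribution is the geometric series
(1 − Pc)·Σ(Pc·M)^k·δ₁; the series is summed exactly through the
resolvent (I − Pc·M)⁻¹ rather than truncated. The GCMS-observable
heavy-atom distribution follows by binomial thinning at the water
enrichment; contaminating unenriched phosphate adds to the zero-heavy
species only, which is why the ¹⁸O₂:¹⁸O₁ ratio — strictly increasing
in Pc and inverted by bracketed root finding — is the estimator of
choice. Two ratio conventions are exposed: `heavy_atom` (observed ¹⁸O
counts, the default) and `water_count` (water-derived-oxygen counts,
enrichment-independent). The published ratio→Pc mapping is not exactly
reproduced by either convention at 48.5% enrichment, so that mapping is
documented but not asserted; the package's forward and inverse models
are exactly consistent with each other.

## Global fitting

Free rate constants are optimized in log space (they span decades and
must stay positive). Independently measured ratios — nucleotide
affinities, the release/resynthesis ratio from isotope exchange — are
enforced exactly by deriving one member of each constrained pair from
the other at every iterate, so constraint residuals are zero by
construction. Phosphate rebinding is frozen at zero by default.
Datasets are weighted by inverse noise standard deviation (recorded by
the generators, or estimated from late-trace differences for imported
data). Multi-start (default 5 seeded starts, up to 10-fold
perturbations) guards against local minima. Approximate standard
errors come from the Jacobian at the solution; a near-flat direction
(smallest singular value below a configurable fraction of the largest)
raises an identifiability flag naming the parameters involved — the
expected outcome when, for example, a fast product-release step is
freed against steady-state data that only constrain the composite
turnover.

## Synthetic data

Generators mirror the published assay designs: the NADH ladder (0.66 µM
enzyme, 0–20 mM ATP), the phosphate-sensor ladder (0.5 µM enzyme, 5 µM
sensor, 0–5 mM ATP), labeled-nucleotide binding (0.5 µM enzyme, 0–50 µM
mant nucleotide, three sequential transitions for labeled ATP and a
weak-then-tight sequence for labeled ADP, fluorescence weights
(0, 1, 1.5, 1.8) — arbitrary but recorded), the RNA titration (0.1 µM
enzyme, 20 mM ATP, 0–4.5 mM RNA nucleotides) and multinomial GCMS
isotopologue counts. Noise is i.i.d. Gaussian, default 2% of each
trace's full-scale amplitude (typical stopped-flow performance), with a
heteroscedastic option; identical seeds give bit-identical outputs and
every generator writes its ground truth into the trace metadata.

The generators deliberately do not emulate instrument dead time
(~2 ms), photobleaching, inner-filter effects, mant isomer
heterogeneity, or baseline drift. Passing recovery tests therefore
demonstrate that the estimators are consistent and correctly
implemented under the model's own assumptions — not that real traces
with those artifacts will fit as cleanly.

## Problem sizes in the test studies

The closed-form/ODE equivalence study uses 100 random parameter sets
with a catalytic enzyme concentration (KM/1000) and product
regeneration, matching the zero-product assumption of the closed
forms. The noiseless global-fit recovery uses 2 NADH + 2 sensor traces;
the 30-replicate noisy study uses 4 NADH + 3 sensor concentrations per
replicate with a single seeded start from 3-fold-perturbed values —
sizes chosen to keep each study a routine desk run while leaving the
estimators' degrees of freedom intact. The Monte-Carlo check of the
isotope chain uses 2×10⁵ draws per Pc value at a 3σ criterion.

## Known limitations

* ADP product inhibition is modeled only through reversible ADP
  binding; no separate inhibited species exists.
* The steady-state occupancy solver clamps free ligand concentrations
  (buffered approximation) — appropriate for catalytic enzyme, not for
  stoichiometric mixes.
* The closed-form kcat/KM are meaningful only for enzyme ≪ KM; the
  quadratic (tight-binding) form is provided for RNA activation where
  depletion matters, but not for ATP.
* mant-nucleotide fluorescence coefficients and the labeled-ADP scheme
  mapping are conventions of the generator, not measured quantities.
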