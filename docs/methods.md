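# Methods

This note documents the models, the synthetic-data conditions, the
numerical choices, and the known limitations of the package.  Units are
molar for all concentrations internally (nM appears only in reports),
minutes for time, and kcal/mol for free energies.

## Equilibrium competition binding

The one-site displacement model is fitted directly in pKi:
response = bottom + (top − bottom)/(1 + [I]/IC50) with
IC50 = Ki(1 + [L]/Kd).  The Hill slope is fixed at 1 (a one-site model);
a free-slope variant is deliberately not exposed as a default because the
downstream Cheng–Prusoff correction assumes simple competition.
Initialization is deterministic: top/bottom from the response extrema, the
starting IC50 from the concentration whose response is nearest half-range.
The pKi standard error comes from the asymptotic fit covariance; when
replicates are present the convention is fit-per-replicate then
mean ± SEM across fits, matching how such assays report n independent
repeats.  Curves whose fitted dynamic range falls below 3× the residual
noise are flagged inestimable rather than reported.

The tracer defaults to 5 nM at an equilibrium Kd of 5 nM — the standard
configuration of the fluorescent tracer CA200645 at the Nluc-tagged human
A3 receptor.  Note that this rounded equilibrium Kd is *not* identical to
k2/k1 from the kinetic constants (5.85 nM); `TracerParams` enforces
consistency when all four values are supplied, so the equilibrium and
kinetic assay configurations are constructed separately.

Nonspecific-binding baseline subtraction is a plain elementwise offset;
the baseline level is a configuration input (assay protocols differ on the
blocking concentration), never hard-coded.

## Competition kinetics

`competitive_binding_signal` implements the closed-form solution for a
labeled tracer and an unlabeled competitor binding the same receptor pool
from zero occupancy, with ligand depletion neglected.  The zero-competitor
case is evaluated through its analytic limit (simple association) rather
than the degenerate general formula.  The closed form is validated against
direct numerical integration of the coupled rate equations to <1e−6
relative error.

Fitting is global across all traces — shared Bmax, k3, k4, with the tracer
constants k1 = 3.25×10⁶ M⁻¹min⁻¹ and k2 = 0.019 min⁻¹ held fixed
(co-fitting them is unidentifiable in this design and the values are known
from prior saturation/kinetic work).  Rates are fitted on a log10 scale
within k3 ∈ [10³, 10¹⁰] M⁻¹min⁻¹ and k4 ∈ [10⁻⁴, 10] min⁻¹, initialized at
the tracer's own constants; weighting is uniform on the untransformed
signal.  A k4 estimate at the lower bound is flagged — residence time is
unmeasurable in that regime ("<1 min").

### Kinetic assay design

The generator's canonical design was chosen by Fisher-information analysis
of the model, not by convenience: the competitor off-rate is encoded
almost entirely in the decay of the early occupancy overshoot, and k3/k4
estimates are strongly correlated (ρ ≈ 0.9) because the concentration
panel pins their ratio (the Ki) much more tightly than either rate.  The
defaults are plate-reader acquisition every 30 s over 2 h, competitor at
0/3/10/30/100/300/1000 nM, duplicate wells, and n = 3 independent
experiments fitted separately and averaged.  At additive noise of 5% of
Bmax this design's information limit gives ≈5–6% standard error on the
triplet-mean rates; sparser designs (e.g. 16 time points) are
information-starved at the same noise, with >12% attainable precision no
matter the optimizer.

## Functional antagonism

cAMP responses are normalized to the 100 μM forskolin response; for
Gi-coupled readouts the inhibition mode returns 100·(1 − raw/max) so
potency is always fitted as a rising three-parameter logistic (basal,
Emax, pEC50; Hill slope 1).  Single-concentration antagonist affinity uses
the Gaddum dose-ratio relation pK_B = −log10([B]/(DR − 1)); a dose ratio
≤ 1 (no rightward shift) is an error, not a silent zero.  The full Schild
analysis regresses log10(DR − 1) on log10[B] by ordinary least squares;
pA2 is the negative of the regression's x-intercept (= intercept/slope)
and the slope is reported — unity indicates simple competition.  Points
with DR ≤ 1 are excluded with a warning and at least three usable
concentrations are required.

The canonical functional design is a 16-point agonist grid spanning
0.1 pM–1 mM in duplicate: the wide grid keeps both plateaus of curves
shifted by up to ~1000-fold dose ratios inside the measured range, which
is what makes the Schild slope reproducible to ±0.025 at 2% noise.

## Alchemical free energies

`LambdaEnsemble` holds per-state samples on a λ ladder with complete
cross-evaluated reduced potentials u_kn (dimensionless) and optional
per-sample dU/dλ (kcal/mol); β is carried explicitly (default 310 K) so
MBAR operates unitlessly while TI integrates in kcal/mol.  Production
sampling is out of scope; ensembles come from a plain-text exchange format
or from the toy generators.

* **TI** uses trapezoidal quadrature over per-state sample means, with the
  standard error combining per-state SEMs with the trapezoid weights.
  Trapezoidal bias is real on coarse ladders: for the default harmonic toy
  (stiffness 1 → 4) a 5-state ladder carries ≈ +0.013 kcal/mol of
  deterministic quadrature bias, comparable to the Monte-Carlo noise at
  2000 samples/state.  Dense ladders (11 states) make it negligible.
* **MBAR** is solved by damped (step-halving) self-consistent iteration
  with log-sum-exp stabilization, f₀ pinned to 0, tolerance 1e−8 on
  max|Δf|, cap 10,000 iterations; non-convergence raises with the residual
  attached.  The asymptotic covariance of the f_k is computed from the SVD
  of the N×K weight matrix; when the smallest adjacent-state overlap drops
  below 1e−3 a warning is emitted and the reported variance is inflated
  10× rather than trusted.
* **BAR** (two-state Bennett acceptance ratio) is implemented as an
  independent cross-check, solved by bracketed root finding on the implicit
  BAR equation; two-state MBAR and BAR agree to <1e−6 by construction of
  the same stationarity condition, which the tests verify numerically.

The thermodynamic cycle combines bound- and solvent-leg ΔA values with
errors in quadrature, and experimental ΔΔG uses R = 1.98720×10⁻³
kcal mol⁻¹ K⁻¹ at a default temperature of 310 K (the membrane-simulation
temperature, and the choice under which the measured 34.7 → 11.7 nM
affinity pair reproduces −0.67 kcal/mol); 298 K is selectable.
Calculated-vs-experimental agreement is summarized by Pearson r, the
least-squares slope of calc on exp, and the mean unsigned error.

### Toy models

Two ensemble families admit closed-form ground truth.  The 1-D harmonic
model interpolates stiffness and center linearly in λ; its free-energy
change is (1/2β)·ln(K₁/K₀) (a center shift contributes nothing, but does
generate nontrivial dU/dλ samples, which makes it a good TI null test).
The Gaussian model specifies per-state reduced potentials
(x−μ_k)²/(2σ_k²) with ΔA = ln(σ₀/σ_last)/β; it has no dU/dλ and exercises
the MBAR/BAR route only.  Anything else raises an unsupported-model error.

## ADME calculators

Equilibrium dialysis: % bound = 100·(area_p − area_b)/area_p and
% recovery = 100·(area_p + area_b)/area_c from HPLC peak areas; a buffer
area exceeding the protein-side area is floored at 0% bound with a
warning.  Bidirectional permeability:
Papp = V_R·C_R,end/(Δt·A·C_D0) reported in 10⁻⁶ cm/s, with a midpoint-donor
variant (mean of initial and final donor concentration) behind a switch;
recovery is end-point mass in both chambers over the donor load.  The
uptake ratio Papp(A→B)/Papp(B→A) is reported to 2 significant figures.
Half-life comes from OLS of ln(% remaining) on time restricted to the
initial first-order range, defined as points with ≥10% remaining (the
protocol phrase "initial linear range" is not quantitative; the 10% rule
is this package's documented default), and
CLint = (ln2/t½)/[microsomal protein]·1000 with a default microsome
concentration of 0.1 mg/mL.

## Synthetic data: what it does and does not emulate

Generators produce data lying exactly on the surface of the paired
fitter's model, plus additive Gaussian noise on the normalized response
scale and independent replicate draws sharing one ground truth.  This is
the right structure for validating estimators (round-trip identity,
bias, information limits) but deliberately omits features of real plates:
heteroscedastic and correlated well noise, dispensing errors in the
concentration axis, ligand depletion at high receptor density, plate-edge
drift, and slow-equilibration artifacts in "equilibrium" reads.  Passing
tests therefore demonstrate correctness of the analysis, not robustness
to assay pathology.  No within-assay noise magnitude is asserted by the
source data (mean ± SEM only), so the noise sd is a free configuration
parameter throughout.

## Reporting conventions

Stored values keep full precision; display rounding (pK values to 2
decimals, Ki to 3 significant figures, kon as ×10⁶) happens only at report
boundaries.  Derived quantities in compound records (Ki from pKi, RT from
koff, pKd from kon/koff) are always recomputed from the stored constants,
never copied, so the record invariants hold to machine precision.  The
three-way affinity agreement flag marks a compound whose available
pKi/pKd/pKB estimates span less than 0.5 log units.  Reciprocal-of-mean
versus mean-of-reciprocals matters at this precision: 1/0.046 min⁻¹ gives
RT 21.7 min while replicate-level averaging of RT can legitimately differ
(e.g. a reported 22.1 ± 1.0), and records carry provenance rather than
reconciling such pairs.

## Known limitations

- The kinetic fitter assumes the tracer constants exactly; errors in k1/k2
  propagate unexamined into k3/k4.
- MBAR standard errors assume uncorrelated samples; the toy generators
  satisfy this, real trajectories would need statistical-inefficiency
  subsampling first.
- The Schild machinery assumes surmountable competitive antagonism;
  insurmountable or hemi-equilibrium behavior is out of scope.
- The half-life "initial linear range" rule can bias t½ when depletion is
  biphasic; only single-exponential depletion is modeled.
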