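# Methods notes

## Kinetic model

The two-tissue compartment model treats arterial plasma and regional tissue
as exchanging compartments with rates K1 (mL/cm³/min, plasma → tissue), k2
(tissue → plasma), k3/k4 (exchange with the specifically bound pool, 1/min).
The tissue impulse response is a sum of two exponentials with rates
α₁,₂ = (a ∓ √(a² − 4·k2·k4))/2, a = k2 + k3 + k4; the discriminant is
non-negative for any non-negative rates.  The measured signal mixes tissue
and whole blood through the fractional blood volume Vb, and frame values are
time averages of the continuous signal over each frame.  The reported
macro-parameter is V_T = (K1/k2)(1 + k3/k4), the equilibrium tissue/plasma
ratio; it is strictly increasing in K1 and in k3/k4.

**Numerics.** The input function is represented piecewise-linearly on a 1 s
grid.  The convolution of an exponential with a piecewise-linear input has a
closed form on each segment, so the forward curve is evaluated by an exact
linear recursion (`scipy.signal.lfilter`) rather than a quadrature rule; the
solution therefore agrees with a stiff ODE integration of the same system to
better than 1e-6 relative (the residual error is the ODE solver's own).  A
double root of the rate polynomial (measure-zero in the parameter space) is
handled by flooring the root separation at 1e-8·a, giving ~1e-8 relative
error there.  Frame averages come from the cumulative trapezoid of the fine
grid, which is exact at the grid resolution.

**Fitting.** Weighted bounded least squares (`scipy.optimize.least_squares`,
TRF) over (K1, k2, k3, k4, Vb) with conventional PET bounds
K1, k2, k3, k4 ∈ [1e-4, 2], Vb ∈ [0, 0.2], from a fixed 8-point multi-start
grid spanning decade ranges of the fast rates; the best restart is returned
and non-convergence is flagged, never silent.  Frame weights are uniform by
default; √duration weighting is available.  No delay/dispersion correction is
applied — blood and tissue clocks are assumed aligned.  Weighting, bounds and
starting values are design choices of this package; they are not dictated by
the analysis design the package implements.

## Quality control

Outliers are cells beyond the pooled whole-sample mean ± k·SD of their ROI
column (k = 3 by default; sample SD, n − 1 denominator — a choice, since only
"3 standard deviations" is specified).  A zero-variance column flags nothing.
The exclusion rule is a closed comparison ("at least 50%"), applied to the
stacked V_T | K1 | Vb masks because all three parameters are screened;
imputation applies only to the network input (V_T).  The donor pool for a
flagged cell is every *other* participant's unflagged value in that column —
restricting donors to unflagged values prevents one outlier from
contaminating another's replacement, at the cost of a slightly smaller donor
pool.  Re-running detection on an imputed table flags no new cells at the
imputed positions.

## Perturbation covariance networks

Partial correlations residualise each ROI column on an intercept plus the
covariates by OLS (age mean-centred, sex coded 0/1) and correlate the
residuals; this equals the inverse-covariance definition per edge.  The
perturbed network refits the covariate regression on the stacked n+1 sample
(freezing the reference coefficients is available behind a flag).  The
z-score uses the *reference* network's PCC in the denominator
σ = (1 − PCC²)/(n − 1), reading the variance expression as a single fraction;
the alternative (perturbed-network PCC) is nearly identical at these sample
sizes but the reference convention is the established one for this method.
For reference-group members the reference is rebuilt on the remaining n − 1
participants, the full-group network plays the perturbed role, and σ uses
n − 1.  The large-sample approximation behind σ is considered safe from about
n ≈ 28; with smaller reference groups the code warns and proceeds.

Edge summaries: `whole_brain` takes the 253 strictly-lower-triangular entries
(each undirected edge once), `hippocampus` the 22 edges incident to the
hippocampus.  The extreme-deviation proportion per ROI is the fraction of its
22 incident edges with |Z| above a critical value, 1.96 by default (two-sided
α = 0.05; the threshold is a documented default, not a given).

## Group inference

The permutation test shuffles **participant** labels, keeping each
participant's edge vector intact, because edges within a participant are
strongly dependent; the observed statistic is the difference of pooled-edge
means (equivalently, of participant-mean averages).  Two-sided
p = (1 + #{|T*| ≥ |T|})/(n_perm + 1), never below 1/(n_perm + 1); 1000
permutations by default, exact enumeration available for tiny groups.
Cohen's d is computed on the pooled edge values (pooled-SD denominator,
n_a + n_b − 2).  One caveat is intrinsic to the design: every participant's
Z derives from the same reference sample, so the vectors are not perfectly
exchangeable between the jackknife (control) and perturbation (patient)
constructions.  In simulation this costs mild anti-conservatism — type-I
error ≈ 0.06 at α = 0.05 at study sample sizes (estimated over 1000 null
cohorts) — and a studentized statistic does not materially change it, so the
simpler mean-difference statistic is kept.

The conventional battery: one-way ANCOVA via OLS with Type II sums of
squares (df_den = N − groups − covariates); a split-plot mixed ANOVA
implemented as multivariate OLS on orthonormal within-subject contrasts with
trace F tests, so between-subject covariates are supported — between-group
df (g − 1, N − g − c), interaction df ((g − 1)(r − 1), (N − g − c)(r − 1)).
Greenhouse–Geisser ε comes from the residual SSP of the contrasts
(ε ≈ 1 under compound symmetry) and scales both degrees of freedom for p_GG.
Effect sizes are generalised eta squared: effect SS over effect SS plus all
error SS.  χ² independence is Pearson's without continuity correction;
correlations are Pearson or residualisation-based partial correlations with
t-based p on n − 2 − k df; multiplicity correction is Holm (step-down) or
Bonferroni.  Where an established implementation exists (statsmodels OLS /
anova_lm / multipletests, scipy chi2_contingency and pearsonr) it is used
behind the module surface; the mixed ANOVA is implemented here because no
installed package supports between-subject covariates in that design, and it
is cross-checked against pingouin in the covariate-free case.

## Synthetic cohorts — what they emulate and what they do not

The generator reproduces the *statistical* structure the analysis assumes:
three groups (HC n=23, CHRp n=22, FEP n=10), group demographics (age
means/SDs 25.1/4.5, 25.1/4.6, 29.0/3.6 truncated to the 18–40 eligibility
window, which shifts means up ~0.5 y; female proportions 14/23, 15/22, 3/10),
symptom scores, and regional V_T drawn per group from a multivariate normal.
Patient-group covariance is shrunk toward independence by
σ′ = (1 − λ)σ + λ·diag(σ) — diagonal preserved, off-diagonals scaled — with
defaults λ = 0.15 (CHRp) and 0.35 (FEP), a graded covariance reduction.

The mean V_T vector and covariance are **synthetic**: per-ROI means are
literature-plausible for a benzodiazepine-site tracer (hippocampus largest at
6.0 mL/cm³, brain stem smallest at 1.6) with a 12% between-subject CV and a
uniform inter-regional correlation of 0.8.  The high correlation reflects
that between-subject V_T variation is dominated by shared tracer delivery
and plasma clearance and that several ROIs are overlapping composites
(whole-brain contains every other region); it also makes a λ = 0.3 shrinkage
a perturbation the method should detect at these sample sizes, which the
calibration suite verifies.  Age/sex effects on V_T default to zero and are
opt-in for covariate-adjustment tests.

TACs come from the 2TCM forward model on the 70.5-minute schedule
(15 s × 10, 60 s × 3, 120 s × 5, 300 s × 11 — the frame list is taken as
authoritative over a nominal 70 min) with zero-mean Gaussian frame noise of
SD = noise_fraction × frame value (duration weighting opt-in).  The input
function is a Feng-type curve: linear rise to a single early peak, then a
normalised multi-exponential decay; whole blood is parent divided by a
constant plasma-to-blood ratio.  Rate constants driving a TAC are derived
from the sampled V_T by fixing K1, k3, k4 and solving for k2.

Not emulated: image formation (reconstruction, attenuation, motion, partial
volume), metabolite kinetics, delay/dispersion of the input, radioactive
decay, non-Gaussian count noise, and any spatial structure beyond the ROI
covariance.  Passing tests therefore demonstrate the correctness and
calibration of the *analysis chain* under its own assumptions, not robustness
to acquisition physics.

## Reproducibility

Every generator and test is a pure function of (config, seed).  The pipeline
splits one global seed into per-stage substreams (`numpy` `SeedSequence`
children indexed by stage), so changing the permutation count does not
perturb the simulation draws; reruns are byte-identical.  Tables are written
with `%.17g` floats and read with round-trip parsing, so artifacts reload to
the exact binary values.  Problem sizes in the calibration suites (400 null
cohorts, 100 shrinkage cohorts, 50 noisy-fit replicates, 100 forward-model
draws) were chosen to keep Monte-Carlo standard errors small relative to the
property bands being checked.

## Known limitations

- The reference-derived-metrics caveat above: inference comparing groups on
  statistics built from the control sample is mildly anti-conservative.
- The 2TCM fit assumes a noise-free, delay-free input function.
- The mixed ANOVA treats covariates as between-subject only (no
  covariate × region interaction), matching the "covariates of no interest"
  design.
- Mean imputation shrinks column variance slightly; with the observed
  outlier rates (a few cells per cohort) the effect is negligible.
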