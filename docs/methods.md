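# Methods

## Decay-chain model

The default chain is the two-member reduction ²²⁵Ac → ²¹³Bi. ²¹⁷At
(sub-second half-life) is merged into its feeding edge — it is irrelevant at
the minute resolution of gamma counting — and the chain stops at ²¹³Bi
because nothing below it is measured in the 380–520 keV window. ²²¹Fr
(t½ = 4.8 min, 170–270 keV window) equilibrates with ²²⁵Ac within ~25 min
and is used only as the equilibrium proxy for the parent in biodistribution
counting. Half-lives default to 10 d (²²⁵Ac), 4.8 min (²²¹Fr) and 45.6 min
(²¹³Bi); a YAML nuclide table can override them with evaluated-data values.

The ingrowth model treats the parent activity A₁ as constant over the
measurement. Over an 18 h count ²²⁵Ac decays by ~0.5%; the effect is
absorbed into the fitted asymptote and is far below the counting noise of
real series. For cases where parent decay matters, `bateman_activities`
solves the full chain analytically: atom numbers are sums of exponentials
whose coefficients are built recursively down the (acyclic, branching)
chain. Coincident decay constants are separated by a 1e-9 relative
perturbation instead of implementing the confluent limit; the induced error
is below 1e-6 relative, verified against ODE integration. Internally
`Nuclide` stores half-lives in seconds; counting schedules and CSV
interfaces use minutes, the unit of recorded gamma-counter cycles.

## Ingrowth fitting and the ratio statistic

With λ₂ fixed, A₂(t) = A₁(1−e^{−λ₂t}) + A₂(0)e^{−λ₂t} is linear in
(A₁, A₂(0)), so the fit is the exact weighted linear least-squares solution
of the two-column design [1−e^{−λ₂t}, e^{−λ₂t}]. Standard errors come from
the normal-equations covariance scaled by the residual variance (n−2
degrees of freedom). The default is unweighted least squares; `poisson`
weighting (1/max(y, 1)) is available when values are raw counts. A design
whose singular-value ratio falls below 1e-10 (all points near t = 0, or all
far beyond 1/λ₂) raises a conditioning error; a span shorter than 2/λ₂
warns that the asymptote is poorly constrained. Negative fitted A₂(0) —
possible under noise when the true value is near zero — is reported as-is
with a warning rather than clipped, so group means stay unbiased.

The ratio A₂(0)/A₁ carries a first-order delta-method standard error using
the full fit covariance. Its classification band around 1 (releasing /
neutral / accumulating) defaults to zero width and is configurable. When
the equilibrium amplitude is not positive (an organ with essentially no
carrier), the ratio is undefined and the back-extrapolated A₂(0) alone is
the meaningful quantity; the cohort table marks such rows `undefined`.

Two group-aggregation conventions are exposed because they genuinely
differ: the default averages per-animal ratios (tying the quoted SD to
between-mouse variation); `pooled` divides the group-mean amplitudes.
Equilibrium is operationalised as the fitted asymptote, not a late
measurement; a late-window mean would estimate the same quantity with more
variance. Group comparisons use the closed-form t statistic with the
Student's-t CDF; the default is unpaired Welch (animal groups are
independent), with `student` (pooled variance) and `paired` modes available
for reproducing legacy analyses.

## Biodistribution

%ID/g = 100 · (sample rate / full-injected-dose rate) / organ mass, with
the full-ID rate derived from a counted aliquot standard of known fraction,
and decay correction to the standard's reference time using the parent λ
(equilibrium windows track the parent). Dose standards are mandatory
inputs: there is no meaningful %ID normalisation without them, and the
synthetic generator always emits one per animal. Blood is treated as an
organ sample by mass, with no total-blood-volume extrapolation.

## Survival analysis

Tumour volume uses the ellipsoid formula V = (π/6)·W·L·H. Relative growth
is normalised to the baseline (treatment) day; the doubling event is the
first measured day at or above 2× baseline, regardless of later regression.
The survival event is the first measurement day with V > 2000 mm³ (no
interpolation between twice-weekly measurements); other endpoints are
censored. Kaplan–Meier estimation is delegated to lifelines; the Mantel–Cox
log-rank statistic is computed directly from the pooled risk sets (O−E with
the hypergeometric variance and standard pooled treatment of ties, p from
χ²₁) and is cross-checked against lifelines in the test suite. Multiplicity
over G groups is handled with a manually computed Bonferroni threshold
α / C(G,2).

A calibration note: with 8 animals per group the χ² approximation to the
log-rank null is slightly anticonservative (empirical type-I error ≈ 0.06
at nominal 0.05 in the simulation tests). This is a property of the test at
small sample sizes, not of the implementation, which agrees with lifelines
to 1e-8.

## Synthetic data generator

The generator emulates the study design it is meant to validate:

- **Carrier biodistribution.** Group-mean equilibrium %ID/g per organ; the
  default intravenous groups use blood/spleen/kidney means of
  17.9/86/4.7 (chelated) and 8.8/69/2.6 (co-precipitated), with the
  remaining injected dose assigned to a rest-of-body compartment so the
  total closes at 100 %ID.
- **Redistribution.** A single-shot model: each organ releases a fixed
  fraction of its equilibrium daughter activity into a common pool, which
  splits 40% to the kidneys, 30% to urine and 30% to the rest of the body —
  the accepted fate of free ²¹³Bi. Release fractions default to 0.94
  (blood), 0.33/0.36 (spleen) and 0 (kidney), chosen so the downstream
  ratios land near 0.06 / 0.67 / 0.64 and several-fold kidney accumulation.
  Mass-weighted activity is conserved exactly; urine and rest-of-body are
  tracked but emit no counting series. No kinetic rates for free-daughter
  transport are modelled — the redistribution is instantaneous at a single
  effective time, which is the main abstraction separating the generator
  from real physiology.
- **Counting.** Whole-organ expected activity follows the ingrowth curve;
  observed values are Poisson with mean (activity × counts-per-unit +
  background) on a 10-min/18 h schedule. Default counts-per-unit is 200 per
  %ID, putting equilibrium counts in the 10³–10⁴ range typical of a well
  counter; `counts_per_unit=None` is the exact noise-free mode. A per-animal
  lognormal factor (CV 0.15 by default) models between-mouse variation;
  activities are positive and right-skewed, hence lognormal rather than
  normal.
- **Tumour growth.** V(t) = V₀e^{gt} from V₀ = 100 mm³ (the treatment
  trigger volume) with per-animal lognormal g (median doubling 18 d
  untreated, CV 0.5), an optional spontaneous-regression switch
  (probability 0.25, switch day uniform on 14–60 d, growth mirrored), a
  treatment effect as a growth-rate multiplier, caliper readings as
  sphere-equivalent diameters twice weekly, and censoring at day 115.

What passing tests show — and don't. Truth-recovery and calibration tests
demonstrate that the inference machinery is exact on model-generated data
and unbiased under Poisson noise at realistic count scales. They cannot
certify behaviour under features the generator omits: detector dead-time
and background drift, incomplete organ collection, non-instantaneous
redistribution kinetics, or tumour growth that is not piecewise
exponential.

## Problem sizes and numerical choices

Simulation-based tests use 100–1000 replicates at the study's group sizes
(5 animals for retention, 8 for efficacy), sizes at which every statistical
check resolves its target comfortably. All generators take explicit seeds
and are bit-reproducible; fits are direct linear algebra with no
initialisation or iteration; brute-force optimiser comparisons use
Nelder–Mead at tight tolerances purely as an independent oracle.

## Known limitations

- The ratio statistic is scale-invariant, but absolute activities (Bq)
  would require a detector-efficiency factor the workflow does not model.
- The ²²¹Fr distribution at sacrifice is not inferable from this design
  (its 4.8 min half-life decays it away before counting can begin) and is
  deliberately out of scope.
- The default chain ignores branching below ²¹³Bi (²¹³Po/²⁰⁹Tl); configure
  an explicit chain if those members matter.
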