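# Methods

## Signal path: forces to CoP

Each balance board reports vertical force at four corner sensors (TL, TR,
BL, BR; "top" anterior, "right" lateral-positive). The board CoP is the
moment-balance solution over the sensor rectangle,

    AP = (L/2) · [(F_TL + F_TR) − (F_BL + F_BR)] / F_total
    ML = (W/2) · [(F_TR + F_BR) − (F_TL + F_BL)] / F_total

with sensor spacings L × W defaulting to 433 mm × 228 mm (the consumer
board this pipeline targets; both are configuration, not code). Dimensions,
per-board lateral offsets (defaults ±114 mm, i.e. boards touching at the
midline), the filter window and the force floor are all settable via
`TrialConfig` / YAML.

Raw force channels are smoothed with a centered moving average (default 15
points at 100 Hz). The window shrinks symmetrically at the boundaries, which
preserves length and introduces no phase shift. Filtering acts on the force
channels, not the CoP; a `filter_forces=False` switch applies the same
filter to the combined CoP instead, for sensitivity analyses — no claim is
made that either ordering is uniquely correct, and for slowly varying loads
they differ little.

The two boards combine by instantaneous force weighting: each board's ML
coordinate is shifted by its offset, then the net CoP is the per-sample
weighted mean with weights proportional to each board's share of the total
vertical force. This is algebraically identical to treating all eight
sensors as one virtual plate (verified to 1e-9 mm in tests). Samples whose
total force falls at or below the force floor (default 1 N) raise a
degenerate-load error naming the sample, since CoP is undefined without
load.

Axis conventions: AP positive anterior, ML positive to the subject's right,
millimetres throughout, time origin at the first sample.

## Sway metrics

For a trace of N samples at f_s Hz, trial duration is (N−1)/f_s, so a
straight path of length ℓ yields mean velocity exactly ℓ/duration. Range is
max−min per axis; RMS is taken about the per-trial mean (not zero — the
mean CoP position is arbitrary); per-axis velocity is the sum of absolute
successive differences over duration; VSM velocity uses Euclidean step
lengths √(Δap² + Δml²). No detrending beyond the implicit demeaning, no
resampling, no sub-epochs: one 30 s window per condition, as in the
screening protocol this mirrors.

These definitions imply invariants the test suite enforces on arbitrary
traces: translation invariance, scale equivariance, time-reversal
invariance, rms ≤ range per axis, and the triangle inequality
max(v_ap, v_ml) ≤ v_vsm ≤ v_ap + v_ml.

Romberg Quotients are per-subject EC/EO ratios; a denominator below 1e-9 mm
(or mm/s) marks the ratio missing rather than zero or infinite. Percent
increases are averaged per subject (mean of percentages), never computed
from group means.

## Statistical routing

Normality is screened with Shapiro–Wilk at α = 0.05. Condition comparisons
(EO vs EC) test the paired differences — the quantity the paired t-test
actually assumes normal — and route to the paired t-test or the Wilcoxon
signed-rank test. Group comparisons route to Mann–Whitney U unless both
groups pass Shapiro–Wilk, in which case Levene's test selects the pooled or
Welch t-test. Rank tests use exact p-values for n ≤ 25 without ties and the
tie-corrected normal approximation otherwise. All tests are two-sided; no
multiple-testing correction is applied (each variable is screened at its
own α, and the report notes this). Every result records the route taken so
the convention is auditable. Constant samples are treated as consistent
with normality for routing (Shapiro–Wilk is undefined there) and produce
p = 1 under any route.

Under Gaussian nulls the routed procedures hold their nominal 5% type-I
error (checked at 2000 seeded replicates within two Monte-Carlo standard
errors). For the hardest contrast in the reference design — 6 multi-fallers
against 47 non-fallers with means 22.06 vs 15.11 and SDs 11.31 vs 5.59 —
the measured two-sided power is ≈ 0.4 at α = 0.05: real but limited, which
is why that contrast's significant-variable set varies between synthetic
cohorts.

## Cut-off constructions

**Clinical cut-off.** c = (σ_n μ_c + σ_c μ_n)/(σ_n + σ_c). The threshold
lies weakly between the group means, is symmetric under swapping the
groups, and is affine-equivariant in the measurement scale. Group SDs must
be positive.

**ROC at constrained sensitivity.** Candidate thresholds are the midpoints
between consecutive sorted unique scores plus one sentinel beyond each
extreme; classification is strict inequality on the stated side, so
boundary equality is non-faller. Among candidates with sensitivity ≥ 0.80
(a screening context prioritises catching fallers), the one with maximal
specificity wins; ties break toward the threshold closest to the faller
group. The sentinel classifying everyone as faller guarantees an admissible
candidate. AUC is the trapezoid over the full sweep and equals the
faller/non-faller pairwise concordance with ties counted one half (tested
against brute-force enumeration and against scikit-learn).

**Linear discriminant.** Two-class Fisher LDA: w ∝ S_w⁻¹(μ_f − μ_n) with
pooled within-group covariance S_w, rescaled to unit pooled within-group
score variance and centred so the grand-mean training score is zero (the
convention under which published discriminant coefficients of this kind are
printed). The cut-off is the centroid midpoint — with equal priors, the
equal-Mahalanobis-distance boundary; class imbalance is deliberately
handled by this convention rather than by priors. Features enter on their
raw scales by default (coefficient magnitudes then remain interpretable per
unit of each measure). A pooled covariance with condition number above 1e12
raises a collinearity error naming the features loading on the degenerate
direction. Reports display thresholds at 2–3 decimals; internal precision
is full.

Performance is resubstitution (training-set) performance throughout, as in
the reference tables; no cross-validation is attempted — with 6 subjects in
the smallest group, sensitivity is quantised to sevenths and out-of-sample
estimates would be noise.

## Cohort analysis

`FallRiskModel.fit()` labels groups from fall counts (prospective groups
require complete follow-up; retrospective fallers are excluded from
PF/PSF/PMF/PNF because a known fall history already marks risk and may
alter sway), compares EO vs EC within each prospective group, screens EO,
EC and RQ variables in the fixed contrasts PAF/PNF, PF/PNF, PSF/PNF,
PMF/PNF and RF/RNF, and fits all three cut-off constructions to every
variable with p < α (the discriminant over all of them jointly). The
faller side of each univariate rule is the side of the faller group's mean.
Contrasts with no significant variables, or groups too small to fit, are
skipped with a logged warning. Subjects missing a condition are excluded
and listed with reasons; every input subject appears exactly once in the
analysis or the exclusion log. The whole bundle is deterministic given the
cohort and settings.

## Synthetic cohorts

The generator's defaults are the study conditions: group sizes 47/42/28/
22/6 prospective plus 24 retrospective fallers (of whom 14 fell again
during follow-up, reconciling 28 prospective fallers among retrospective
non-fallers with 42 prospective fallers overall), one subject lost to
follow-up, and group-conditional metric distributions parameterised by the
published mean ± SD per metric and condition. Only mean and SD are
published, so generation assumes (truncated) normality; demographics are
carried as metadata and do not shape the sway draws. Retrospective fallers
have no published sway profile of their own and reuse the non-faller (or,
for those who fell prospectively, the all-faller) profile.

Metric-level sampling draws a 14-dimensional equicorrelated Gaussian per
subject (default correlation 0.5 between all metric pairs, within and
across conditions — steadier subjects are steadier throughout; configurable
0–0.9). Metric-set invariants are enforced by redrawing only a violating
component from its exact truncated-normal conditional on the feasible
interval: non-negativity for ranges and velocities, [0, range] for RMS, the
triangle band for VSM velocity. Unconstrained marginals therefore keep
exactly their profile mean and SD (the non-faller EC AP velocity reproduces
its generating 15.11 ± 5.59 within 2%/5% at n = 10⁴); VSM velocity, living
on a narrow subject-specific band, drifts a few percent, and profiles whose
mean sits within about one SD of zero (the all-faller EC velocities)
inherit the upward shift that zero-truncation of such a normal implies. A
warning fires if any other component needs constrained resampling in more
than a quarter of draws.

Romberg Quotients of synthetic subjects are computed from their sampled
EO/EC pairs, so group RQ statistics drift from the published RQ table
(mean-of-ratios versus ratio-of-means). For calibrating the cut-off
estimators against known generating parameters, `sample_rq_groups` draws RQ
vectors directly from the published RQ profiles; clinical cut-offs fitted
to 5000-per-group draws recover the generating-parameter values within 2%
(the residual is the zero-truncation shift, well under that band).

Trace-level simulation exists to exercise the force→CoP→metrics plumbing
end to end, not to claim physiological realism: per axis an
Ornstein–Uhlenbeck process (exact discretisation, stationary start;
diffusion σ in mm/√s, reversion θ in 1/s), eyes closed multiplying the
diffusion scale. Calibration pins σ from the target mean velocity (the mean
absolute increment of the discrete process is known in closed form), the EC
multiplier from the EC/EO velocity ratio, and θ from a 200-point log-grid
minimising the joint log-error of the expected within-trial RMS under both
conditions (also closed form). A single-timescale process sampled at 100 Hz
cannot reach both the published velocities and the published amplitudes:
velocity pins the increment scale, and even in the random-walk limit the
within-trial RMS of such a path tops out well below some EC amplitude
targets. Calibration therefore matches velocities essentially exactly and
reports the amplitude shortfall in a `CalibrationReport` (15% tolerance)
rather than hiding it; real sway separates a slow drift from fast
corrective activity, which a one-timescale model cannot. Rendering traces
to forces keeps each board's local CoP at (ap, 0) and produces net ML sway
by redistributing load between the boards — which is also how ML sway
arises physically — and inverts the unfiltered pipeline exactly.

What passing tests on synthetic cohorts do **not** show: that the published
effect sizes, p-values, AUCs or accuracies hold on real cohorts (those
depend on the unreleased recordings); that sway is Gaussian or
equicorrelated; or that the OU traces are physiologically realistic.

## Problem sizes and numerical choices

The test suite runs the type-I-error checks at 2000 replicates, recovery
checks at 5000 subjects per group, generator calibration checks at 10⁴
draws, and OU property checks at 100–200 replicates of 30 s × 100 Hz paths
— sizes at which Monte-Carlo error is comfortably inside each asserted
band. Sampling-rate validation of force files tolerates 1% timing jitter.
Equality at a decision boundary always classifies non-faller. Seeds are
explicit everywhere randomness exists; identical seeds reproduce cohorts,
traces and report bundles bit for bit.

## Known limitations

- Published group statistics, not raw recordings, anchor the generator;
  cohort-specific quantities (p-values, AUCs, discriminant coefficients)
  are reproduced in structure, not in value.
- The generator's truncated-normal assumption is untestable against the
  source data beyond mean ± SD.
- The OU trace generator underproduces sway amplitude at matched velocity
  (single timescale); use metric-level sampling for calibrated work.
- ROC thresholds from 6-subject faller groups are quantised and fragile;
  the sensitivity floor dominates their placement.
- No multiple-testing correction: with 21 variables per contrast screened
  at α = 0.05, occasional spurious cut-off variables on null contrasts are
  expected and visible in synthetic runs.
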