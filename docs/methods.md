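# Methods

This note documents the models, conventions and numerical choices behind
`irapfast`, in the order data flow through the pipeline.

## Scoring conventions

**Latency definition.** An IRAP trial carries a single latency: the time
from trial onset to emission of the *correct* response, so error trials
include the error-correction time. First-response accuracy is stored
separately and is used only by the practice gate.

**Boundary semantics.** All thresholds are read literally from their
wording: the trial filter removes latencies strictly *above* 10,000 ms
(exactly 10,000 is retained); the fast-responder rule excludes a participant
when strictly *more than* 10% of test trials are under 300 ms; the practice
accuracy criterion is inclusive (≥ 80%); the practice median-latency
criterion is strict (< 2000 ms). The median of an even-sized block is the
mean of the two central order statistics.

**Order of operations.** Practice latencies are discarded first, the 10 s
trial filter runs second, the fast-responder participant check third,
scoring last. The fast-responder proportion is computed over *all* test
trials, before the 10 s filter: "test-block trials" most plainly means all
of them. The test suite asserts on its fixtures that applying the two
filters in either order excludes the same participants, so the choice is a
documented convention rather than a behavioural fork.

**Standard deviation.** D scores use the sample (n−1) standard deviation,
the convention of the D-score family this statistic descends from
(Greenwald-style IAT D scores). The source description does not pin this
down; scale invariance of D makes the choice a fixed convention, not a
tuning knob.

**Cumulative records.** The count at trial i includes trial i
(right-closed). Slopes are OLS on trial order 1..50; the intercept is
estimated and discarded. Slope is invariant to shifting the trial index, so
regressing on 0..49 would change nothing.

**KSOG.** Missing cells are dropped from the mean, not imputed; an
all-missing grid propagates a missing score, and the number of cells used
is reported alongside. The scorer enforces ratings in [1, 7]. (Published
summaries of this instrument occasionally print group minima below the
scale floor of 1; no transformation producing such values is documented
anywhere we know of, so the scorer deliberately refuses them.)

## Inference

**Rank-sum battery.** W is the Mann–Whitney pair count for the straight
group with ties half-weighted; r = W/(n₁n₂). This direction convention is
what makes r coincide with Vargha–Delaney's A and with the ROC AUC under
the controls-above-cases direction; the identity chain r = A = AUC,
δ = 2A − 1 is asserted in the tests. The p value is exact (enumeration) for
combined n ≤ 25 without ties — mirroring the common default of R's
`wilcox.test` — and otherwise a tie-corrected normal approximation with
continuity correction.

**Split-plot ANOVA.** The repeated-measures analysis of the four trial-type
D scores is the classical two-stratum decomposition: orientation is tested
against subjects-within-groups on (1, N−2) df, trial-type and the
interaction against the within-subject residual on (3, 3(N−2)) df. For
complete data these F tests coincide with the REML random-intercept mixed
model's Type III tests; with unequal group sizes the within-stratum terms
use unweighted (Type III, sum-to-zero) sums of squares, which the suite
verifies against an OLS Type III oracle and which matches `lmerTest`-style
output. Incomplete data are rejected with an explicit message rather than
approximated, because the equivalence breaks there.

**Contrasts.** Within-group trial-type contrasts use the residual mean
square and Tukey adjustment over the family of four measures (studentized
range). Between-group per-trial-type contrasts and the cell-mean confidence
intervals combine the two error strata, (MS_subject + (m−1)·MS_residual)/m,
with Satterthwaite df; the CI family is Bonferroni-adjusted for the eight
cell means. This is an approximation to Kenward–Roger df, accurate to a few
df at this design size; inference is insensitive to the difference.

**ROC and DeLong.** The AUC is the tie-half-weighted pair count U/(n₁n₂),
identical to the trapezoid area over the full threshold sweep (asserted).
Variances use DeLong's structural components. Curves built on the *same*
participants are compared with the paired normal z using the components
covariance; curves on different participant subsets (averaged D on the
IRAP-eligible subset vs slope differences on everyone) cannot be paired, so
the statistic uses the two independent variances with a Welch–Satterthwaite
fractional df, each variance weighted by its sample size minus one. The
inverted female-picture predictor is handled by sign-flipping the scores,
which is AUC-equivalent to swapping the case/control roles.

**Power sensitivity.** The minimal detectable effect is found by Brent
bisection on the monotone power function to |power − target| ≤ 1e−8 in the
effect. Two-sample t: noncentral t with df = n₁+n₂−2 and noncentrality
d·√(n₁n₂/(n₁+n₂)). Within–between interaction: noncentral F with
df₁ = (g−1)(m−1)ε, df₂ = (N−g)(m−1)ε and λ = f²·N·m·ε/(1−ρ) — the
"as in SPSS" G*Power convention, with defaults ρ = 0.5, ε = 1. Under
exactly this convention the design N = 48, g = 2, m = 4 yields f = 0.17
(η²p = 0.028), and n = 28/20 yields d = 0.84. Conversions published
alongside such sensitivity statements that mix f-to-d rules of thumb are
not reproduced here: the plain algebraic conversions give different values,
and guessing the intermediate convention would be arbitrary. scipy's
noncentral-t survival function returns NaN at extreme noncentrality; the
power function falls back to the asymptotic normal approximation there,
which only matters far above any minimal detectable effect.

## The synthetic cohort generator

The generator emulates the study conditions: 33 straight and 25 lesbian
participants; IRAP sessions with up to three practice block-pairs and
exactly three test pairs of two 24-trial blocks (four trial-types six times
each, randomized within block, block order alternating from a per-participant
random start); FAST with one 16-trial practice block and two 50-trial test
blocks in random order; full 7 × 3 KSOG grids with four lesbian grids
generated as missing.

**Latency model.** log-latency = base + participant intercept + increment +
noise, with the increment applied in the history-incoherent block (the
lesbian-rule block for straight participants, the straight-rule block for
lesbian participants), parameterized per trial-type and per orientation,
plus a participant-level shift common to all trial-types. Latencies are
log-normal because response times are right-skewed; since D is scale- and
shift-invariant, the base (1500 ms median) and intercept SD (0.15) are
cosmetic and only the increments (relative to the residual log-SD of 0.25)
and the participant shift SD drive the D-score moments. A small fraction of
trials (1%) is replaced by a >10 s latency to exercise the trial filter;
a configurable fraction of participants emits many sub-300 ms latencies to
exercise the participant filter (0 by default).

**Practice gate.** Pair-level pass/fail is drawn as a Bernoulli
(default per-pair failure 0.557 = (10/58)^(1/3), so ~10 of 58 participants
fail all three attempts) and then *realized* in the trial data: passing
blocks are built with ≥ 20/24 correct and median < 2000 ms, failing blocks
with ≤ 19/24 correct. The gate logic itself is tested against explicitly
constructed accuracy/latency patterns; the generator only needs the
cohort-level rate to be emulatable, and the suite verifies that re-scoring
the generated practice data reproduces the intended eligibility exactly.

**FAST model.** P(correct at trial t) = p∞ − (p∞ − p₀)e^(−κt) with
p₀ = 0.35, p∞ = 0.95, an independent 2% timeout process forcing errors, a
per-orientation per-block κ, and an independent per-participant, per-block
log-normal κ multiplier (SD 0.6) that produces realistic between-participant
slope-difference spread. Starting below chance in the history-incoherent
block reflects prepotent responding from prior history.

**Calibration.** Defaults are moment-matched to the published group
summaries and frozen in `defaults.yaml`: per-trial-type increments matched
to the per-trial-type D means of both groups (via the measured ≈3.8 D units
per log-unit increment at residual SD 0.25), participant shift SDs (0.07 /
0.09) matched to the averaged-D group SDs, κ values solved from the expected
OLS slope of the expected cumulative record (lesbian group 0.633 / 0.430;
straight group 0.54 / 0.52 giving a mean slope difference near 0.02), and
KSOG latent group means/SDs on the 1–7 scale. At population scale the
generator reproduces averaged-D moments of ≈0.10 (0.32) and ≈−0.42 (0.35)
and an averaged-D group AUC of ≈0.87.

**What the generator does not model.** Stimulus-identity effects, inter-trial
dynamics, latency autocorrelation, practice-to-test learning carryover, and
any dependence between IRAP eligibility and the other measures. Passing the
calibration suite shows the pipeline recovers the moments this model
encodes; it does not validate the latency model against real response-time
distributions, which the study summaries do not constrain.

## Problem sizes in the validation suites

The stochastic suites run at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 2000 replicates for the null rejection-rate
check (binomial SE ≈ 0.005 at α = .05), 20 cohort seeds for the calibration
checks (SE of the mean AUC ≈ 0.01), 2000 bootstrap resamples for the DeLong
variance cross-check, and 10⁵ draws per group for the binormal AUC
simulation (SE < 0.002).

## Known limitations

- The split-plot route requires complete trial-type data; genuinely
  unbalanced repeated measures need a true mixed-model fit, out of scope.
- Exact rank-sum p values are only used for combined n ≤ 25 without ties;
  at the study's sizes the tie-corrected normal approximation is used, so
  p values near the exact/approximate switch may differ in the third
  decimal from enumeration.
- The unpaired DeLong df convention (variances weighted by n−1) is one of
  several Welch-style choices; statistics and p values are insensitive to
  the alternatives at these sizes.
- The generator's Bernoulli practice gate deliberately decouples practice
  failure from the latency model; correlations between eligibility and
  D-score magnitude cannot be studied with it.
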