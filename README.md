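# irapfast

Scoring and inference for two latency-based implicit measures of sexual
orientation in women: the **Implicit Relational Assessment Procedure (IRAP)**
and the **Function Acquisition Speed Test (FAST)**, alongside the **Klein
Sexual Orientation Grid (KSOG)** self-report. The package takes trial-level
task logs, produces the bespoke per-participant scores, and runs the full
group-discrimination battery — nonparametric and parametric two-group tests,
a mixed within–between ANOVA over IRAP trial-types, ROC/AUC analysis with
DeLong comparisons, and analytic power-sensitivity computations. A calibrated
synthetic cohort generator makes every stage testable without any external
data.

It is written for behavioural researchers who work with implicit-measure
task logs and want a scriptable, fully reproducible scoring pipeline.

## The measures and their scores

**IRAP.** Participants alternate between blocks whose response rule is
coherent with their learning history ("Straight woman" vs "Lesbian woman"
block rules) across four trial-types (male/female picture × positive/negative
word). Each trial records the latency from trial onset to the *correct*
response. After discarding practice blocks, dropping test latencies above
10,000 ms, and excluding participants with more than 10% of test trials
under 300 ms, the D score is computed per pair of test blocks *p* and
trial-type *t*:

    D_{p,t} = ( mean latency in lesbian-rule block − mean latency in straight-rule block ) / SD_{p,t}

where SD_{p,t} is the sample standard deviation of the latencies pooled over
both blocks of the pair for that trial-type. Averaging over the three pairs
gives four per-trial-type scores D_t, and averaging those gives D̄. Positive
scores mean faster responding under the straight-block rule. Eligibility
requires one practice pair (of at most three) with ≥ 80% first-response
accuracy and a median latency < 2000 ms in *both* blocks.

**FAST.** Two 50-trial feedback-driven test blocks teach key assignments
that either align or conflict with the participant's history. Each block's
cumulative record of correct responses y_i = #{j ≤ i : correct_j} is fitted
by ordinary least squares; the slope is the learning rate, and the score is

    slope difference = slope(straight-rule block) − slope(lesbian-rule block).

**KSOG.** 7 orientation components × 3 timeframes rated 1–7; the score is
the mean of the rated cells (1 = strictly heterosexual, 7 = strictly
homosexual).

**Inference.** The two-group battery reports Wilcoxon's rank-sum W (the
Mann–Whitney pair count for the straight group, ties half-weighted), the
effect estimator r = W/(n₁n₂), Cliff's δ, Vargha–Delaney A = (δ+1)/2,
Welch's t, and pooled-SD Cohen's d. On shared inputs r = A = AUC and
δ = 2A − 1 — identities the test suite asserts. The four trial-type scores
are analysed with the classical split-plot decomposition (equivalent, for
complete data, to the random-intercept mixed model ANOVA), with Tukey
within-group contrasts and Satterthwaite-df between-group contrasts. ROC
curves use the tie-corrected pair-count AUC and DeLong's structural
components for variances; curves from different participant subsets are
compared with a Welch-style fractional df. Sensitivity analyses invert the
noncentral-t and noncentral-F power functions by bisection.

## Worked example

```sh
irapfast run --synthetic --seed 7 --out out/
```

generates a 58-participant cohort (33 straight, 25 lesbian), scores it, and
writes the full bundle. On this seed the run log shows 6 participants
failing the practice gate, so the IRAP statistics use n = 52 while FAST uses
all 58 and KSOG 54 (four lesbian grids are generated as missing, mirroring
the study structure). `stats_report.json` then contains, e.g. for the
averaged D score:

```
"d_avg": { "w_statistic": 574.0, "r_estimator": 0.861, "cliffs_delta": 0.721,
           "vd_a": 0.861, "t_statistic": 5.998, "t_df": 33.485,
           "cohens_d": 1.776, "n_straight": 29, "n_lesbian": 23 }
```

i.e. the straight group out-scores the lesbian group in 86% of cross-group
pairs — the IRAP separates the groups strongly. `roc_report.json` shows
AUC = 0.861 for the averaged D and 0.841 for the FAST slope difference, and
their unpaired DeLong comparison (the two measures retain different
participant sets) is null: statistic 0.243 on 106.4 fractional df,
p = 0.809. The per-measure sensitivity block reports a minimal detectable
d of 0.798 at n = 29/23 and f = 0.164 for the 2 × 4 interaction.

`summary.md` renders the same numbers as tables, including the
picture-gender panel where female-picture trial-types are sign-flipped *for
display only* (straight group: pro-male bias +0.28; lesbian group:
pro-female bias +0.61 on this seed).

The command-line entry points are `irapfast simulate`, `run`, `score-irap`,
`score-fast`, `score-ksog`, `power`, `report`, and `stats`; every step is
also available as a library call (`irapfast.irap.score_cohort`,
`irapfast.stats.compare_groups`, `irapfast.roc.delong_test_unpaired`, ...).

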