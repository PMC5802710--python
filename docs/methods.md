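# Methods

## Cutoff behavioral criteria (CBC)

The classifier treats the untreated control group as the reference
("normal") population. For each configured measure j the control
values x₁..x_n give a nearest-rank percentile cutoff at level q:

- lower tail (`flag-low`): the order statistic at rank ⌈q·n⌉;
- upper tail (`flag-high`): the order statistic at rank n − ⌈q·n⌉ + 1.

An animal's measure is *deviant* when it lies beyond the cutoff, and an
animal is *affected* when at least k of its m measures are deviant.
Defaults: m = 7, q = 0.20, k = 4, matching standard CBC practice for
EPM data. Control animals are classified against cutoffs computed from
the full control group including themselves (no leave-one-out), and
cutoffs always come from the single designated control group, never
pooled with treated controls.

Conventions, chosen where the procedure's verbal description is
ambiguous and config-switchable:

- **Percentile estimator** — nearest rank rather than interpolation.
  Consequences: with no ties the flagged control fraction is exactly
  ⌈q·n⌉/n per measure, and flags are invariant under any strictly
  increasing transform of a measure (cutoffs are order statistics).
- **Tie handling** — comparisons are inclusive (≤ for lower tails,
  ≥ for upper), so the control animal defining a cutoff is itself
  flagged. A strict mode (`strict_comparison: true`) is available.
- **Constant control measures** — kept, with a warning: silently
  dropping a measure would change the k-of-m criterion. Under the
  inclusive rule such a measure flags every animal tying the constant;
  users who prefer to exclude it do so in the configuration.
- **Small reference groups** — cutoff derivation refuses control
  groups below `min_control_n` (default 10); tail percentiles from
  tiny samples are not meaningful.
- ⌈q·n⌉ is computed after rounding q·n to 10 decimal places so that
  decimal levels such as q = 0.2 behave exactly at n divisible by 5
  despite binary floating point.

The seven default measures (open-arm distance and duration, closed-arm
distance and duration, total distance, and the open/closed distance and
duration "anxiety indices", lower ratios = more anxious) are a
documented stand-in set: published CBC-on-EPM work describes its seven
parameters only as distance and duration measures. Any measure set can
be declared in the YAML configuration with per-measure tail directions.

Under measure independence the classifier's null false-positive rate is
the binomial tail Σ_{j≥k} C(m,j) q̃^j (1−q̃)^{m−j} with q̃ the
per-measure flag rate (`null_classification_rate`); for 7/4/0.2 this is
0.0333. Correlated measures raise it toward q as dependence grows.

## Goodness of fit and count inversion

Group affected:unaffected splits are tested with the two-category
Pearson statistic χ² = Σ (O − np)²/(np), df = 1, **without** Yates
continuity correction, against fixed reference proportions — the q-
derived 20:80 control norm by default, optionally a named baseline
group's empirical proportion rounded to two decimals (the pipeline's
`--baseline-group` second pass). The rounded form (0.35/0.65, not
11/31) is used deliberately: only the rounded reference reproduces the
published companion statistics, and the inversion suite verifies this.
The no-correction choice is likewise verifiable: applying Yates to the
recovered counts does not reproduce the published values (e.g. ≈3.73
instead of 4.65).

Because counts are integers, a χ² value printed to two decimals
usually determines the affected count uniquely at the printed group
size. `invert_gof` exhausts counts 0..n; `verify_reference_statistics`
(CLI: `epmcbc verify`) applies it to the published six-group table and
confirms the full cross-consistency chain, recovering counts
6/30, 1/12, 2/12, 11/31, 2/19, 7/12. p-values come from the
chi-squared survival function (erfc(√(x/2)) at df = 1).

## Averaged-group ANOVA

`anova_two_way` fits a fixed-effects two-way model with interaction via
OLS and reports Type III sums of squares with sum-to-zero contrasts —
the convention of mainstream commercial packages for unbalanced
factorial designs, which the six-group 2×3 layout (n = 30..12) is.
Types I and II are available (`ss_type`). The raw data behind published
group-mean F values are not available, so the SS type is a documented
convention rather than a verified reproduction. Degenerate fits (zero
residual variance) report F = 0 when the effect sum of squares is also
null-scale, ∞ otherwise; empty design cells and zero residual df are
refused. Bonferroni post hoc tests compare all level pairs of one
factor with t statistics on a pooled error term (the surrounding
two-way residual in the pipeline, the one-way pooled variance
otherwise), with adjusted p = min(1, m·p) over that factor's
comparisons only. No multiplicity adjustment is applied across the
per-group goodness-of-fit tests, matching how such per-group χ²
values are conventionally reported; a caller can apply one downstream
from `stats.json`.

## Synthetic cohorts

`generate_cohort` draws each measure log-normally with an
equicorrelated Gaussian copula: Zᵢ = √ρ·W + √(1−ρ)·Eᵢ per animal,
value = exp(μ + σZ). Each animal is affected with probability π;
affected animals' measures are multiplied (upper-tail measures) or
divided (lower-tail) by 1 + δ·w with per-measure weight w. All values
are strictly positive by construction. Randomness flows from one
counter-based Philox generator keyed by the seed, so cohorts are
bit-reproducible across platforms.

The EPM-shaped generator draws five base zone summaries — open-arm
distance/duration (weight 1), closed-arm distance/duration and center
distance (weight ½, with closed-arm duration rising in affected
animals) — and *derives* total distance (sum of distances) and the two
anxiety indices (exact open/closed quotients), so the seven default
measures carry the deterministic dependencies real EPM summaries have,
and all seven move toward their deviant tails for affected animals.
Defaults: δ = 2 (affected open-arm activity roughly a third of normal,
strong separation from the control cutoffs), ρ = 0.3 (moderate latent
behavioral correlation; true inter-measure correlations in EPM data are
unknown, and ρ is a free parameter).

`generate_paper_like_study` emits the six-group design with the exact
published group sizes (30, 12, 12, 31, 19, 12; 116 animals). Latent
fractions are back-computed from the target classified proportions via
π = (target − f)/(1 − f), where f = 0.095 is the generator's measured
null classification rate under the default measure set (frozen from a
one-off large-n calibration: 5 × 200 000 probe animals against
independent 100 000-animal control cutoffs, f = 0.0950 ± 0.0013; the
correlated, partially derived measures lift it above the independent-
measure tail of 0.0333). Classified proportions on any single 116-
animal draw therefore scatter binomially around the targets.

What the generator does *not* emulate: session-length constraints
(durations need not sum to the trial length), heavy-tailed or
zero-inflated open-arm times of extreme freezers, sex or cohort batch
effects, and any trajectory-level structure. Group differences enter
solely through the latent affected fraction — unaffected animals are
exchangeable across groups — so averaged-group mean effects on a single
cohort are modest relative to the individual-differences signal.
Passing tests demonstrate correctness of the procedure and its
operating characteristics under this model, not fidelity to any
particular laboratory's EPM distributions.

## Parameter-recovery conditions

The recovery suite uses cohorts of n = 31 with latent π = 0.35 against
n = 200 controls, seven independent log-normal measures (σ = 0.5) and
δ = 10, giving near-perfect classifier sensitivity. The classified
proportion estimates π with a known positive bias (1−π)·FPR, where the
out-of-sample per-measure flag probability under nearest-rank cutoffs
from n controls is exactly ⌈q·n⌉/(n+1); the suite checks both that the
raw classified mean over 200 replicates is within one single-cohort
binomial SE of π and that the misclassification-corrected
(Rogan–Gladen) estimate (p̂ − FPR)/(1 − FPR) recovers π to three
Monte-Carlo standard errors. The null-rate suite uses 100 000 animals,
where the closed-form binomial tail carries a Monte-Carlo SE of
≈ 5.7 × 10⁻⁴.

## Limitations

- The seven-measure set is configurable precisely because the
  canonical set is under-specified in the literature; results depend
  on it, and the shipped default is a stand-in.
- Inclusive vs strict cutoff comparison changes classifications of
  boundary animals in small control groups; both are provided, with
  inclusive the documented default.
- The two-way ANOVA assumes homoscedastic Gaussian residuals; no
  assumption diagnostics are built in.
- Repeated-measures designs (body weight, fluid intake over time) are
  out of scope.
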