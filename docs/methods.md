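# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the study sizes used by the test and acceptance
suites — and what passing those suites does and does not establish.

## Measures

For a response $\hat c$ (kcal) to a food with ground truth $c$:

- error $e = \hat c - c$ (positive = overestimate),
- percent error $\eta = e / c$ (stored as a fraction; rendered as percent
  only in reports),
- absolute error $|e|$,
- discrete accuracy $D$ = number of a participant's answers with
  $|\eta| \le 0.20$. The 20% boundary is **inclusive**: "within 20%" most
  naturally includes the boundary, and the convention is centralised in one
  constant (`error_metrics.CORRECT_THRESHOLD`).

## Quality control

Participants are removed when their reported BMI is below 15 or above
50 kg/m² (strict inequalities; exactly 15 or 50 is kept), when BMI is
missing, or when gender is missing. Responses below the quiz floor or above
the ceiling (50/800 kcal, strict) are removed individually; their owners are
kept with partial data, because the exclusion targets implausible answers,
not people. Both filters are idempotent and order-independent; counts of
everything removed are reported in a `QcReport`. Missing BMI is treated as
removable because the BMI×density model cannot use such records and
missing-demographic records were excluded from the original survey's
analysis population.

## Crowd consensus and the bootstrap crowd-size test

A crowd of size $k$ is a set of $k$ distinct participants (sampled without
replacement — a crowd is a set of people, and one shared draw covers all
foods). Its consensus is the per-food mean (default; the median is available)
of the members' estimates; crowd accuracy is computed from the consensus via
the same code path as individual metrics, so crowd $D$ has exactly the same
semantics as individual $D$. The crowd error statistic is the mean over foods
of the consensus absolute error, in kcal by default with a percent variant.

`bootstrap_crowd_test(k1, k2, B)` asks whether a size-$k_1$ crowd is any more
or less accurate than a size-$k_2$ crowd. It draws one *observed* crowd pair
and differences their errors, then $B$ further iid crowd-pair differences;
the reference draws are centred at their own mean (removing any true
size-$k_1$ vs size-$k_2$ gap, so they represent the no-difference
hypothesis), and the two-sided Monte-Carlo p-value is

$$p = \frac{1 + \#\{|d_b - \bar d| \ge |d_{obs}|\}}{B + 1}.$$

When the two sizes are genuinely interchangeable, $d_{obs}$ is exchangeable
with the centred reference draws and $p$ is uniform — the test holds its
nominal level, which the acceptance suite verifies directly (200 null
cohorts of 60 participants, $k_1=k_2=10$, $B=500$: rejection at
$\alpha=.05$ required within [0.02, 0.09]). A degenerate dataset in which
every crowd scores identically returns $p = 1$. An earlier design that
compared the *reference distribution itself* to zero was rejected during
development: with $k_1=k_2$ the reference distribution is symmetric about
zero by construction, so such a test can never reject and has no level to
hold.

The expert comparison scores each expert as an individual (mean $|e|$ over
their own answers) and the crowd by its consensus, averaged over draws; the
minimal $k$ is the smallest crowd whose average consensus error falls
strictly below the best expert's. A perfect expert ($|e| = 0$) is flagged
as unbeaten rather than producing a spurious $k$.

## Mixed-effects bias models

Four registered models, each with crossed random intercepts $u_i$
(participant) and $v_j$ (food):

| name | outcome | fixed effects |
| --- | --- | --- |
| `reference_object` | $\|e\|$ | has-reference-object flag |
| `density_bias` | $e$ | centred log energy density |
| `bmi_density_interaction` | $\eta$ | (BMI − 25) × centred log density, with main effects |
| `demographics` | $\|e\|$ | male indicator + age-bin midpoint |

Choices: energy density enters as **centred log(kcal/g)** (log respects the
multiplicative error structure; centring makes the intercept the grand mean;
a raw-density switch exists). BMI is centred at 25 kg/m², the
normal/overweight boundary. Age enters as the numeric midpoint of the
reported bin, because only an age *group* is collected. No multiple-testing
correction is applied across the four models (each is reported at its own
α = .05), and the reports say so.

**Estimation.** The crossed design is fitted by exact profiled REML. Writing
the variance ratios $\gamma_u = \sigma_u^2/\sigma^2$,
$\gamma_v = \sigma_v^2/\sigma^2$, the marginal covariance is
$\sigma^2 W$ with $W = I + \gamma_u Z_uZ_u' + \gamma_v Z_vZ_v'$; the Woodbury
identity reduces every REML ingredient ($W^{-1}$ products, $\log|W|$,
$X'W^{-1}X$) to one Cholesky factorisation of the $(p+f)$-dimensional
capacitance matrix per evaluation. The two ratios are optimised by
Nelder–Mead on the log scale with boundary snapping (a ratio collapses to
exactly zero when that does not worsen the criterion), making a 10,000-row
fit run in a fraction of a second — which is what permits the 100-seed
recovery and 150-seed calibration studies below. The test suite checks this
solver against statsmodels' `MixedLM` (variance-component formulation) on a
small cohort: fixed effects, standard errors and the residual variance must
agree to a relative 10⁻³.

Fixed-effect p-values use the large-sample normal approximation. For
food-level covariates the effective replication is the 20 foods, so these
p-values behave like a $t_{18}$ statistic read off a normal table — slightly
anticonservative (~6–7% rejection at nominal 5%). The calibration band below
accounts for this; it is a property of any Wald approach at 20 items,
including at the original survey's full cohort size.

$R^2$ is the squared Pearson correlation between the outcome and the model's
*conditional* predictions (fixed effects plus predicted random intercepts):
the proportion of outcome variance described by the model's predicted
values. It is invariant to affine rescaling of the outcome and equals 1 when
the outcome is replaced by the predictions. Rank-deficient designs (e.g. a
single-gender cohort making the male indicator constant) return minimum-norm
estimates with NaN uncertainties and `converged = False` — never a silent
fallback.

## Error-correlation network

Entry $(j, j')$ of the food-by-food matrix is the Pearson correlation of
per-participant $\eta$ between the two foods, over participants answering
both; pairs with fewer than 3 common participants are left missing and never
become edges. $\eta$ rather than raw $e$ is the default so that the shared
signal is proportional bias, not food size (switchable). Edges connect pairs
with $r \ge 0.3$ by default (the threshold is exposed; negative correlations
never form edges) carrying distance $1 - r$ — the standard bounded,
monotone correlation distance. Clusters come from average-linkage
agglomerative clustering on that distance, cut at 0.7 (configurable), i.e.
foods stay together while their average correlation exceeds 0.3; singletons
are allowed, and a food with no defined correlations is its own cluster.

## Synthetic cohorts

The generator produces, for participant $i$ and food $j$,

$$\log \hat c_{ij} = \log c_j + \beta_d\,\mathrm{cld}_j + \beta_m\,\mathbb
1[male_i] + \beta_a\,\mathrm{agebin}_i + \beta_{bd}\,(BMI_i - 25)\,
\mathrm{cld}_j + u_i + v_j + \varepsilon_{ij},$$

with $\mathrm{cld}_j$ the centred log energy density, crossed random
intercepts $u_i \sim N(0, sd_{participant}^2)$, $v_j \sim N(0, sd_{food}^2)$
and noise $\varepsilon_{ij} \sim N(0, \sigma^2)$. Estimates outside the quiz
bounds are redrawn ($\varepsilon$ only, up to `max_resample` times) and then
clipped — mirroring a quiz interface that forces answers into range without
distorting the bulk of the distribution. Noise is multiplicative (log-scale)
because calorie estimates are positive and percent error is the scale-free
bias measure of interest. A single master seed spawns independent substreams
for demographics, random intercepts and noise, so e.g. growing the cohort
does not disturb the food intercepts; fixed seeds reproduce response tables
byte for byte.

Defaults: cohort shape echoes the original survey (2028 nonexperts plus 5
experts, 62% female, mean BMI 27.5 kg/m² with SD 5.5 truncated to the
plausible range, a young age distribution); invalid-BMI and missing-gender
records are injected at 2.5%/2.2% so QC has work to do, matching the
survey's ~4.6% overall removal. Noise scales ($\sigma = 0.55$,
$sd_{participant} = 0.25$, $sd_{food} = 0.15$) were chosen once to give a
mean absolute percent error near the 50–60% seen in real data. All bias
coefficients default to **zero** — no per-demographic effect sizes were ever
published on this scale, so effects are opt-in, order-of-magnitude choices
documented where used. Experts are generated by the identical process and
only flagged (the survey found no expert advantage).

What the generator does *not* emulate: integer-rounded answers, anchoring on
the stated 50–800 range, heavy-tailed or participant-specific noise scales,
item-order effects, and non-random participation. Passing tests therefore
demonstrate correctness and calibration of the *analyses* under the assumed
structure, not that real crowds satisfy that structure.

Two auxiliary fixtures support structure-recovery tests:
`perturb_duplicate_foods` appends copies of a food sharing the source's
participant-level errors plus independent noise, and `simulate_block_cohort`
plants a $K$-block factor structure (within-block $\eta$ correlation
$\approx sd_{block}^2/(sd_{block}^2 + \sigma^2)$, between-block ≈ 0) with
the planted labels returned as ground truth. The block fixture leaves
estimates un-truncated by default, since clipping at the bounds censors
exactly the correlations it exists to provide.

## Study sizes and acceptance bands

The acceptance suite runs these studies end to end:

- **Fixture:** density–mass Pearson correlation of the packaged quiz
  = −0.70 at two decimals; 20 foods spanning exactly 100–720 kcal, 8 mixed.
- **Metric oracle:** 1,000 random (estimate, truth) pairs must match a
  definitionally direct reimplementation exactly, including $D$.
- **QC boundaries:** BMI 14.9/15.0/50.0/50.1 and estimates
  49.9/50/800/800.1 removed/retained per the strict rules.
- **Convergence:** unbiased cohort, $n = 500$, $\sigma = 0.3$; across 200
  draws the per-food consensus SD times $\sqrt k$ must agree within 15%
  over $k \in \{2, 10, 50\}$ (the small residual spread is the
  without-replacement finite-population correction, $\approx$ 5% at
  $k = 50$ of $N = 500$), and mean crowd $D$ must be non-decreasing in $k$.
- **Bootstrap level:** as above — 200 null cohorts, rejection in
  [0.02, 0.09].
- **Recovery/calibration:** $\beta_d = 0.3$, $\sigma = 0.2$, $n = 500$:
  positive significant density slope in ≥ 95/100 seeds. Null cohorts
  (all effects zero, $n = 150$, 150 seeds): every model's headline-term
  rejection rate within [0.01, 0.12], the upper edge reflecting the
  food-level $t_{18}$ effect above. The reference-object model is calibrated
  on an energy-balanced quiz variant (all energies set to 300 kcal, flags
  and masses unchanged): on the real quiz the reference flag rides on
  portion energy (flagged foods average ~405 kcal vs ~238 for the rest), so
  under multiplicative noise flagged foods genuinely have larger $|e|$ and
  the contrast is not null. This confound is worth remembering when
  interpreting reference-object effects on $|e|$ in real data of this
  design.
- **Network recovery:** 3 planted blocks, $n = 200$, $sd_{block} = 0.3$,
  $\sigma = 0.15$: adjusted Rand > 0.9 against the planted labels in
  ≥ 90/100 seeds.
- **Determinism:** one master seed reproduces the entire pipeline bundle
  byte for byte (the manifest stores per-artifact SHA-256 checksums and
  omits the output path for location independence).

Study sizes (cohorts of 60–500, seed counts of 100–200) are the package's
choice of smallest sizes at which the binomial/Monte-Carlo noise of each
check is comfortably inside its band.

## Known limitations

- Published cohort-level results of the original survey (mean $D = 5.15$,
  crowd $D = 7$, the 4.6 kcal reference-object coefficient, R² values of
  .31/.57) are **context only**: the raw responses were never deposited, so
  those numbers are not reproducible and are not asserted anywhere; the
  suite checks the corresponding qualitative behaviours on synthetic
  cohorts.
- The exact age bins of the original survey are unpublished; the package's
  bins (13–17 … 65+) and midpoints are a convention.
- Whether "within 20%" was boundary-inclusive in the original analysis is
  unknowable from the text; this package is inclusive and says so.
- p-values are Wald/normal; food-level contrasts at 20 items carry the
  $t_{18}$ caveat above. No marginal/conditional R² decomposition is
  offered beyond the verbal definition implemented.
- The network stage outputs the graph and clusters; map-style layout and
  rendering are out of scope.
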