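# Methods

This note records the modelling conventions, generator design, numerical
choices, and problem sizes used by `tapcog`, in enough detail to reproduce or
audit any number the package prints.

## Data model

A tapping session consists of six blocks: four 10-s single-key blocks
(spacebar, dominant hand) and one 30-s alternate-key block per hand ("s" and
";" pressed alternately). Each key event is a (label, key-down ms, key-up ms)
triple with timestamps relative to block start; absolute wall-clock time is
deliberately outside the data model. Events are stored long-form, one per CSV
row, because keystroke capture is an append-only stream and no standard
interchange format exists. A key-down without a key-up (key still held at
block end) is truncated to the block end and flagged rather than dropped:
dropping it would bias the frequency feature downward while truncation leaves
the press count exact and dwell time defined.

The data model permits overlapping presses (a second key down before the
first is released), which can occur in alternate-key tapping; all downstream
features are defined so that overlap is harmless (intervals use key-down
times only).

## Motor features

Per block:

- **Frequency** = press count / block duration (presses per second). A block
  with no presses scores 0.
- **Variability** = sample standard deviation (n−1 denominator) of the
  natural log of inter-press intervals, where an interval is the difference
  between successive key-*down* times. At least two intervals are required;
  otherwise the value is missing (`NaN`) with a warning — never a silent
  zero. Non-positive intervals (simultaneous downs) are excluded since their
  log is undefined. The choice of natural log and sample SD is a convention:
  any log base rescales the statistic by a constant, so the base cannot
  matter scientifically, but one documented convention is needed for
  reproducibility. The statistic is invariant to rescaling and translating
  the timestamps.
- **Dwell time** = mean (key-up − key-down) in ms over presses.
- **Accuracy** = Σ per-press points / press count, with 1 point for the
  expected key, 2 for a key adjacent to it, 3 for any other key. Bounds are
  [1, 3]; 1.0 iff every press hit its target. For the single-key test the
  expected key is the spacebar on every press. For the alternate-key test
  the expected key alternates between the two targets, anchored to whichever
  target the participant pressed first (starting on ";" rather than "s" is
  legitimate and unpenalized); if the first press hits neither target,
  alternation anchors to "s". The expectation advances on every press,
  right or wrong, because the protocol demands one alternation per press —
  a doubled key is scored against the key that should have come next.
  Adjacency is configurable; the shipped default is a QWERTY map (spacebar:
  c v b n m; s: a d w e z x; ";": l p o ' . /).

Feature columns are named `sk_{freq,var,dwell,acc}_b{1..4}` and
`ak_{feature}_{d,nd}` — 24 per participant. Blocks are kept separate (no
within-test averaging): block-to-block change is real signal (a warm-up
trend), and the model comparison treats every block's features as distinct
candidates. Missing blocks leave missing cells.

## Cohort exclusions

A participant is excluded iff any of: a "yes" to one of the three cognitive
self-report screening questions; self-reported Parkinson's disease;
self-reported multiple sclerosis; an incomplete tapping protocol (anything
short of 4 single-key blocks plus both alternate-key hands); or a missing
cognitive score. Exactly one reason code is recorded per excluded
participant, assigned in that priority order, which makes per-reason counts
mutually exclusive and the ledger reconcilable (included + Σ reasons =
total). The priority order is a convention of this package; single-reason
reporting requires one. A missing screening boolean raises an error rather
than being read as "no".

## Synthetic cohort generator

The generator emulates a community cohort of older adults (50–90 years,
predominantly female, majority university-educated) completing the tapping
protocol and three cognitive count scores, with exclusion flags injected at
realistic rates (74 symptomatic + 3 PD + 8 MS in 1254 by default, leaving
1169 analyzable).

**Demographics.** Age is drawn from a truncated normal on [50, 90] whose
parent (μ, σ) are solved numerically so that the *truncated* distribution has
exactly the target mean 65.8 and SD 7.37 — naive truncation of N(65.8, 7.37)
would shift the realized mean by about +0.3 years. Sex is Bernoulli
(73.1% female); education is a six-level categorical (4.2/9.2/13.9/49.4/
17.3/6.1%); HADS anxiety and depression are rounded, clipped normals
(4.28 ± 3.55 and 2.90 ± 2.72, floor 0, cap 21) — the simplest shapes
matching the target mean/SD/range.

**Tapping streams.** Each block is a stationary renewal process with
lognormal inter-press intervals: LogNormal(μ, σ) with mean 1/frequency, and
the first press placed at `U·Î` where `Î` is drawn from the length-biased
interval distribution LogNormal(μ+σ², σ) and `U` is uniform. The stationary
start matters: an ordinary renewal start biases the expected count by
`(CV²−1)/2` presses per block (≈ −0.5 at these parameters), which a large-n
calibration check would detect; with the stationary construction the
expected frequency feature equals the configured target exactly, at any
block duration. The lognormal interval choice makes "SD of log interval" the
literal generator parameter, so the variability feature recovers it directly
(up to the ~1% small-sample bias of a sample SD).

Participant heterogeneity: a shared standard-normal speed score `z` maps to
each block's frequency as `target + z·SD(block)` (reference targets
5.54/5.62/5.70/5.77 presses/s for single-key blocks 1–4 — a warm-up trend —
and 2.17/2.00 for dominant/non-dominant alternate-key, with the matching
between-participant SDs), times a mild multiplicative age slope
(−0.4%/year). Sharing `z` across blocks induces the strong between-feature
correlation real tapping data shows. Rhythm and dwell get mean-one lognormal
participant multipliers. Within a block, dwell times are lognormal per press,
capped below the next inter-press interval (a key must be released before the
same or next key goes down) and at the block end. Wrong keys are injected
per press (adjacent vs. other, defaults 0.4%+0.2% single-key, 3%+1.2%
alternate-key). Interval SDs (0.15 single, 0.20 alternate), dwell medians
(90/110 ms), and wrong-key rates have no published reference distribution;
they are plausible conventions, and nothing downstream is calibrated against
them.

Timestamps are rounded to integer milliseconds interval-by-interval before
accumulation, so a zero-σ configuration produces exactly constant intervals
and exactly zero variability.

**Cognitive counts.** Each outcome is drawn from a log-link count model
whose linear predictor combines configured coefficients with *centered*
predictors (demographics at their configured means, motor features at their
configured targets), so the intercept is the log of the target mean count.
The features entering the outcome are the participant's *realized* features
(computed from the generated events), not latents — so a regression of
simulated counts on extracted features recovers the injected coefficients
without attenuation. PAL total errors and SWM between-errors are negative
binomial (gamma–Poisson, θ = 1.05 and 1.35, matching target mean/SD 4.40/4.80
and 3.22/3.32); the SWM strategy score is Poisson because its reference
distribution is *under*dispersed (mean 7.75 > variance 7.62 ≈ 2.76²), which
no NB can produce. Counts are capped at the observed task maxima (22/13/13),
a convention, not a task rule. The default motor→cognition link: episodic
memory errors increase with lower dominant-hand alternate-key frequency
(β = −0.35 per press/s) and higher non-dominant variability (β = +2.0 per
log-unit); working-memory between-errors have no motor link; the strategy
score has a mild single-key block-4 frequency link (β = −0.12). The two
alternate-key effect sizes were set by a power calculation (Wald z ≈ 5 at
n = 1169) so the injected signal is decisively detectable at the reference
cohort size.

**Reproducibility.** Every participant consumes an independent random
substream keyed by (seed, participant index): growing the cohort never
perturbs earlier participants, and the whole cohort is a pure function of
the seed. Exclusion-flag injection uses a separate cohort-level stream and
is the one stage that depends on n.

## GLM engine and model selection

Count families use a log link. Fitting is iteratively reweighted least
squares; for the negative binomial, IRLS steps on β (working weights
μ/(1+μ/θ)) alternate with Newton steps on log θ until the log-likelihood
changes by less than 3·10⁻⁹ relative (≤ 50 outer iterations). Digamma and
trigamma sums are evaluated over the distinct count values with
multiplicities, which makes a fit on n ≈ 1200 take ~3 ms — the all-subsets
loop performs thousands of fits per table. Standard errors come from the
inverse Fisher information at the MLE, conditional on θ for the NB (the
convention of standard NB-GLM software). The linear predictor is clipped to
[−30, 30] to prevent overflow; a fit whose coefficients exceed 20 in
magnitude (e.g. under perfect separation) is flagged non-converged. A θ
reaching the upper bound 10⁷ is reported as a converged boundary MLE
(equidispersion) with a `dispersion_at_boundary` flag, so Poisson data do
not spuriously trigger the non-convergence fallback. The engine's
coefficients and log-likelihoods are cross-checked against statsmodels in the
test suite; statsmodels is the independent oracle, never the implementation.

**Parameter counting.** `k` counts every estimated parameter once: intercept,
covariate coefficients (education enters as an unordered categorical with
the lowest level as reference — five dummies, each counting toward k), motor
coefficients, the NB dispersion, and the Gaussian residual variance. AICc
is used for ranking; plain AIC is also reported.

**Enumeration.** All `2^m` additive subsets of the candidate features are
fitted, every model containing the fixed covariates; the empty subset is the
null model. The design matrix for the full candidate set is built and
rank-checked once (QR with pivoting names collinear columns), and each subset
slices columns out of it, warm-starting from the null fit. Tables are ranked
by AICc with ties broken by smaller k, then lexicographic feature names, so
output is fully deterministic. Non-converged fits remain visible in the
table but are excluded from the equivalence set and can never be "best".
The hypothesis decision is: motor features improve prediction iff the null
model's ΔAICc exceeds 2.

**Family selection** fits the NB and Poisson covariates-only models: NB is
chosen if its AICc beats Poisson by more than 2; otherwise Poisson is
retained. If the NB null fails to converge, the Gaussian family is used and
the fallback recorded. A hard error occurs only if every family fails.

**Adjusted pseudo-R².** The paper-style summary
`1 − (D_model/D_baseline)·(n−1)/(n−k_mean)`, clamped below at 0, where the
baseline is the intercept-only deviance evaluated **at the fitted model's own
dispersion** (the intercept-only MLE mean is ȳ for every family used here,
so this is closed-form). Evaluating both deviances at the same θ is essential
— deviances under different dispersions are not comparable and would make the
ratio meaningless. For the Gaussian family the formula reduces exactly to the
classical adjusted R². This definition is a stated convention of this
package; reports label it as such.

## Default study problem sizes

The full study crosses three outcomes with three candidate sets (single-key,
alternate-key, combined). The complete sets have 16, 8, and 24 features —
2¹⁶, 2⁸, and 2²⁴ models per cell. The default `StudyConfig` uses scaled
candidate sets that preserve each set's character at desk scale: single-key
blocks 1+4 (8 features), all alternate-key (8), and block-1 + alternate-key
for the combined set (12 features, 4096 models/cell) — a full 9-cell run
takes ~30 s. The full 16- and 8-feature sets are available by preset name,
and the 2²⁴ combined enumeration is allowed only behind an explicit
`allow_full_enumeration` flag (it is a cluster-scale job). Acceptance-grade
checks in the test suite use: n = 2000 for coefficient recovery, 100
replicates of n = 1000 for null-scenario calibration, 9 replicates of the
full n = 1254 study for the qualitative pattern, and n = 10⁴ for generator
moment calibration.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline is internally correct: features
equal their definitions, the enumeration is exhaustive and correctly ranked,
injected effects are recovered without bias, the false-positive behaviour of
the ΔAICc < 2 rule is calibrated, and the qualitative decision pattern
follows the injected motor→cognition structure. They do not validate the
scientific claim on real humans: the generator's lognormal intervals, its
lack of fatigue/learning dynamics within blocks, device- and
keyboard-latency artifacts, non-compliance (e.g. two-handed alternate
tapping), and the true joint distribution of motor and cognitive measures
are all outside what synthetic agreement can establish. Under a true null
with eight correlated candidate features, the best subset beats the null by
more than 2 AICc in roughly a fifth to a third of replicates — users
comparing a single dataset should read a marginal ΔAICc (2–8) accordingly.

## Known limitations

- The adjusted pseudo-R² convention is package-defined; numeric values are
  not comparable to other software's pseudo-R² variants.
- The accuracy index depends on the adjacency map; non-QWERTY layouts need a
  custom map.
- The generator injects exclusion flags independently of motor performance;
  real attrition is unlikely to be independent.
- IRRs are per raw unit of each feature (presses/s, log-units, ms); features
  are not standardized before modelling.
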