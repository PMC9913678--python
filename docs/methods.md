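# Methods

## Study design and stratification

The bundled design follows a sanctuary chimpanzee group of seven
individuals (five males, two females; two wild-caught) through three
phases of constant composition: an all-male group of five, a mixed-sex
group of seven after two females joined, and a mixed-sex group of five
after two males died. The chronology is known only to calendar-year
precision, so phase boundaries default to January 1 of the bracketing
years (the last phase ends with the observation window in March of its
final year); they are explicit dates in configuration and fully
replaceable. Seasons are defined by a month rule, by default November–
April = cold and May–October = warm, consistent with the Mediterranean
temperature means reported for the site (≈14.5 °C vs ≈24.8 °C); the rule
is configurable because the original month split is not documented.
Phases × seasons give six strata; all response variables are computed per
individual within each stratum, giving the 34-row (5 + 7 + 5) × 2 index
table.

Enumerating unordered pairs of the seven-member roster yields 21 dyads:
10 male–male, 10 male–female and 1 female–female. The reported total for
this roster is 20 (with 9 male–female); the package derives its counts
from the roster and documents the discrepancy rather than hard-coding the
reported value.

A presence convention ties everything together: an individual is present
at a scan timepoint iff a record exists for it there. Absences therefore
appear as missing records, and co-presence is counted per timepoint (the
finer of the two possible readings of a "scan" denominator).

Grooming direction is canonicalized to "given" records; mutual grooming
is represented as two directed records. Only canonical records are
counted, so paired groomer/groomee records never double-count.

## Network measures

For one stratum, `p[i,j]` counts slots where both `i` and `j` have
records, `c[i,j]` counts canonical records of `i` grooming `j`, and the
edge weight is `w[i,j] = 100·c/p`, undefined (missing edge) when
`p = 0`. Zero and missing are deliberately distinct: a zero says the dyad
had access and never groomed; treating never-co-present dyads as zeros
would bias the evenness measures downward.

Vertex strength centrality divides the summed outgoing weight by
`n − 1` from the *roster*, not by the count of defined edges — the index
explicitly normalizes by group size, and an individual that was denied
access to a partner still has that partner in its potential pool. The
edge weight disparity `H = Σ (w/s)²` is computed over defined outgoing
edges and is undefined when the outgoing strength `s` is zero;
disparity-of-nothing is mathematically meaningless, so such cells are
missing (and excluded from models), never imputed. `H` is reconstructed
as the sum of squared edge-weight shares — the normalized form whose
floor is exactly `1/(n−1)` for even grooming and whose ceiling is 1 —
and DEWD subtracts that floor; the formula sits in a single function so
an alternative normalization can be swapped in. DEWD is invariant to
rescaling an individual's outgoing weights, which the property suite
checks, along with the closed-form limits (even ⇒ 0; single-partner ⇒
`(n−2)/(n−1)`).

## Synthetic generator

The generator emulates the sampling protocol: sessions of 10 scans at
2-minute spacing, scheduled evenly over each stratum's calendar days with
start hours cycling through the 10:00–18:00 outdoor-access window; whole-
session absences are independent Bernoulli events per individual
(default probability 0.05). Each present individual's behavior at each
timepoint is one of four classes — groom, other active, rest, undesired —
drawn from a multinomial whose log-weights are the baseline
`(g_i, 0.38, 0.47, 0.05)` (the groom component replaced by the
individual's propensity trait `g_i`) plus additive covariate shifts:
cold-season and wild-caught shifts on both active classes, wild-caught
and female shifts on grooming alone, and an all-male shift on the
undesired class. Additive log-odds effects were chosen because they are
sign-interpretable and match the direction-of-effect claims the model
stage must recover. Grooming picks a partner among co-present others in
proportion to a preference vector drawn once per phase from a symmetric
Dirichlet with concentration `κ_i`; fixed-per-phase preferences make
grooming evenness a stable individual trait, which is what DEWD is meant
to measure (large `κ` ⇒ near-uniform choice ⇒ DEWD → 0; tiny `κ` ⇒
single-partner choice ⇒ DEWD → its ceiling). An individual alone in a
session cannot groom; such draws fall back to rest.

Defaults reproduce the scale and the qualitative effect structure of the
original campaign: 700 sessions per stratum ≈ 4200 sessions and ≈2.2×10⁵
records at 5% absence; effect sizes 0.35 (cold-season activity), −0.6
(wild-caught activity), −0.8 (wild-caught grooming), 0.5 (female
grooming), 0.6 (all-male undesired) on the log-odds scale; propensity
traits spread 0.08–0.14 across individuals so the random intercept is
real. Tests and the acceptance script run the same generator at reduced
session counts (2–6 per stratum for unit and calibration work, 120 for
the end-to-end acceptance run), which keeps the suite fast without
changing any mechanism.

What the generator does *not* emulate: dominance hierarchies, spatial
structure within the enclosure, temporal autocorrelation within sessions
(scans are conditionally independent given presence), observer error,
and demographic change beyond the scripted phase rosters. Passing tests
therefore demonstrate that the pipeline's estimators and tests behave
correctly under the protocol's sampling structure, not that real
chimpanzee data meets the model's assumptions.

## Mixed-model stage

Each response (VSC, DEWD, GAI, undesired proportion) is modeled as
Gaussian with five binary treatment-coded fixed factors and a
per-individual random intercept. Rows with missing responses are dropped
with a logged count. statsmodels' `MixedLM` performs the likelihood
maximisation; because this model has a single free variance ratio, the
fit is then polished by a 1-D search of the profiled REML criterion with
the boundary (zero intercept variance) as an explicit candidate.
Optimizers frequently stall at tiny positive ratios when the optimum is
singular, and the polish makes the fitted variance components match
lme4's to ~7 significant digits on identical data (verified in a test via
`Rscript`).

Per-factor tests are Wald F statistics (1 numerator df, so F = t²) with
Satterthwaite denominator df computed from the REML information matrix of
the two variance parameters by the delta method. At the boundary the
model degenerates to OLS and the residual df apply. On the 34-row design
this reproduces the expected repeated-measures pattern: between-subject
factors (sex, origin — carried by only 7 individuals) get single-digit
df, within-subject factors get ~24–28. A containment-style df
partition was considered and rejected: it yields between-subject df of 4
on this design, inconsistent with the reference toolchain
(lme4 + lmerTest) that the Satterthwaite implementation matches
numerically.

The full-vs-null comparison refits both models with ML (REML likelihoods
are not comparable across fixed-effect structures) and refers
`λ = 2(ℓ_full − ℓ_null)` to χ² with one df per factor. At n = 34 the ML
likelihood ratio carries the usual small-sample inflation (expected mean
up to ≈ n/(n−p) × 5 ≈ 6.1 rather than 5 under the null); the calibration
suite allows for this.

Post hoc contrasts are the marginal-mean differences between each
factor's two levels — with binary treatment coding and no interactions
these equal the coefficients, which a brute-force prediction-grid oracle
confirms — with Bonferroni adjustment over the family of five factors
tested within one model (the family size is configurable; the original
analysis does not state its family). Interaction terms are deliberately
out of scope, as is any trend machinery for continuous covariates: all
five factors here are categorical. Cohen's d uses the classical
pooled-SD formula on the raw response values, signed alternative-minus-
reference (cold−warm, F−M, wild−captive, mixed−all-male, 7−5).

Collinearity is reported two ways. The design-based VIF,
`1/(1 − R²)` from regressing each factor's indicator on the other four,
is the implemented diagnostic; on the reconstructed 34-row design it
spans exactly 1.00 (seasonality, balanced within every individual-phase)
to 1.66 (sex ratio). A model-based VIF (from the fixed-effect coefficient
correlation under the fitted variance components) is also provided: with
a positive intraclass correlation the between-subject collinearity
shrinks, and the reported ceiling of 1.61 for this design corresponds to
the model-based value at ICC ≈ 0.13. Since the original variance
components are not recoverable without the raw data, the package treats
the design-based value as its canonical output and documents the
relationship.

The QQ diagnostic pairs sorted conditional residuals (observed minus
fixed and predicted random effects) with Blom-position normal quantiles
and summarizes with their correlation.

## Calibration suite

Type-I error is assessed by simulating the full pipeline under the null:
all five covariate effects zero, with each replicate drawing fresh
per-individual propensity traits (normal, mean 0.105, sd 0.025, clipped
to (0.04, 0.25)) independent of all covariates. Drawing traits per
replicate matters: with identical individuals in every replicate the
random intercept that the model assumes random is in truth a fixed
constant pattern, which makes between-subject tests systematically
conservative; with trait variation present the model is correctly
specified and all five factors reject at the nominal 5% rate within
Monte-Carlo error (500 replicates, 3 sessions per stratum). Effect
recovery injects a cold-season activity shift of 0.8 log-odds and
requires a significant, correctly-signed seasonality test in ≥95% of 200
replicates.

## Numerical and degenerate-input choices

* Edge-list CSVs are written with `%.17g` and read with round-trip float
  parsing, so exported weights reproduce bit-exactly.
* A response with numerically zero variance yields a flagged degenerate
  result (no test statistics) instead of an exception; perfectly
  collinear factors yield infinite VIFs with a logged error.
* The REML boundary is declared when the fitted variance ratio falls
  below 1e-8; Satterthwaite df are clamped to [1, n − p].
* Grooming records lacking a partner are a hard error in the counting
  stage (data corruption), but only a validation finding in the report
  stage, where the caller decides strictness.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed reproduce
  byte-identical artifacts, which the determinism tests assert.

## Known limitations

* The Gaussian LMM is applied to proportions and bounded indices as in
  the original analysis; no GLMM variant is provided.
* Satterthwaite df are approximate; exact reproduction of any particular
  published F table is not attempted (and is impossible without the raw
  data).
* The generator's independence assumptions (across timepoints and
  individuals) understate the serial dependence of real behavior, so
  real-data standard errors will typically be more optimistic than the
  calibration suite suggests.
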