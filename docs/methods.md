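# Methods

This note documents the statistical model behind `deconfound`, the
assumptions of the synthetic cohort generator, the numerical choices
made where the design was genuinely open, and the limits of what the
validation battery shows.

## The association model

For one omics space and one disease contrast (control vs mild =
"status"; mild vs severe = "severity"), every feature Y and clinical
variable X is first screened naively. Binary X: Cliff's delta

δ(A, B) = ( #{aᵢ > bⱼ} − #{aᵢ < bⱼ} ) / (|A||B|),

computed through the rank-sum identity δ = 2U/(mn) − 1 with midranks
(tied pairs contribute zero), tested with the two-sided Mann–Whitney
rank-sum test. Continuous X: Spearman's ρ with its two-sided p.
P-values are Benjamini–Hochberg adjusted; the default family is one
omics space × one contrast (configurable, and recorded in the output).
A variable with fewer than three nonzero observations in either contrast
group is excluded from the screen as untestable. Repeated samples of one
subject enter the screen as-is — the framework deliberately defers
within-subject correlation to the modeling stage (a per-subject collapse
option exists but is off by default; see *Calibration* below for the
consequence).

For every naively significant pair (Y, X) and every *other* naively
significant variable C for that Y, three linear mixed models are fitted
to the midranked feature:

- rank(Y) ~ X + (1|subject)
- rank(Y) ~ C + (1|subject)
- rank(Y) ~ X + C + (1|subject)

Estimation is full maximum likelihood, not REML, because the
likelihood-ratio tests compare fixed-effect structures and REML
likelihoods are not comparable across different fixed effects. Two LRTs
follow: Test 1 (full vs X-only; does C add anything beyond X?) and
Test 2 (full vs C-only; does X survive adjustment for C?). The statistic
2·Δll is clamped at zero and referred to χ² with df equal to the number
of added fixed-effect columns; no boundary correction is needed because
the random-effect structure is identical across the compared models. All
LRT p-values of a run form one BH family; "significant" means adjusted
p ≤ 0.05. Verdict per candidate: Test 2 significant (alone or with
Test 1) → the association *passes* C; only Test 1 significant → it is
statistically *reducible* to C; neither → *ambiguous*.

These verdicts are folded into one status per (Y, X) pair: `NS` when the
naive screen was not significant (this gate precedes any modeling); `D`
(robust/deconfounded) when the pair passes every candidate; `confounded:
[C, ...]` listing every candidate with a reducibility verdict;
`ambiguous` when no confounder is named but at least one candidate could
not be separated. An `ambiguous` or `untestable` candidate never lets a
feature count as robust — an unresolvable competitor is not evidence of
robustness. The single-omics and cross-omics stages use the identical
two-test rule; it is the only rule under which "confounded" and
"robust" are both well defined.

### Mixed-model degeneracies

Two degenerate regimes are handled explicitly. With one observation per
subject the random intercept is unidentifiable and the fit falls back to
ordinary least squares (flagged `fallback_ols`). When the ML estimate of
the random-intercept variance reaches the zero boundary, the mixed
likelihood coincides with the OLS likelihood; the implementation detects
this both through the variance estimate itself and by evaluating the OLS
profile (if OLS matches or beats the optimizer's interior solution, the
boundary is the ML optimum) and uses the exact OLS likelihood, flagged
`singular`. This guarantees that at the boundary the mixed and ordinary
LRT p-values agree exactly. Non-converged fits mark the affected pair
untestable rather than contributing a silent verdict.

### Cross-omics integration

Features robustly associated with the contrast in each space are paired
across spaces (self-pairs guarded; samples aligned on the intersection
of the tables). Each pair gets a naive Spearman edge, BH-adjusted over
all candidate pairs; retained edges (adjusted p ≤ 0.05) are re-modeled
with the two-test rule in both orientations, and a reducibility verdict
reclassifies the feature's disease association as confounded by the
cross-omics feature. Edges are reported with both orientation verdicts —
the map shows associations; reducibility is an annotation, not a filter.

## The synthetic cohort generator

The generator emulates the feature-table level of a small repeated-
measures infection cohort; it does not attempt read-level metagenomes or
spectra. Reference design: 15 controls / 22 mild / 8 severe subjects,
two samples each. Clinical covariates are subject-level: antibiotics
(binary; prevalence 0.2 in mild rising to ≈0.64 in severe at the default
dependence strength, always 0 in controls), hospitalization days and a
comorbidity index (Gaussian with severity-shifted location; controls are
never hospitalized). A covariate's dependence on severity is a single
strength parameter in [−1, 1]; strength 0 gives exact independence. For
simulation studies that *condition* on a coupling (e.g. a point-biserial
of ≈0.5 between antibiotics and severity), binary covariates can be
assigned by exact per-group counts instead of Bernoulli draws, pinning
the realized design.

Every feature is built on a latent Gaussian signal per observation:
planted effect + subject intercept u ~ N(0, σᵤ²) + residual ε ~ N(0, 1),
with σᵤ = 0.5 by default so the mixed model is non-degenerate. Binary-
driver effects are location shifts calibrated by the closed-form
relation δ = 2Φ(Δ/(√2 σ_tot)) − 1; |δ| = 1 uses a 12 σ shift (complete
separation). Continuous and mediated effects are specified on the
Spearman scale and calibrated through the bivariate-normal identity
ρ_Pearson = 2 sin(π ρ_S/6), applied to normal scores of the driver (or
to the upstream feature's realized latent, for mediation chains, which
are topologically ordered and checked for cycles). Confounded features
depend *only* on their covariate; mediated features *only* on their
upstream feature.

Observation models: metabolite/cytokine panels are strictly positive
log-normal, monotone in the latent signal, so rank statistics see the
planted effect size exactly. Taxa spaces draw per-feature base log
abundances N(0, 1.5²) and structural-zero rates uniform on [0.1, 0.6]
(effect-carrying taxa use [0.1, 0.25] — the associations the framework
studies live on prevalent taxa, and this keeps them clear of the
prevalence filter), then sample Poisson counts against a log-normal
library size centered at 5× the space's rarefaction depth (σ = 0.35),
with a 5% admixture of shallow libraries to exercise the rarefaction
drop rule. Zero inflation and counting noise attenuate planted effect
sizes in taxa spaces; the calibration guarantees therefore hold on the
latent/monotone scale and are tested on the metabolite panel.

A *diversity effect* plants the classic community-disturbance pattern:
a dedicated structural block of 12 extra taxa holds half of each
sample's mass, with fixed evenly-spread loadings and a per-sample
temperature exp(strength · driver) that concentrates the block's mass
when the driver is on, lowering Shannon entropy. Because mass moves only
*within* the block (the block total is pinned to the rest of the
sample), the relative abundances of all planned features are untouched —
planted nulls stay null under compositional closure. Block taxa are
recorded in the truth ledger as driver-responsive with unspecified
magnitude (target 0) and are excluded from recovery-rate denominators.

Randomness flows from one root seed through named substreams (metadata,
per-space features, per-space observation, rarefaction), so each module
regenerates independently and all outputs are byte-identical given the
seed.

## Preprocessing

Rarefaction is multivariate-hypergeometric subsampling (without
replacement) to a fixed depth (defaults: 10 000 reads for gut, 600 for
oropharyngeal samples); samples below depth are dropped and the drop
list recorded. Genus binning sums mapped features and conserves
per-sample totals exactly (unmapped features go to an `unassigned` bin).
Counts are converted to relative abundances and features are removed
when (a) nonzero in strictly less than 20% of samples, (b) mean relative
abundance below 1e-4, or (c) exactly constant (zero variance; tested by
range, since floating-point variance of identical values is not exactly
zero). Removal reasons are logged per feature. Survivors take a natural
log after a per-feature pseudocount of half the smallest nonzero
relative abundance — the transform only needs to be monotone for the
rank-based stages, and the pseudocount convention is surfaced as
configuration and recorded in the run manifest rather than hidden.
Shannon entropy H = −Σ p ln p (nats) is computed per sample on rarefied
counts and passed downstream as an ordinary feature
(`shannon_diversity`); no other diversity statistic is computed.

## Calibration and validation studies

The studies in `deconfound.simulations` (reported by
`scripts/acceptance.py` and asserted in the test suite) run the full
framework on freshly generated cohorts:

- **Null calibration** — 2000 pure-noise metabolite features on the
  reference cohort, status contrast: KS distance of raw disease
  p-values from uniform, and the fraction of null features ending up
  labeled robust (≤ a few per mille in practice). Because the naive
  screen uses clustered repeated samples as-is (intraclass correlation
  0.2 under the generator defaults, design effect 1.2), the rank-sum
  test is mildly anti-conservative: the p-value distribution sits at a
  systematic KS distance of ≈0.04 from uniform, and a 2000-feature
  measurement scatters around it by roughly ±0.015. This is a property
  of the naive stage only — the final classification gate (BH + the
  mixed-model stage, which does model the clustering) is what controls
  the false-robust rate, and that is the quantity that stays bounded.
- **Confounder recovery** — 45 patients (22 mild / 23 severe), two
  samples each, antibiotics pinned at point-biserial ≈0.5 with severity;
  per replicate one cytokine generated solely from antibiotics (δ = 0.8)
  and one solely from severity at equal magnitude. Over 200 replicates
  the confounded feature is labeled `confounded: antibiotics` in ≈95%
  and the direct feature stays `D` in ≈100%.
- **Mediation recovery** — a planted taxon → metabolite → cytokine chain
  (severity drives the taxon, links at Spearman 0.8) among null
  features: over 200 replicates the cross-omics stage retains both true
  edges in ≈80% and reclassifies the cytokine–severity association as
  reducible to the metabolite in ≈95%; forced pairings of independent
  features are retained at ≤ the FDR level.
- **Qualitative structure** — severity drives gut diversity directly
  while antibiotics (coupled to severity) drive oropharyngeal diversity:
  the pipeline labels gut `shannon_diversity` robust and oropharyngeal
  `shannon_diversity` `confounded: antibiotics`.
- **Effect-size calibration** — 200 metabolite features planted at
  δ = 0.5 are recovered by the naive screen to within a few hundredths
  on average.

Problem sizes (45 subjects, 2000 null features, 200 replicates) are the
package's reference desk scale: large enough for stable rates, small
enough to re-run routinely.

## What passing these studies does and does not show

The generator's latent-Gaussian, monotone-observation world is
deliberately idealized: real cohorts have heavier tails, batch
structure, informative missingness, uneven sampling schedules, and taxa
whose abundances are compositionally entangled beyond a structural
block. Passing the battery shows the *classification machinery* is
correct and calibrated under known ground truth — not that any
particular real-data association is true. Statuses are statements of
statistical reducibility, not causal claims: a "confounded" label means
the disease signal is explainable by the named variable on these data,
and an "ambiguous" label usually reflects insufficient power to separate
collinear explanations, not evidence of absence. With eight severe
subjects, severity-contrast power is intrinsically limited; the
two-test rule inherits the usual hazards of conditioning on a collider
and of measurement error in the competitor variable (a noisily measured
confounder can fail to absorb the signal it truly drives).
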