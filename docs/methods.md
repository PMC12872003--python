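# Methods

## Setting and data model

The package analyses a comparative larval source management (LSM) trial
across eight sub-districts of Kwaebibirem District, Ghana: four
intervention districts where drone mapping and AI risk triage replaced
manual scouting, and four controls running conventional LSM. The unit
of comparison is the sub-district. Inputs are plain CSV logs —
sub-district metadata (arm, population, area, LSM start month),
work-phase records (workers × days), monthly spray logs (found sites,
sprayed sites, larvicide packs), drone-vs-manual detection counts,
CDC light-trap catches (site, week, genus, sex, count), and waterbody
feature tables. The trial's own printed records are packaged as
fixtures and audited by tests against their printed totals.

## Efficiency indicators

**TPDUA** (total person-days per unit area) is
`(1/S) Σᵢ Wᵢ·Dᵢ` with S the operation area in km². It is additive over
phase lists and homogeneous of degree −1 in area; both properties are
property-tested. An empty phase list contributes 0 person-days rather
than an error so partially-logged districts aggregate safely.

**Sites per pack** is sprayed sites divided by larvicide packs per
month; **detection ratio** is drone-found over manually-scouted sites
(undefined, and an error, when the manual count is zero); **high-risk
ratio** is sprayed/found in the intervention arm (control districts
spray every found site, ratio 1 by design).

**Quartiles are Tukey hinges**: the median of each half-sample, halves
including the middle observation when n is odd; at n = 4 each hinge is
the midpoint of a pair. This choice is deliberate — with four districts
per arm, linear-interpolation quartiles give 2.95/2.90-type values and
cannot reproduce the published interquartile ranges, while hinges
reproduce all four printed IQR pairs exactly.

**Display rounding** is half-away-from-zero (2.905 → 2.91), applied
only when rendering; all computation carries full precision. Values are
pre-rounded at 10 decimals before the display quantization so binary
float artefacts (e.g. `(5.41+6.72)/2 = 6.0649999…`) cannot flip a tie.
Two conventions follow the way the source summaries were evidently
derived: arm-level "average" rows are means of per-district indicator
values, not ratios of arm totals (169 vs the totals-ratio 169.2), and
the reproduction harness feeds the *display-rounded* per-district
TPDUAs into the group summaries, since the printed medians/IQRs are
functions of the printed two-decimal table (6.065 → 6.07 for the
control lower hinge; the full-precision hinge is 6.064).

## Economics

The daily wage R compounds a base monthly salary through ordered annual
adjustment fractions and divides by working days per month; with the
defaults (GHS 2,594; +30%; +23%; 20 days) R = 207.39 GHS/day (monthly
4,147.8). The per-operation labor margin is `M = R·S·(Ec − Ep)`, linear
in each factor; Ec and Ep default to the arm *mean* TPDUAs (8.03, 4.00)
rather than medians because the published savings curves are built on
the table averages. Break-even reports both the continuous `C/M` and
the smallest integer n with `n·M ≥ C` (integer arithmetic verified
against a linear-scan oracle); with the defaults this is 8.97 → 9
cycles. The prose claim of "approximately ten" cycles is treated as
qualitative: with mean-based inputs the computation gives ≈9, with
median-based inputs (7.23 − 3.92) ≈11, and the package exposes both
input choices rather than guessing the original arithmetic. Currency is
a plain positive real tagged GHS; no discounting. (For context, labor
is reported elsewhere to be ~58% and larvicide ~14% of LSM programme
cost; the package reports these only as documentation constants.)

## Exact inference

With four districts per arm the rank-sum test must be exact. U is
`min(U_A, U_B)` computed from mid-ranks; the two-sided p is
`min(1, 2·min(P(U_A ≤ u), P(U_A ≥ u)))` with the null distribution
enumerated over all C(n₁+n₂, n₁) assignments of the pooled mid-ranks
(ties thereby handled by permutation of tied ranks). Complete
separation at 4-vs-4 gives p = 2/70 ≈ 0.029 — the trial's headline
value — regardless of magnitudes. Enumeration is used up to a pooled
n of 20 (C(20,10) = 184,756 assignments, well under a second); beyond
that the tie-corrected normal approximation without continuity
correction is substituted and flagged in the result's `method` field.
The implementation is enumeration over rank vectors; tests cross-check
it against an independent pairwise-comparison-count oracle.

The chi-square is plain Pearson `Σ(O−E)²/E` without Yates correction
(the correction is a 2×2 device and the published 3×2 statistic, 33.63,
is uncorrected), expected counts from the product of margins; any zero
margin is an error. Confusion-matrix metrics report precision/recall as
NaN ("missing") when their denominators vanish rather than forcing 0
or 1.

## Risk classifier

Larval risk is a binary label (any larva found ⇒ high risk). The
classifier is a gradient-boosted decision-tree ensemble over the six
categorical features with native categorical splits
(scikit-learn `HistGradientBoostingClassifier`); the contract is the
config surface, not a serialization format: iteration cap (default
1000), tree-depth cap (default 10), early stopping on an internal 10%
validation split with patience 50 (the original early-stopping protocol
is unpublished, so this is the package's own documented choice), fixed
decision threshold 0.5, and a seed that makes training and prediction
deterministic. Unknown category levels at prediction are an error
naming the level — field-data hygiene over convenience.

Evaluation is stratified 5-fold cross-validation (folds preserve the
class ratio; metrics are unweighted fold means of confusion-count
accuracy/precision/recall). "Recall-first" tuning is implemented as
model selection maximizing CV recall subject to a configurable
precision floor (default 0.3), encoding the operational asymmetry that
missing a productive habitat costs more than overtreating. Feature
importance is permutation importance on the supplied data (10 repeats),
clipped at zero and normalized to percentages (RFI) summing to 100.

The original ~4,000-waterbody training survey (Sierra Leone and Greater
Accra) is not publicly deposited, so the published CV numbers
(accuracy 0.70 / precision 0.70 / recall 0.72) are context, not a
reproducible target. The classifier stage is instead validated by
*parameter recovery*: on synthetic data from a known conditional-risk
process, held-out recall and precision must land within ±0.05 of the
Bayes rule's exact values computed over the full feature lattice
(asserted at n = 4000). Likewise the field confusion matrix's published
metrics (0.70/0.40/0.875) come from a figure whose cell counts are not
printed and do not reconcile to a unique integer matrix; the
`field_validation` operation is tested against loop oracles and
constructions (e.g. recall 7/8 = 0.875) instead.

## Entomology

Proportions follow each published percentage's implied base: genus and
sex shares are fractions of the mosquito total, the mosquito share is a
fraction of all insects captured. Weekly series are 1-based, ascending,
zero-filled over the common trapping calendar, and exclude non-target
by-catch by default. The genus-by-site contingency table keeps genera
with total count ≥ 2 by default — a general exclusion rule that, on the
packaged data, drops exactly the single Mansonia specimen — and tests
verify conservation: table cells + excluded genera + non-target
by-catch = total insects captured.

## Synthetic generator

`gen_waterbodies` draws the six features independently from
configurable marginals and the label from
`Bernoulli(sigmoid(intercept + Σ weights))`, additive log-odds over the
drawn levels — the simplest generative process a boosted-tree learner
should recover, with an exactly computable Bayes rule. Default weight
magnitudes are ordered waterbody type > turbidity > vegetation inside >
origin > vegetation around > size class, mimicking the field model's
RFI ranking, and the intercept (−0.57) puts lattice prevalence near
0.5, echoing the observed high-risk ratios (0.56–0.75). The returned
`GroundTruth` carries all 672 cell masses and presence probabilities,
from which prevalence and Bayes accuracy/precision/recall are computed
in closed form.

`gen_operation_log` gives intervention districts separate mapping and
spraying phases and controls a single combined phase (the two
workflows' actual day structures); phase days are `1 + Poisson(rate ×
area)` with per-arm crew sizes and rates, intervention spraying treats
`round(found × high_risk_spray_fraction)` sites (default 0.62) and
controls treat everything. `gen_trap_catches` draws weekly mosquito
totals Poisson(45)/site, splits them multinomially over a
Culex-dominant genus mix (0.909/0.047/0.043/0.001), sexes binomially
(75.5% female), plus a Poisson(11) non-target stream. All randomness
flows through one `numpy.random.default_rng(seed)`; identical config
and seed give identical tables.

What the generator does *not* emulate: spatial structure and habitat
contiguity, seasonality and rainfall dependence of catches, feature
correlations (features are independent by construction), observer
subjectivity in turbidity grading, and label noise from imperfect
dipping. Passing recovery tests therefore show the pipeline recovers a
known additive-log-odds process at survey scale — not that the field
model's published metrics are correct.

## Problem sizes and determinism

The test suite runs the classifier recovery at n = 4000 with 5-fold CV
(~1–2 s), the calibration checks at n = 20,000 draws, and the
operation-log resampling oracle over 200 replicates of 8 districts —
sizes chosen so the full suite completes in seconds while keeping
Monte-Carlo error well inside the asserted tolerances (3 SE bands for
calibration, ±0.05 for recovery). Property tests run under a
derandomized hypothesis profile. The reproduction harness and the
acceptance script are closed-form functions of the packaged tables and
are bit-deterministic.

## Known limitations and source-table quirks

The packaged tables preserve the source's internal inconsistencies as
printed, surfaced by `fixture_notes()` rather than corrected: the
detection table and the spray log swap Nkwantanang's and Abaam's
found-site counts (154/131); three quoted high-risk ratios differ in
the third decimal from sprayed/found on the printed counts; and the
narrative's per-site mosquito totals (430/353) swap their attached
percentages while the contingency table's Pramkese column totals 429
(the excluded Mansonia). The packaged trap-catch table reproduces every
printed weekly value and total exactly; weeks the narrative does not
enumerate are a synthetic completion constrained to the printed
site/genus/sex totals and are flagged as such. Statistical power at
n = 4 per arm is minimal — the exact test's floor of p = 2/70 is the
only attainable "significant" value — so the rank tests are supportive,
not definitive, and the package makes no multiplicity adjustment
(none was applied in the source analysis).
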