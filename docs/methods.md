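# Methods

## Data model and deduplication

Input is the FAERS quarterly ASCII layout: six `$`-delimited tables keyed
by PRIMARYID (report version) and CASEID (case). Files are read as Latin-1
with replacement (FAERS extracts contain non-UTF-8 bytes); rows whose field
count disagrees with the header are counted and skipped, never silently
dropped. Dates are parsed leniently into partial dates (day / month / year
/ invalid precision); only day-precision dates participate in arithmetic.

Deduplication keeps, per CASEID, the row with the latest FDA_DT and then
the highest PRIMARYID (numeric comparison for all-digit ids). Partial
FDA_DT values order by zero-filled (year, month, day); when every candidate
of a case has an unparseable FDA_DT the highest PRIMARYID alone decides,
with a warning. Deduplication is idempotent and runs on the pooled
multi-quarter DEMO concatenation before any event filtering; rows of other
tables belonging to non-surviving PRIMARYIDs are discarded.

## Cohort construction

A case is event-positive when at least one of its reaction PTs matches the
configured preferred-term list — by PT code when the row carries one,
otherwise by case-folded, whitespace-collapsed name. The bundled VTE PT
list is an editable stand-in covering the common venous thromboembolism
preferred terms; real analyses should substitute their own MedDRA-derived
list. Signal analysis uses primary-suspect mentions only; one (case,
ingredient) pair counts once however many PS rows repeat it. Verbatim drug
names resolve through a many-to-one synonym dictionary after normalization
and the stripping of trailing dosage/form tokens; unmapped names are kept
under their normalized verbatim string, still contribute to totals, and are
excluded from per-drug ranking unless requested. Fixed-dose combinations
are treated as their own ingredient entities.

## Disproportionality statistics

Counting unit: the deduplicated case. For drug D the 2×2 table is
a = event-positive cases with D as PS, b = D without the event,
c = event without D, d = neither; N = a+b+c+d.

* **ROR** = ad/(bc); 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  Any zero cell triggers the Haldane correction (+0.5 to all four cells)
  and the result is flagged.
* **PRR** = [a/(a+b)]/[c/(c+d)]; the accompanying χ² is the 2×2 statistic
  with expectations from the marginals and Yates continuity correction
  (terms (max(|O−E|−0.5, 0))²/E; configurable off). Zero drug or comparator
  margins are hard errors naming the margin.
* **BCPNN information component.** Default `simplified` variant:
  IC = log₂(aN/((a+b)(a+c))) (continuity-corrected on zero cells) and
  IC025 = IC − 2√V with V the three-term posterior variance of the
  beta-binomial model with vague priors (α=β=2, α₁=β₁=1, γ₁₁=1, γ
  calibrated so the expectation vanishes at independence). The `bate`
  variant reports the posterior expectation E(IC) under the same prior.
* **MGPS.** Default `closed_form` variant: EBGM = aN/((a+b)(a+c)) (the raw
  relative reporting ratio) with a one-sided lognormal 5th percentile
  (z = 1.645), continuity-corrected on zero cells. The `em` variant fits
  DuMouchel's two-component gamma–Poisson mixture prior on λ (observed
  a ~ Poisson(λE), E = (a+b)(a+c)/N) by direct maximization of the
  negative-binomial marginal likelihood (L-BFGS-B on log shapes/rates and
  logit weight, started from (0.2, 0.1, 2.0, 4.0, 1/3); components ordered
  by prior mean to fix label switching); EBGM is then exp E[ln λ | a] and
  EBGM05 the posterior 5th percentile solved from the mixture-gamma CDF.
  The closed-form variants are the defaults for reproducibility; both
  variants are exposed because published FAERS screens rarely state which
  they used.

**Combined rule** (all four must hold; thresholds configurable):
a ≥ 3 ∧ ROR CI lower > 1; a ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4; IC025 > 0;
EBGM05 > 2. Positive drugs are ranked by ROR descending (ties: larger a,
then drug name) and cut at cumulative ranks floor(0.05n) / floor(0.20n) /
floor(0.50n) into levels A/B/C/D. The floor convention reproduces the
canonical 6/21/40/68 split of 135 drugs.

## Time-to-onset

TTO = (EVENT_DT − START_DT in whole days) + 0.5, so a same-day onset
contributes half a day. The therapy start is the earliest valid START_DT
among the case's therapy rows. Records with non-day-precision or invalid
dates are excluded (`missing_date`/`partial_date`), as are non-positive
intervals (`negative_or_zero`, onset before start being an input error);
inclusion and exclusion counts always conserve the input count.

The two-parameter Weibull (scale α days — the 63.2% quantile — and shape
β) is fitted by ML: the shape solves the one-dimensional profile
estimating equation Σtᵝln t/Σtᵝ − 1/β − mean(ln t) = 0 by bracketed
bisection (deterministic, no random initialization; data pre-scaled to
geometric mean 1 for conditioning), the scale then has the closed form
(mean tᵝ)^(1/β). 95% CIs come from the analytic observed information in
(ln α, ln β), back-transformed — deterministic and fast; per-drug fits
require more than 10 records. Failure modes are called against the shape
CI: `early` when β̂ < 1 with CI upper < 1, `wear_out` when β̂ > 1 with CI
lower > 1, otherwise `random`.

Group comparisons use the Kaplan–Meier estimator (onset times are fully
observed, so 1 − S(t) equals the ECDF) and the k-sample Mantel–Cox
log-rank test, both via lifelines. Quantiles throughout are type-7
(linear interpolation).

## Descriptives

Age bins {<18, 18–44, 45–64, 65–74, ≥75}; sex percentages out of the full
cohort (unknown is a level); countries ranked by count; outcomes tallied
one per case in severity order DE > LT > DS > HO > CA > RI > OT (so the
outcome percentages partition the cases with any outcome); reporter
occupation mapped from OCCP_COD. The annual series counts reports and
death reports (DE) by FDA_DT receipt year — receipt year is complete in
spontaneous-report extracts, while event years are not — with
year-precision dates contributing and invalid dates excluded and logged.

## Synthetic generator

The generator draws independent cases: per-drug exposure is
Bernoulli(background_use_prob), one exposed drug (forced draw when none)
becomes the primary suspect and the rest concomitant mentions; the target
event occurs with probability base_event_prob × true_rr(PS drug) —
association injected on the reporting-ratio scale, which is what
disproportionality estimates; configurations where the scaled probability
exceeds 1 are rejected at validation. Onset times are Weibull(α, β) per
drug, emitted as day-precision START_DT/EVENT_DT (a configurable fraction
of event dates degraded to month precision or dropped to exercise the TTO
exclusions); FDA_DT adds a 30–400 day reporting delay. Duplicates clone a
case under a higher PRIMARYID and later FDA_DT, so deduplication must
restore exactly n_cases. Ground truth (per-case PS drug, event flag, onset
time, duplicate map) is returned alongside and the exact 2×2 counts are
recomputed from it by brute-force recount.

Defaults are chosen to emulate a large VTE-style safety cohort: event
prevalence 1%; sex mix 55% female / 35% male / 10% unknown; age normal
with median 56 y (sd 22, clipped to 0–105); weight lognormal with median
80 kg; country, outcome and reporter-occupation marginals matching a
typical mostly-US cohort; onset model α = 120 days, β = 0.649 (an
early-failure pattern); 5% duplicate fraction. The default drug panel has
two associated drugs (reporting ratios 8 and 4) and three nulls, each with
synonym spellings to exercise the dictionary.

What the generator does **not** emulate: correlated co-prescription,
free-text drug-name noise beyond the configured synonyms, secular trends
in reporting, within-case dependence of multiple events, and
under-reporting structure. Passing tests therefore demonstrate
correctness of the pipeline's computations and calibration under the
stated generative model, not performance on real FAERS data.

## Numerical conventions and problem sizes

Continuity corrections are applied only when a zero cell occurs and are
flagged in output. The mixture fit raises on optimizer failure, carrying
the last parameter values. Weibull fitting refuses fewer than the minimum
records or an all-identical sample (degenerate likelihood). The test
suite exercises the end-to-end detection and null-calibration properties
at 100 000 synthetic cases (5 injected associations at RR 10 among 50
nulls; 200 all-null drugs), EM recovery at 5 000 pairs, and Weibull
recovery at 1 000–20 000 onset times — sizes at which the stochastic
checks are stable under fixed seeds while the whole suite runs in about a
minute.

## Known limitations

* The XML dialect and the pre-2004 legacy AERS schema are out of scope.
* Partial dates are excluded from TTO rather than treated with an
  interval-censored likelihood.
* Disproportionality is unadjusted (no age/sex stratification of the
  expected counts).
* The bundled PT list is a stand-in; results on real data depend on the
  user-supplied MedDRA term list and drug synonym dictionary.
* With several strong signals in a small simulated drug panel, the
  comparator background is inflated and realized RORs sit below the
  injected reporting ratios; this dilution is a property of the design,
  not a bug.
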