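# Methods

This package measures physician turnover at the level of the primary care
centre (PCC) from raw consultation events, and relates it to practice
characteristics. Because the motivating data — a regional care database in a
system where GPs are salaried employees — is confidential, the package ships a
synthetic registry generator with known ground truth; every measurement stage
is exercised and validated against that ground truth or against closed-form
oracles.

## The measurement model

**Regular workforce.** The workforce of practice *j* in calendar month *m* is
the set of physicians with consultations on at least `min_days` distinct days
in (*j*, *m*). The reference threshold is 10 days; 15 and 20 are sensitivity
settings. Only heads are counted, not visit volume.

**Spells.** A spell is a maximal period of regular care provision by one
physician at one practice. Sorted distinct consultation dates of a
(physician, practice) pair are segmented wherever the break between
consecutive consultations is at least `gap_days` (365 by default, inclusive:
a break of exactly 365 days ends the spell). The rule deliberately absorbs
leaves of up to a year. Spell duration is the day count between first and
last consultation. A spell whose last consultation lies within `gap_days` of
the end of the data is flagged *censored*: its termination cannot be
confirmed.

**Turnover within a horizon.** For each practice-month with a non-empty
workforce and each horizon *h* ∈ {6, 12, 18, 24, 36, 48, 60} months,

&nbsp;&nbsp;&nbsp;&nbsp;Turnover<sub>jm</sub>(h) = 100 ·
#{members whose spell ends on or before the last day of month *m*+*h*} /
#{members of (*j*, *m*)}.

Only months whose horizon fits inside the data window are emitted. Censored
members are governed by `censor_policy`: the default `as_ongoing` counts them
as stayers (conservative), `as_ended` trusts the observed last date, and
`exclude` drops them from numerator and denominator. In the packaged
analyses the final measured year is additionally chosen so that both the
horizon and the 365-day confirmation window fit inside the data, which keeps
the default policy unbiased.

**Aggregation.** Monthly rates are averaged over the defined months of each
practice-year; a practice-year with no regular workforce in any month is
imputed with the practice's mean over its observed years (the count of
imputations is reported). A practice with no observed year at all is dropped
from the analysis population with a report entry — there is nothing to
impute from. Practice-year rates are averaged again into a time-invariant
practice-level rate, the outcome of the association analysis. All rates are
carried as percentages.

**Permanent-staff turnover.** Consultation data cannot distinguish contract
types, so a separate rate is computed from employment records: among
physicians on a given contract employed at the practice on 31 January, the
share whose employment ends during that calendar year. Mid-year hires are
excluded from both numerator and denominator, keeping the ratio within
[0, 100].

**Mixture decomposition.** If the overall workforce turns over at rate *T*
and permanent staff at rate *P*, and temporary spells end within a year with
probability *E* (taken as 100%), the temporary share of the workforce solves
*T* = (1−*s*)·*P* + *s*·*E*. With *T* ≈ 30 and *P* ≈ 14 this gives
*s* ≈ 0.19 — about one fifth.

**Covariate coding.** Practice-level means of size (registered patients),
morbidity (ACG-style case-mix score relative to the regional mean),
deprivation (CNI-style score), and workload (registered patients per
workforce physician, averaged over months with a defined workforce) are coded
into terciles of the practice-level distribution. The coding is rank-based: a
value with minimum rank *r* among *n* gets code ⌊3(*r*−1)/*n*⌋+1, so ties
fall into the lower tercile and the groups differ in size by at most one when
values are distinct. Code 0 marks a missing underlying value (workload has no
missing level; a practice without a computable workload is dropped from
specifications that include workload dummies and reported).

**Association analysis.** Boxplot-style summaries use linear
rank-interpolated quantiles and the adjacent-value whisker rule: whiskers end
at the most extreme observations inside p25/p75 ∓/± 1.5·(p75−p25); points
outside are outliers. The regressions are OLS of the practice-level rate on
dummy sets for the coded covariates (reference categories: lowest terciles,
public ownership, city location) in three specifications — full, without the
private dummy, without the workload dummies — with heteroskedasticity-robust
HC1 standard errors (sandwich estimator scaled by n/(n−k), the convention of
the major econometrics packages). Missing-category dummies are estimated but
reported as auxiliary. Stars: * p<0.05, ** p<0.01, *** p<0.001.

## The synthetic registry

The generator emulates the features of the motivating registry that the
measurement depends on; defaults (in `SimulationConfig`) are the package's
reference study conditions:

* **Panel**: 157 practices over 2010–2019; 55% public. Private practices
  split into investor-owned chains, a national GP partnership, local chains
  and GP-owned independents (0.251/0.058/0.045/0.096 unconditionally).
  Locations: city 0.49, commuting 0.11, town 0.17, rural 0.23. About 10% of
  practices open mid-panel and 7% close (the closure month winds every spell
  down; the closure year never enters the panel).
* **Staffing**: permanent slots per practice ~ Poisson with mean 5.6 scaled
  by (patients/8,665)^0.7, at least 1; 0.85× in private practices (which
  induces the private–workload correlation); 0.5 registrar slots. Temporary
  slots are sized so that `temporary_share` (default 0.20) is the share of
  temporary contracts among *measured* workforce member-months: a temporary
  spell of mean M months has only M−1 threshold-qualifying months, so slot
  counts are scaled by M/(M−1).
* **Exits**: memoryless monthly hazards per contract — permanent 0.0134
  (annual spell-end probability 1−(1−q)¹² ≈ 14.9%), registrar 0.011,
  freelance 0.25; fixed-term contracts draw their length at hire (geometric,
  mean 4 months) and end at expiry; foundation placements last 6 months. A
  physician's exit month is a partial month with 1–9 consultation days (they
  leave mid-month, below every workforce threshold) and the employment record
  ends on that month's last day. Under this convention the probability that a
  current workforce member's spell ends within h months is exactly
  1−(1−q)^h, and the January-workforce employment rate has the same
  expectation — the closed forms the recovery tests check.
* **Activity**: full months draw distinct consultation days from a rounded
  normal (mean 13.5, sd 3.5, clipped to the month), placed uniformly without
  replacement; each consultation day carries a visit count targeting an IQR
  of 6–8 visits/day (drawn but unused by the head-count measurement). With
  10% probability a long spell contains a leave of up to `leave_max_days`
  (300) — a consultation-free block short enough that the gap rule absorbs
  it. Newly opened practices emit only sub-threshold activity for their
  first 18 months, which reproduces the observed pattern of ~15 recently
  established practices contributing ~25 workforce-free practice-years to
  the imputation rule. Optionally (`return_prob`) a refilled permanent slot
  rehires a previously departed physician after a gap long enough to start a
  second spell.
* **Covariate ground truth**: morbidity and deprivation scores are normal
  around 1 (sd 0.11 and 0.36); registration counts are a practice-level base
  (normal, mean 8,665, sd 3,802, truncated at 500) with 1% monthly noise.
  `covariate_effects` shifts the permanent/registrar exit hazard additively:
  tercile effects per step *relative to the middle tercile* (so the mean
  hazard, and hence the ~30% overall turnover, is unchanged) and indicator
  effects for private ownership and town location. The defaults
  (size −0.003, deprivation +0.003, workload +0.0035, private −0.004,
  town +0.006, morbidity 0) reproduce the sign and ordering of the observed
  associations at magnitudes that keep the additive hazard inside its linear
  range; larger values would clip at the hazard floor and attenuate
  contrasts. Morbidity is left at zero because its observed association is
  non-monotone (inverse U), which a linear per-step shift cannot represent.
* **Randomness**: one substream per (practice, purpose) spawned from the
  root seed, so adding a practice leaves the draws of the others untouched
  (exactly true when covariate effects are off; tercile cut points couple
  practices by construction).

What the generator does *not* emulate: physician mobility between practices
(each physician works at one practice; returns only via the explicit
mechanism), patient-level visit assignment, seasonality, secular trends, and
any behavioural response of exits to workload or covariates beyond the
configured hazard shifts. Passing tests therefore certify the measurement
pipeline — segmentation, counting, aggregation, estimation — not the realism
of any particular covariate effect in real registries.

`sample_practice_panel` is a separate, fast practice-level sampler (covariate
codes drawn independently, outcome = known linear predictor +
heteroskedastic noise) used for estimator-calibration studies where hundreds
of full-registry replications would be wasteful; its coefficients are exact
by construction.

## Numerical and design choices

* Rates are percentages end to end; shares (mixture) are proportions.
* Quantiles use numpy's linear interpolation everywhere.
* Dates are day-resolved; months are calendar months (`pandas.Period`).
  "Ends within h months" means last consultation ≤ last day of month m+h.
* A physician may belong to two practices' workforces in the same month; no
  exclusivity is imposed.
* Duplicate same-day events collapse for day counting but are preserved in
  event storage.
* The tercile tie rule (ties to the lower tercile) and the HC1 scaling are
  fixed project-wide so results are reproducible across software
  conventions.
* Degenerate inputs fail loudly with typed exceptions: empty event tables,
  unparseable dates (with row indices), horizons/thresholds < 1, infeasible
  mixture rates, rank-deficient designs (naming the collinear columns), and
  imputation without an observed year.

## Problem sizes in the packaged runs

The analysis scripts and the acceptance script use the reference registry
(157 practices × 10 years, ~1.7M consultation-day records, simulated in a
few seconds) for the main analysis; the hazard-recovery and mixture checks
use 100 practices × 8 years with the last two years reserved as horizon and
confirmation buffer; the robust-SE coverage study uses 500-practice panels
(400 replications in the script, 1000 in the test suite). Monte-Carlo checks
against the closed forms reproduce them within ~2% relative error, with no
bias detectable beyond Monte-Carlo noise at these sizes.

## Known limitations

* The spell rule cannot distinguish a true exit from a >365-day leave, and
  symmetric conventions for the exit month (mid-month departure vs full final
  month) change the within-h probability from 1−(1−q)^h to 1−(1−q)^(h+1);
  the generator and the measurement share one convention, documented above.
* Whether the motivating analyses counted unconfirmable tail spells as ended
  is unknowable from the published material; the package exposes the choice
  as `censor_policy` instead of guessing.
* Workload is endogenous to the workforce measurement (it divides by the
  same roster), so its regression coefficients should be read as
  associations, never effects.
* The imputation rule assumes a practice's missing years resemble its
  observed ones; for practices whose workforce-free years are systematically
  different (e.g. start-up years), the imputed rate inherits the level of
  the established years.
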