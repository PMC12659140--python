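# Methods

This note documents the statistical procedures implemented in
`regiscan`, the assumptions behind them, the defaults of the synthetic
registry, and the numerical choices made where the design was open.

## Study design being modelled

A matched cohort of children followed from birth to the earliest of
death, emigration or the fifth birthday (1,826 days; person-time in
365.25-day years).  Exposure is having at least one parent diagnosed
with lymphoma before the child's birth.  Each exposed child is matched
on maternal age to five children of lymphoma-free parents.  Outcomes
are coded healthcare contacts: inpatient admissions and outpatient
visits (ICD-10) and drug dispensations (ATC); dispensation analyses are
restricted to matched sets whose exposed child was born after the
Swedish prescribed-drug register opened (July 2005).

## Classification trees, masking, exclusion

ICD-10 and ATC hierarchies are ingested from TSV dictionaries
(code, parent, label, level) and validated (unique codes, single root,
resolvable parents, acyclicity).  Codes are normalised by upper-casing
and stripping dots, so the dot-free Swedish dialect and dotted codes
coincide.  Block and chapter nodes may be en-dash ranges
(e.g. `H65–H75`); range membership is decided on the 3-character stem.

Registry extracts deliver some chapters only at coarse granularity, so
events are *masked* before analysis.  The shipped ICD defaults: eye
diseases (H00–H59) and perinatal conditions (P00–P96) at chapter level;
congenital malformations (Q00–Q99) at block level; ear diseases
(H60–H95) at 3-character category level.  The ear chapter is a known
ambiguity — extracts have been described as block-level while reported
results include the category H66 — so the granularity is a per-rule
configuration, with the category default matching reported practice.
For ATC, class J (anti-infectives) keeps full 7-character detail,
classes A, B, C, G, H, L, M, N are truncated to five characters, and
the incompletely characterised classes D, P, R, S, V are coarsened to
3-character therapeutic subgroups (a package choice; the source
granularity for those classes is not documented).  Masking is
idempotent, and events whose codes cannot be resolved on the tree even
after coarsening are dropped with a counter.

Hospital-visit analyses exclude the chapters S00–T98 (injuries),
V01–Y98 (external causes) and Z00–Z99 (contact factors) wholesale;
removal counts are reported.

## Sampling weights and matching

Comparator parents enter the source platform by being sampled as
matches for lymphoma patients, which distorts their demographic mix.
The Kaplan–Meier-type inverse-probability-of-sampling weight for a
comparator in stratum *s* (sex × birth year by default), first eligible
in year *e* and sampled in year *t*, is

    w = 1 / ( ∏_{e ≤ u < t} (1 − p_su) · p_st ),    p_su = sampled_su / population_su,

the inverse product-limit probability of that sampling history.  When
the supplied population counts are the not-yet-sampled totals, each
sampling year's weighted comparators re-inflate to the full stratum
population (verified to 2% in tests).  The exact stratification of the
original platform's weights is not public; this product-limit reading
is one defensible construction, and the per-stratum-year probabilities
are exposed for audit (`.attrs["stratum_weight_table"]`).

Matching is greedy in seed-randomised exposed order, without
replacement, selecting comparators with probability proportional to
their sampling weight among those at the same integer maternal age
(widening to ±1 year when the pool runs short, logged).  Downstream
analyses pool the groups rather than conditioning on matched sets,
consistent with the unconditional Bernoulli scan; the weights are used
for cohort construction only and do not enter the scan.

## Rates and exact intervals

Incident analyses count at most one event per child, censoring that
child's person-time at the first event of the row's setting filter
(each setting row censors at its own first event); all-event analyses
count every event over full person-time.  The rate-ratio interval uses
the classical exact conditional construction: given m = c₁ + c₀, c₁ is
Binomial(m, π) with π = RR·t₁/(RR·t₁ + t₀); the Clopper–Pearson
interval for π (beta quantiles) is mapped through the odds transform to
RR, and the two-sided exact binomial test at π₀ = t₁/(t₁+t₀) gives the
p-value.  With c₀ = 0 the upper limit is infinite and flagged.  The
construction is invariant to rescaling both person-times and is
conservative by design (coverage ≥ the nominal level; verified ≥ 93%
empirically at RR ∈ {1, 2}).

Five-year risks are 100·c/n against the full cohort denominators; risk
ratios and differences are computed on unrounded risks and rounded to
two decimals for display.  Utilisation summaries use
linear-interpolation quantiles (the convention is stated because the
original one is unknowable).

## Mean cumulative count

MCC(t) = Σ_{u ≤ t} Ŝ_D(u⁻)·d(u)/n(u), with d(u) recurrent events at
age u, n(u) children still under observation (end of follow-up =
min(death, censoring)), and Ŝ_D the Kaplan–Meier survivor for death
censored by emigration/age five only.  Ŝ_D is evaluated
left-continuously; ties between events and deaths/censorings at the
same age are resolved event-first.  With no deaths the estimator
reduces to the Nelson–Aalen-type sum of d(u)/n(u); with no censoring
either, MCC at the horizon equals total events over n exactly.  The
implementation agrees with an independent daily-grid discrete-time
oracle to 10⁻⁹.  No variance bands are provided.

## Tree-based scan

Counting unit: the **distinct child** per cut — `n` children with at
least one event at or below the cut, `c` of them exposed.  This matches
reported 5-year risks (children over cohort size) and means the
Monte-Carlo relabelling operates on children, preserving each child's
correlation across codes (induced in the generator by the shared
frailty).  Event-level relabelling, where each child-code first event
is randomised independently, is available behind
`ScanConfig(relabel="event")` for comparison.  Cuts with n = 0 are
skipped; c = n is a valid maximum.  ICD and ATC trees are scanned
separately, each against its own null distribution, with p recomputed
for the drug sub-cohort.  Ranking is by descending LLR with
code-lexicographic tie-breaks, so outputs are byte-stable.

Calibration: under the model's own null (exposure labels iid
Bernoulli(p)), the family-wise rejection rate is 0.05 as constructed.
Applied to a cohort with *fixed* exposure margins — the matched design,
where exactly n₁ of N children are exposed — cut counts are
hypergeometric rather than binomial, with smaller variance for large
cuts, and the scan becomes mildly conservative (empirically ≈ 0.03 at
nominal 0.05 on the toy tree).  Conservatism, not inflation; both
behaviours are asserted in the test suite.

## Synthetic registry

The generator emulates the statistical structure the analysis assumes,
not Swedish morbidity: per child i and tree leaf j, events are Poisson
with mean `rate_j · g_i · m_i · T_i`, where g_i is a gamma frailty
(mean 1, variance 0.5 by default) shared across all leaves — one
sickness-propensity factor per child — and m_i multiplies in the
exposure effect.  Defaults: per-leaf baseline 0.02/year (≈ 0.8
events/child-year on the ~40-leaf toy ICD tree, the scale of an
early-childhood hospital-contact rate), uniform exposure multiplier
1.08 (the overall excess utilisation rate of the exposed group,
modelling health-seeking behaviour without disease clusters), optional
injected clusters multiplying exposed rates on the leaves under a cut,
death and emigration as independent exponentials (0.0005 and
0.005/year), and day-resolved dates uniform over follow-up.  Maternal
age is Normal(31, 4.5²) clipped to 18–45 in both groups; comparator
sampling weights are emulated as 1/U, U ~ Uniform(0.5, 1).

What the generator does **not** emulate: calendar-period and seasonal
effects, code-specific morbidity profiles, sibling clustering beyond a
shared parent id, dependence between death and morbidity, and
primary-care contacts (absent from the modelled registers).  Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not realism of Swedish childhood morbidity.

## Power analysis

Power for the scan design is estimated by brute force on a balanced
background tree (default three levels, 10×10×10 → 1,000 leaves, 1,110
cuts) with uniform per-leaf background first-event probability 0.002
(≈ 2 distinct background codes per child; ~14% event-free).  One
penultimate-level cut is the cluster: its leaves share per-leaf risks
solving 1−(1−q)^10 = prevalence for comparators and prevalence·RR for
exposed children.  Each simulation draws child-by-leaf first-event
indicators directly (first-event counting needs no event dates), runs
the full scan with 999 replicates, and scores a detection when the
cluster cut or a direct ancestor/descendant reaches adjusted p ≤ α.
Defaults: α = 0.05, target power 0.80 (a stated assumption — the
original criterion is unpublished), 200 simulations per grid point with
Monte-Carlo standard errors always reported.  The minimum detectable RR
search walks the grid in ascending order and stops at the first point
reaching the target, which is valid because power is monotone in RR.

At the study scale (1,424/7,120, 10% prevalence) this design lands at
1.5 on a 0.1-step grid, close to but slightly above the originally
reported 1.37 — expected, since the original simulation's background
tree, risks and power criterion are not fully specified.

## Problem sizes and numerical choices

Stochastic checks use sizes chosen as package defaults: family-wise
error on 500 null cohorts of 200/1,000 children on the toy ICD tree
(R = 999); signal recovery at the full 1,424/7,120 scale on a 216-leaf
tree; interval coverage on 2,000 Poisson pairs per true RR; power at
the full design described above (1,000-leaf tree, 200 simulations per grid
point).  Monte-Carlo replicate matrices are processed in chunks of at
most ~2×10⁷ label entries.  Degenerate inputs: empty event streams
yield empty outputs; zero-population strata, infeasible
prevalence×RR > 1 and matching failures raise typed errors naming the
offending unit.
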