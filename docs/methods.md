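# Methods

## The model

The package implements a knowledge-base-driven probabilistic engine for
interpreting verbal-autopsy (VA) interviews in the InterVA-5 lineage.
Each death is described by a vector of binary indicators (353 items in
the full WHO-2016 input format), with ternary responses yes / no /
missing. The knowledge base (KB) supplies, for every indicator *i* and
cause category *c*, the conditional probability P(substantive response
on *i* | *c*), encoded as a letter grade, together with an
unconditional prior P₀(c) per cause and two parallel blocks over
pregnancy-status categories and circumstance-of-mortality (COMCAT)
categories.

Per case, the posterior likelihood of category *c* is the naive-Bayes
product

    L(c) ∝ P₀(c) · ∏_{i ∈ S} P(i | c)

where *S* is the set of indicators whose recorded response equals
their *substantive value* — the evidential polarity of the item, which
may be "yes" ("Did she/he have a fever?") or "no" ("Was the placenta
completely delivered?"). Missing responses and responses of the
non-substantive polarity contribute no factor, so they carry no
evidence for or against any cause. This treats negative and unknown
responses alike; models that distinguish them (e.g. InSilicoVA) make a
different, deliberate choice.

The three classifications run in a fixed order: pregnancy status, then
cause of death, then COMCAT. Pregnancy status is the posterior argmax
over the pregnancy block; male deceased and neonates short-circuit to
the not-applicable category with likelihood 1. The cause posterior is
restricted to causes applicable to the case's resolved age band and
sex, and the maternal chapter (09.*) is gated to zero whenever
pregnancy status resolved to not-applicable. COMCAT is the argmax over
a configurable category list; its semantics are carried generically
(categories are configuration, not hard-coded meaning).

### Cause reporting and the indeterminate residual

Up to three causes are reported per case. The top-ranked cause is
reported only if its normalised likelihood reaches `top_min`
(default 0.4); the second and third only if they reach `ratio_min`
(default 0.5) of the top likelihood. Both thresholds follow the
InterVA lineage and are exposed in `ClassifierSettings` — the
published description fixes only the "up to three causes" contract, so
the constants are configuration. Unreported likelihood is the case's
*indeterminate* residual; reported + indeterminate ≡ 1 per case, which
makes per-case and population-level output mutually consistent.

## Knowledge-base parameterisation

* **Grade ladder** — the published KB spreadsheets encode
  probabilities as letter grades; the numeric ladder is not part of
  the publication, so the package ships an explicit default
  (A+ = 0.8, A = 0.5, A− = 0.2, B+ = 0.1, B = 0.05, B− = 0.02,
  C+ = 0.01, C = 0.005, C− = 0.002, D+ = 0.001, D = 0.0005,
  D− = 0.0001, E = 0.00001, N = 0) that is strictly decreasing,
  validated on construction, and fully overridable. `N` always means
  "no association" and annihilates a cause when its substantive
  response is observed.
* **Prevalence levels** — population HIV and malaria prevalence enter
  as prior multipliers on causes 01.03 and 01.05: high = 1 (reference),
  low = 0.1, very low = 0.01, configurable. Only priors are scaled
  (conditionals untouched), the multiplier is *set* rather than
  compounded (so the operation is idempotent and the two diseases
  commute), and scaled priors are clipped to [0, 1].
* **KB file dialect** — one plain UTF-8 CSV: indicator rows with
  optional metadata columns (question text, substantive polarity,
  sex/age applicability, exclusivity group, demographic role, format
  membership), cause-code grade columns, and `PREG:` / `COMCAT:`
  prefixed columns for the auxiliary blocks; reserved rows `PRIOR`,
  `SEX`, `AGE`. Prior cells may be grade tokens *or* numeric literals —
  the latter lets the synthetic generator plant an exact cause
  distribution that grade quantisation would distort.

## Input harmonisation and consistency rules

The WHO-2012 and Tariff-2 item sets are proper subsets of WHO-2016, so
format conversion is masking: responses on indicators outside the
target subset become missing, which in turn removes them from every
likelihood product. This guarantees the masking monotonicity property
(the substantive-response set under Tariff-2 is a subset of the set
under WHO-2016) by construction.

Consistency checking is rule-classified rather than exception-driven.
ERROR-class violations exclude the record: no resolvable age band, no
resolvable sex, or contradictory assertions of either. WARNING-class
violations blank the offending response and keep the record: a
substantive response on a sex- or age-inapplicable item, or more than
one "yes" inside a mutually exclusive category group (e.g.
fever-duration bands). The published rule list is not printed
anywhere, so the rule set here is configuration-driven and explicitly
not claimed complete. Demographics are resolved from designated *role*
indicators (male / female / neonate / child / adult); when a KB
defines none (tiny test fixtures), the demographic rules are skipped
rather than excluding everything. In exclusivity conflicts the
last-listed member is kept, on the convention that groups are listed
in ascending duration/severity — deterministic and conservative, and
always logged as a warning.

Continuous source items are expanded to one-of-k binary band
indicators with left-closed/right-open intervals; a missing
measurement yields all-missing bands.

## Population aggregation and evaluation

Cause-specific mortality fractions (CSMFs) are the mean of
individually assigned likelihoods: per stratum, CSMF(c) = Σ reported
likelihood for *c* / deaths in stratum, with the indeterminate
residual aggregated identically, so each stratum row sums to 1.
Aggregation deliberately uses the post-threshold reported likelihoods
(not the full posterior) so population output is exactly the sum of
the per-case output file. Strata default to the under-5 / 5-plus
reporting split with neonates in under-5.

Downstream operations all conserve mass to 1e-9: proportional
redistribution of the indeterminate fraction (scale by
1/(1 − indeterminate); idempotent; an all-indeterminate stratum is an
error), amalgamation of causes a comparator does not distinguish
(fresh + macerated stillbirths; dengue + other haemorrhagic fevers),
and rollup into the seven broad groups, derived from the WHO cause
code's chapter prefix unless overridden per cause.

Agreement between CSMF tables uses Lin's concordance correlation
coefficient with population (n-denominator) moments — the convention
of the Stata `concord` command —

    ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

with a 95% interval from the Fisher z-transform using Lin's asymptotic
standard error. Pairs are built over causes with a value present in
both tables for the stratum; near-zero rare causes are kept
deliberately (the conservative reading of concordance), and the
indeterminate row is included or excluded by flag — included by
default for same-model format comparisons, not applicable after
redistribution.

### Packaged evaluation tables

Two published comparison tables ship as CSV fixtures (percentages, two
decimals): the PHMRC tertiary-hospital comparison (6130 deaths;
hospital-assigned vs model-assigned CSMFs, indeterminate
redistributed) and the Afghanistan 2010 national mortality survey
format comparison (4009 deaths; WHO-2016 vs WHO-2012 vs Tariff-2 input
formats, indeterminate retained). Blank cells (causes not printed for
an age group) are carried as NaN and drop out of pairing.
`scripts/acceptance.py` recomputes all six published concordance
coefficients from these fixtures.

One caveat is asserted rather than hidden: four broad-group cells of
the hospital-comparison table are not the sum of their printed member
causes. In the ≥5 hospital column, ~3.3 percentage points (the 01.99
"other infections" mass) sit in "Other NCD" instead of "Infections",
and the <5 "Other NCD" cells include the stillbirth fraction. The
test suite verifies every other broad-group cell to printed rounding
and verifies that these four differ in exactly those two ways.

## Synthetic data

Because the published KB and the reference datasets are external
downloads, the test bed is synthetic. The generator builds a KB in
which each cause owns a disjoint signature set of indicators: the
signature cell snaps to the grade-ladder rung nearest
p_off + informativeness·(0.8 − p_off) with p_off = 0.05 ("B"), so
informativeness 0 degenerates to identical cause columns and
informativeness 1 reaches the strongest grade. Cohorts are drawn from
a planted CSMF with indicators conditionally independent given the
true cause, then thinned by a per-response missingness probability.
All randomness flows from a single seed.

Defaults — 30 indicators, 5 causes, informativeness 0.9, missingness
0.05, 2000-case cohorts for recovery checks (400–500 for faster
checks) — describe a clean, strongly informative archive at a size
where binomial sampling error (~0.01 on a fraction of 0.3) is well
inside the ±0.05 recovery tolerance.

The generative assumption *matches* the engine's own
conditional-independence assumption. That is deliberate: it makes CSMF
recovery a well-posed oracle test of the implementation. It is not a
realism claim — real VA data have correlated symptoms, informative
missingness, interviewer effects and reporting bias, so passing
recovery tests demonstrates correctness of the machinery, not expected
field accuracy.

## Numerical choices

* Likelihood products accumulate in log space (exact zeros tracked as
  −∞), so hundreds of small factors cannot underflow; results match
  direct products to well below 1e-9.
* A conditional of exactly 0 annihilates a cause. If every applicable
  cause annihilates, the engine falls back to uniform over the
  applicable set and flags the case (`all-causes-annihilated`).
* Argmax and ranking ties break by KB category order (stable sort),
  so output is deterministic under permutation of equal likelihoods.
* Zero-prior categories remain exactly zero through propagation.
* Posterior normalisation tolerance is 1e-9 throughout; mass
  conservation in population operations is asserted at 1e-9.

## Open design points resolved here

* Whether prevalence levels scale conditionals as well as priors is
  unstated in the published description; priors-only is implemented.
* Whether pregnancy likelihood should weight maternal-cause priors
  continuously is unstated; hard gating on the not-applicable status
  is implemented as the simpler reading of the staged processing
  order.
* The "not applicable" pregnancy category is identified positionally
  (last column of the pregnancy block), documented in the KB dialect.
* The `cli` module is a thin `click` wrapper (`classify`, `csmf`,
  `compare`, `simulate`) over the library; all logic lives in the
  library modules.

## Limitations

* The published numeric knowledge base and the full 353-item registry
  are not shipped; structural counts specific to the full registry
  (353 / 245 / 241 indicators) are only meaningful when a user
  supplies that registry file.
* COMCAT categories are processed generically; their substantive
  interpretation is out of scope.
* CSMF uncertainty intervals, chance-corrected concordance and
  CSMF-accuracy metrics from the wider VA literature are not
  implemented.
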