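# Methods

## The disproportionality model

Spontaneous-report databases have no denominator population: every row is an
adverse-event report, so absolute risks are not estimable and analysis
proceeds by disproportionality. The unit of analysis throughout is the
**case** (one report), not the drug–event pair. For each drug the 2×2 table
against the rest of the analysis universe is

    a = cases suspected of the drug that report the target event
    b = cases suspected of the drug without the target event
    c = all other universe cases with the target event   (= N_event − a)
    d = the remaining universe cases                      (= N_total − (a+b) − c)

and the reporting odds ratio is ROR = ad/bc. Under this case-level counting
a drug's report total is a + b and the identity "no-event = total − event"
holds row by row, which is what makes published per-drug count tables
sufficient to rebuild every statistic at desk scale.

The comparator is the **filtered universe itself** (all cases passing the
role and route filters), not the raw database. Rebuilding the reference
screen from the packaged counts requires exactly this choice: the published
per-drug RORs are only recovered with N_total = 97,567 and N_event = 1,762,
the filtered totals.

## Inclusion rules

A drug mention enters the universe only with involvement role `suspected`
(causality strongly suspected by the reporter) and route `intravenous`;
concomitant/interaction mentions and oral formulations are dropped before
any counting. A case enters the universe if it retains at least one mention.
The event flag is case-level: true iff any reaction row carries one of the
target MedDRA Preferred Terms (defaults 10051792, infusion-related reaction;
10052015, cytokine release syndrome); a case reporting both PTs counts once.
Duplicate (case, drug) pairs are deduplicated. Drug names are normalized by
trimming, whitespace collapse and case-folding, with an optional
user-supplied synonym map; no other unification is attempted because
brand/generic mapping is database- and language-specific.

## Confidence interval, signal rule, exact test

* **CI**: Woolf log-normal, `exp(ln ROR ± z·SE)` with
  `SE = sqrt(1/a + 1/b + 1/c + 1/d)` and z = Φ⁻¹(0.975) = 1.959964. This
  interval reproduces the published reference CIs at 2 decimal places on
  all 25 antibodies, which is how it was selected among the common choices.
* **Signal rule**: CI lower bound > 1 (strict) and a ≥ 2. The two-case
  minimum guards against single-report artifacts; a lower bound exactly 1.0
  does not signal.
* **Zero cells**: the ROR and CI are reported as *undefined* rather than
  silently corrected; the Haldane–Anscombe +0.5 correction is available as
  an explicit opt-in (`continuity=True`). The packaged reference data never
  needs it (all a ≥ 1).
* **Fisher exact test (2×2)**: two-sided by the small-p-values rule — sum
  the hypergeometric probabilities of every table with the observed margins
  whose point probability is ≤ the observed one (relative tolerance 1e-7,
  the same convention as R's `fisher.test`). Computed entirely in log space
  via `hypergeom.logpmf` + logsumexp: at database scale p-values fall far
  below the smallest positive double (cetuximab-scale counts give
  log₁₀ p ≈ −325), and the log-space path keeps the magnitude exact even
  when `p` itself underflows to 0.0. A zero margin gives p = 1.
* **Freeman–Halton (2×K)**: complete enumeration of all 2×K tables with the
  observed margins, log-space point probabilities, same small-p-values rule;
  for K = 2 it agrees with the 2×2 test to 1e-12. Margin structures
  admitting more than a configurable number of candidate tables (default
  5·10⁶) raise an explicit "not computed" error — never a silent
  approximation. On the reference antibody-type detection table the
  enumeration gives p = 0.6674, matching R's `fisher.test`.
* **Multiplicity**: Benjamini–Hochberg step-up across the per-drug exact
  tests of one screen (delegated to statsmodels). Adjusted values are
  monotone in the raw p-values, order-preserving and capped at 1;
  thresholding them at α reproduces the BH procedure's rejection set.
  Note that the step-up map is *not* idempotent on non-constant vectors —
  re-adjusting already-adjusted values inflates them — so adjusted p-values
  are reported once and never re-entered into the adjustment. Underflowed
  p-values enter the BH family clipped to the smallest positive double.

## Pooled groups and detection tables

Group RORs pool member drugs **additively**: the group's a and a + b are the
sums of the members' per-drug counts, so a case suspected of two member
drugs contributes once per drug. This matches the additive construction of
published group tables (the ADCC-positive pool's 1,142 IR cases equal the
sum of the 14 member drugs' IR counts) and makes pooled tables independent
of case-overlap information that per-drug count tables do not carry.
Detection tables cross the per-drug signal flag with a curated attribute
(ADCC status, antibody type); their exact test is the 2×2/2×K machinery
above. The curated attributes are shipped as data, not computed: ADCC
activity is a literature/package-insert determination, not something a
report database can decide.

## Volcano output

x = ln ROR (natural log, the field convention for effect size),
y = −log₁₀ p from the unadjusted exact test (base 10 chosen as the volcano
convention; the y-value is computed from the log-space p directly). Points
with an undefined ROR, or with p below a display floor (default 1e-300,
i.e. below double-precision representability), are flagged `excluded` with
a reason instead of being plotted at infinity. Figure rendering is optional
and headless (`Agg`); coordinates are always emitted as CSV.

## The synthetic generator

`generate_database` emulates the structure the statistics depend on — a
case-keyed four-table database with per-drug report volumes, a background
event rate, and per-drug effects — with effects planted on the **odds
scale**: a case whose suspected drug has multiplier r is an event with
probability r·q/(1 − q + r·q), so the drug's population ROR against the
background pool is exactly r and the estimator's target is the planted
value. Each case gets one suspected drug (drawn from the configured shares,
remainder to a background pool), demographics and history noise fields, one
decoy reaction row, and a target-PT row if it is an event case.
Deliberately *not* modelled: realistic demographics, dosing, outcome
severity, reporting-over-time dynamics (Weber effect), correlated
multi-drug regimens (a flag adds random second mentions only). Passing
tests therefore demonstrate estimator correctness and calibration under the
stated sampling model — not robustness to the reporting biases of real
pharmacovigilance data, which have no denominator and no ground truth.

A single integer seed drives four deterministic child streams (cases,
demographics, reactions, history); identical configurations produce
byte-identical CSV output.

## Calibration checks and problem sizes

The suite verifies, beyond unit examples: exact-test agreement with
brute-force margin enumeration oracles (2×2 and 2×K, small margins,
tolerance 1e-12); ~95% CI coverage under a planted null (1,000 generator
replicates of 1,500 cases, background rate 0.05, drug share 0.3; coverage
required within ±3 points); planted-effect recovery (ROR 5 planted at
50,000 cases, share 0.05, background rate 0.02; the true value must fall
inside the estimate's 95% CI in ≥90 of 100 seeds); and a null screen of 25
drugs across 30 seeds whose empirical signal rate must stay at or below the
one-sided false-positive rate of the CI rule with no systematic direction
in ln ROR. These sizes keep the full suite under about a minute while
leaving the Monte-Carlo bands comfortably wider than their standard errors.

## Known limitations

* Disproportionality is hypothesis-generating: an ROR is a reporting
  association, not an incidence or a causal effect.
* The additive pooling convention double-counts cases suspected of two
  drugs in the same group; with per-drug count tables as input this is the
  only construction available, and it is the one the reference tables use.
* The Freeman–Halton enumeration is exponential in K and margin size; it is
  intended for the small detection tables of stratified screens.
* Attribute curation (ADCC status, antibody type) is input data; the
  package performs no literature inference.
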