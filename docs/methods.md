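# Methods

## The analysis model

Spontaneous reporting systems are numerator-only databases: they contain
reports, not an exposed population, so incidence cannot be estimated and
all inference is *disproportionality* — whether an event is reported more
often among reports mentioning the drug of interest than among the rest.
`pvsignal` operationalizes this for a stratified question: *which adverse
events of the Z-drug class are disproportionately reported specifically in
elderly patients, and do those events carry a worse prognosis there?*

### Counting

The counting unit is the case (one report contributes at most one to any
cell). Exposure = at least one drug row whose normalized name is in the
target set (default: zolpidem, zopiclone, eszopiclone, pooled as one
class) and whose involvement role passes the role filter (default:
"suspected" only — concomitant mentions are not exposure). Events are
aggregated from preferred terms (PT) to High Level Group Terms (HLGT)
through a user-supplied hierarchy table; several PTs of one case mapping
into the same HLGT count once. The event universe is every HLGT with at
least one report in either stratum. Cases with blank sex, unusable age, or
no primary-disease row are excluded beforehand, with reasons attributed by
a fixed priority order (sex → age → primary disease) so the exclusion log
is deterministic; ages arrive decade-binned, and the elderly stratum is
the 60s bin and above (the data's resolution makes a finer 60-vs-61 split
meaningless).

### Statistics

For each (stratum, HLGT) 2×2 table (cells a=n₁₁, b, c, d):

* PRR = [a/(a+b)] / [c/(c+d)];
* χ² = Pearson statistic on the table;
* signal value = ln(PRR) + ln(χ²);
* detection: n₁₁ ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4 (Evans' criterion; all three
  thresholds configurable).

When any cell is zero, PRR or χ² degenerate and the log is undefined, so
the table receives the Haldane–Anscombe ½ correction (+0.5 on all four
cells) and the statistics are computed on the corrected cells; tables with
all cells positive are used uncorrected. The reported n₁₁ is always the
uncorrected count.

**χ² variant.** A Yates continuity correction is available
(`yates=True`), but the default is the plain Pearson statistic. The
composite signal value needs χ² > 0, and Yates floors every deviation
|O−E| ≤ 0.5 to zero — exactly the regime of the weak-stratum tables the
half-value comparison must evaluate — which would make ln(χ²) undefined on
tables that are perfectly well-formed. Published stratified signal tables
of this design print χ² values as small as 0.0007, which only the
uncorrected statistic produces. Detection thresholds are unchanged either
way.

### Elderly-risk judgment

Among HLGTs detected in the elderly stratum, flag those with

    (elderly signal value)/2 − (non-elderly signal value) > 0

evaluated at full floating precision on pipeline output (the replay path
consumes printed 1-decimal values as given); an exact tie is not flagged (strict
inequality). The non-elderly signal value entering the rule is the
corrected-table value whenever that stratum's table had a zero cell.

### Prognosis

Outcome labels classify as good (recovery, light), poor (death,
with-sequelae, unrecovered) or excluded (anything else, e.g. unknown); a
configurable vocabulary maps other locales' labels onto these. Per HLGT,
exposed cases with the event (conditioning on exposure is the default and
is configurable) form the elderly/non-elderly × poor/good table; a case
with several reactions in the HLGT counts once, worst outcome dominating.
Unlike the signal arm, +0.5 is added to **all** cells **unconditionally**
— this arm routinely handles tiny tables, and the blanket correction keeps
every RR and CI defined and reproducible, at the cost of shrinking
estimates from sparse tables toward 1. On the corrected cells:

    RR = [e_poor/(e_poor+e_good)] / [n_poor/(n_poor+n_good)]
    95% CI = exp( ln RR ± 1.96 · √(1/e_poor − 1/(e_poor+e_good)
                                   + 1/n_poor − 1/(n_poor+n_good)) )

with the Pearson χ² (no Yates; the +0.5 already regularizes) on the same
cells. RR > 1 marks an event whose prognosis is worse among elderly
reporters ("noted"), regardless of CI coverage — the flag is a screening
aid, not a test. Degenerate all-zero tables return RR = 1 with a CI that
spans 1, never an NA.

## The synthetic generator

`pvsignal.synthetic` emulates the statistical structure the analysis
assumes, not any real database's content. Per case: an elderly indicator
(default fraction 0.625, matching the roughly 5:3 elderly-to-non-elderly
split typical of hypnotic-drug report sets), a decade bin drawn within the
stratum, sex, a suspected-exposure indicator (default prevalence 0.05),
concomitant drug rows (including occasional concomitant Z-drug rows, so
the role filter is exercised), per-HLGT event draws at
baseline_rate × multiplier(HLGT, stratum) for exposed cases (clipped to
[0, 1]; default baselines cycle through 0.005–0.03), outcome labels from a
per-stratum poor-probability model with a 10% "unknown" share, and a
primary-disease row. Missingness (blank sex 2%, blank age 1.5%,
subjective-token age 1%, missing primary disease 3% by default) is
injected after the ground truth is recorded, so exclusion logic can be
validated against exact injected counts. Generation is bit-reproducible
given the seed.

What it does **not** model — and what passing tests therefore do not show
about real data: reporting-time trends, duplicate/follow-up reports of one
patient, drug–drug interactions, dose, name-spelling noise, correlated
events within a case, or stratum-dependent reporting propensity unrelated
to the drug. The generator validates the machinery and the statistical
calibration of the rules, not the clinical conclusions drawn from any real
extract.

## Validation set-up and problem sizes

* Counting is verified cell-for-cell against a naive per-case double-loop
  oracle on 50 seeded datasets of ≤ 200 cases each.
* Parameter recovery: 20 replicates of a 20,000-case scenario with one
  HLGT spiked ×20 in the exposed elderly only; the spiked term must be
  detected and risk-flagged in ≥ 95% of replicates and null terms flagged
  in ≤ 5%.
* Null prognosis calibration: 15 replicates × 20 HLGTs at 6,000 cases with
  equal poor-outcome probabilities in both strata; the 95% CI may exclude
  1 in at most 7.5% of term-replicates.
* Algebraic invariants (χ² swap symmetry, PRR reciprocality under row
  swap, monotonicity of the signal value, +0.5 conservation, CI containing
  the point estimate) are checked on 1,000 random tables, plus
  hypothesis-driven property tests per statistic; our χ² is cross-checked
  against `scipy.stats.chi2_contingency` (with and without Yates), which
  serves only as an oracle.
* The statistics layer is replayed against a bundled published stratified
  Z-drug signal table (28 HLGTs, both strata): detection recovers all 28
  rows, the half-value rule re-flags exactly the published 12, and their
  SOC roll-up gives bucket sizes 4/3/2/2/1. Printed tables carry rounding:
  where a test recomputes ln(PRR)+ln(χ²) from 1-decimal inputs, its
  tolerance is the half-ulp of the printed output plus the exact log-scale
  propagation of each input's half-ulp — a bound fixed by the table's
  typography before any comparison is made. One published elderly row
  (PRR 13.4, χ² 52.2, printed signal value 6.5) recomputes to 6.5503,
  i.e. the printed inputs and output disagree in the last digit; the
  propagation-aware tolerance covers exactly this class of discrepancy.

## Numerical and design choices

* PRR uses the Evans form; on uncorrected tables PRR = 0 when a = 0 and
  +∞ (with a warning) when c = 0 — callers needing a signal value must
  correct first, and the pipeline does so automatically on any zero cell.
* The Haldane correction refuses double application.
* Replaying printed tables takes the published statistics as given
  (including corrected values where the source shows them) and applies
  only detection, judgment and roll-up — no attempt is made to
  reverse-engineer the underlying cells.
* SOC roll-ups sort by descending bucket size, ties broken alphabetically;
  HLGTs absent from the hierarchy land in an explicit "unmapped" bucket.
* Whether one case may contribute several PTs is left to the data; the
  counting layer deduplicates per (case, HLGT), which makes the choice
  harmless.
* Report-quarter filtering is available when a quarter column is present,
  but is data-vintage bookkeeping, not method.

## Known limitations

* The log-normal RR interval is a Wald approximation; with the +0.5
  correction it is conservative on sparse tables (the null-calibration
  test shows well under nominal 5% exclusion), but it is not an exact
  interval.
* Detection thresholds are screening heuristics; no multiplicity
  adjustment is applied across the HLGT universe, by design.
* The package deliberately does not implement Bayesian shrinkage signals
  (BCPNN/GPS) or per-PT analyses; the HLGT level is the unit of analysis
  throughout.
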