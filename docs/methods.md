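# Methods

## Problem and scope

`pvsignals` mines disproportionality signals from spontaneous adverse-event
report corpora shaped like the FDA Adverse Event Reporting System (FAERS):
quarterly `$`-delimited tables of report demographics (DEMO), drug records
with role codes (DRUG), reaction preferred terms (REAC) and outcome codes
(OUTC). The pipeline restricts to reports naming a drug of interest as the
primary suspect, deduplicates case versions, builds one 2×2 contingency
table per drug–event pair against the rest of the corpus, and scores each
pair with four disproportionality statistics plus their conventional signal
thresholds. A disproportionality signal means *disproportionate reporting*,
never proven causation; the statistics share a single four-grid

|                      | target event | other events |
|----------------------|--------------|--------------|
| target-drug reports  | a            | b            |
| background reports   | c            | d            |

with N = a+b+c+d.

## Statistics

- **ROR** = ad/bc, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` (Woolf).
- **PRR** = [a/(a+b)] / [c/(c+d)],
  `SE(ln PRR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d))`.
- **χ²**: Pearson chi-square of the 2×2 with the Yates continuity
  correction by default (`N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)]`); a flag
  disables it. Zero-margin tables report χ² = 0 with a warning.
- **IC / IC025** (BCPNN): the information component
  `log2 P(x,y)/(P(x)P(y))` under the Bate (1998) priors
  (α₁ = β₁ = γ₁₁ = 1, α = β = 2, with the joint prior scale
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) so that E(IC) = 0 under exact
  independence). IC025 is E(IC) − 2·√V(IC) with the Bate three-term
  variance; it is the conventional "IC−2SD" bound, not a posterior
  quantile. The priors make IC finite on any non-empty table, including
  all-zero margins.
- **EBGM / EBGM05**: the observed/expected relative reporting ratio
  `a·N/((a+b)(a+c))` — the quantity the empirical-Bayes geometric mean
  shrinks toward 1 — with a Woolf-type lower limit
  `exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d))`. The full gamma-Poisson mixture
  (MGPS) with fitted hyperparameters is deliberately **not** implemented:
  this package computes the unshrunk observed/expected form, and the run
  metadata records that choice so EBGM columns are not confused with MGPS
  output.

Thresholds (all four must fire for the intersection flag `pass_all`):
`a ≥ 3` and interval lower limit > 1 for ROR and PRR; IC025 > 0;
EBGM05 > 2. All comparisons are strict; the count gate `min_a` defaults to
3 and is configurable. No multiple-testing adjustment is applied — the
thresholds are the only filter, as is standard in this type of analysis.

### Numerical choices

- Zero cells: the Haldane–Anscombe correction (+0.5 to every cell) is
  applied only when some cell is zero and only for the statistic that needs
  it; raw cells are always reported alongside. With `correction="none"` a
  zero cell raises an error naming the cell. `a = 0` yields EBGM = 0.
- Scored output is ordered by EBGM descending with ties broken
  lexicographically by event id, making ranked reports deterministic.
- Deduplication keeps, per case id, the highest case version, ties broken
  by latest FDA receipt date, then largest primaryid — a fixed total order,
  so the pipeline is insensitive to input row order.

## Counting unit

The default counting unit is the (report, PT) *occurrence*: a report listing
three PTs contributes three units, and the margins a+b / c+d are total
occurrence counts, identical across all tables of a run. This is the
convention under which SOC-level counts exceed the number of reports (one
report fans out over several events) and SOC counts are exactly the sum of
their member-PT counts. Unique-report counting (`unit="report"`) is offered
as an option; the run metadata records which unit produced a given output.

## Screening

Pipeline order: receipt-date window filter → deduplication →
missing-information exclusion → target/background split. "Missing patient
information" is operationalised as *all four* of sex, age, country and
reporter missing; real corpora keep large "unknown" strata (e.g. ~71%
unknown age), so any single missing field cannot be exclusionary. The
minimum-count screen is the `a ≥ 3` gate on drug–event pairs applied at
decision time, not a per-case record-count filter. Drug matching is a
case-insensitive substring test on both the verbatim drug name and the
active-ingredient field, because free-text names carry dose and formulation
suffixes. The PT→SOC mapping is user-supplied (MedDRA is licensed and not
bundled); unmapped PTs stay in the PT-level analysis and are excluded, with
a count, from SOC aggregation.

## Synthetic corpus generator

The generator emulates the FAERS features the pipeline must survive:
multiple drug records per case with role codes, several PTs per report,
case versioning (a `duplicate_rate` fraction of cases is re-emitted as a
higher version a week later), per-field missingness, and demographic strata
whose default proportions mirror a real capmatinib corpus (49% female
reports, 54% consumer-reported, 63% US, 71% missing age, receipt dates over
2020Q2–2023Q4). Outcome codes are drawn per report as independent
Bernoulli events (death 0.26, hospitalisation 0.157, disability 0.018,
life-threatening 0.015, following the narrative's reading of the published
outcome counts where the table's labels conflict with its text).

Signals are planted multiplicatively: a target report draws catalog PT *j*
with probability `min(1, background_prob_j × RR_j)`, so the planted RR is
the estimand disproportionality statistics target. The default catalog is
100 PTs over 20 SOCs at background probability 0.02, giving a Poisson-like
PT count per report with mean ≈ 2; reports that draw no PT are redrawn
(min 1), which inflates marginal PT probabilities by < 2% — negligible for
ratio estimands since it applies to target and background alike.
Demographics are generated independently of PTs (no confounding). Default
corpus sizes are 2,000 target and 20,000 background reports, a desk-scale
setting in which the target drug is a small fraction of the corpus, as in
real spontaneous-report databases. All randomness flows from a single seed:
identical configurations produce byte-identical files.

The ground-truth object (exposure flags, per-pair occurrence counts,
duplicate lineage, missingness masks) supports an independent counting path
(`truth_tables`) used as the oracle against the pipeline's tables.

**What passing synthetic tests does not show:** the generator has no
drug–drug co-reporting structure, no demographic confounding, no temporal
reporting trends and no terminology noise (misspelled or non-preferred
terms), so recovery results speak to the correctness of the counting and
scoring machinery, not to robustness against those real-data features.

## Known limitation: EBGM saturation at high exposed fractions

The observed/expected EBGM equals RR/(f·RR + 1 − f) in expectation, where f
is the target drug's share of the corpus's event occurrences. It therefore
approximates the planted RR only when f is small (real databases: one drug
among thousands). In a synthetic corpus with target and background of equal
size (f ≈ 0.5), EBGM is bounded above by 1/f = 2 regardless of RR, and
EBGM05 > 2 can never fire — so the all-four intersection cannot flag any
pair in such a corpus, however strong the planted signal. The odds ratio
(ROR) is invariant to f and recovers the planted RR in that regime; the
test suite asserts exactly this behaviour. Analyses with a large exposed
fraction should rely on ROR/PRR/IC, not EBGM.

## Descriptive summaries and reports

Percentages are count/total rounded half-up to 2 decimals (the convention
of printed report tables; half-up is fixed for determinism at boundaries).
Age bands are <18, 18–45, 45–65, 65–75, ≥75 with missing ages in an
"Unknown" stratum; outcome codes are counted per report and may overlap, so
outcome strata need not sum to the total. Outcome codes are reported
verbatim (DE/LT/HO/DS/…) rather than adopting display labels, since
published label↔code pairings are not always internally consistent. The
ranked PT report filters to `pass_all` pairs, sorts by EBGM descending and
truncates to `top_n` (default 30); the SOC report lists every SOC with its
scores.

## Determinism and problem sizes

The pipeline writes no timestamps; outputs are pure functions of
configuration and seed, and end-to-end byte-identity under a repeated run
is asserted in the test suite. Validation suites use corpora of 4×10⁴
reports per replicate (100 replicates for recovery properties), sizes at
which binomial sampling error on planted-pair counts is ~2–5% and each
replicate runs in about two seconds.
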