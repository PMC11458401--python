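# pvsignals

Disproportionality signal mining for FAERS-style spontaneous adverse-event
report corpora.

Pharmacovigilance teams screen spontaneous-reporting databases such as the
FDA Adverse Event Reporting System (FAERS) for drug–event pairs that are
reported *disproportionately* often. `pvsignals` implements that analysis
as a reusable pipeline for a drug of interest (built and validated around a
capmatinib-style screen): it ingests quarterly `$`-delimited DEMO / DRUG /
REAC / OUTC tables, restricts to reports naming the drug as primary
suspect, deduplicates case versions, maps MedDRA preferred terms (PTs) to
system organ classes (SOCs) via a user-supplied mapping, builds one 2×2
table per drug–event pair against the rest of the corpus, and scores each
pair with four statistics and their conventional signal thresholds.

For the four-grid (a, b, c, d), N = a+b+c+d:

| method | statistic | signal threshold |
|---|---|---|
| ROR | ad/bc, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | a ≥ 3 and CI lower limit > 1 |
| PRR | [a/(a+b)]/[c/(c+d)], `SE(ln PRR) = √(1/a−1/(a+b)+1/c−1/(c+d))` | a ≥ 3 and CI lower limit > 1 |
| BCPNN | IC = log₂ P(x,y)/(P(x)P(y)) with Bate-1998 priors | IC025 = E(IC) − 2√V(IC) > 0 |
| EBGM | a·N/((a+b)(a+c)) (observed/expected) | EBGM05 > 2 |

plus the Yates-corrected Pearson χ² and the all-four intersection flag. A
synthetic-data module generates FAERS-shaped corpora with planted relative
risks, duplicate case versions, missing demographics and realistic strata,
so the whole pipeline is testable offline — no FAERS download and no
licensed MedDRA content required. See `docs/methods.md` for the model
details and known limitations (in particular when EBGM saturates).

## Worked example

Score a synthetic corpus of 2,000 target and 20,000 background reports with
two planted signals (relative risks 8 and 4):

```yaml
# example.yaml
output_dir: example_out
simulate:
  n_target_reports: 2000
  n_background_reports: 20000
  planted_signals: [[PT_007, 8.0], [PT_031, 4.0]]
  duplicate_rate: 0.1
  seed: 7
top_n: 10
```

```sh
pvsignals run --config example.yaml
head -3 example_out/top_signals_pt.csv
```

```
event_id,case_reports,ror_95ci,prr_95ci,chi2,ic_ic025,ebgm_ebgm05
PT_007,341,7.54 (6.53–8.70),7.08 (6.17–8.12),1034.96,2.15 (1.96),4.49 (3.89)
PT_031,206,4.02 (3.41–4.75),3.90 (3.32–4.57),317.16,1.60 (1.37),3.06 (2.59)
```

Exactly the two planted pairs are flagged by all four algorithms. The ROR
(7.54 and 4.02) tracks the planted relative risks; EBGM (4.49 and 3.06)
sits lower because the observed/expected ratio is damped when the target
drug contributes a non-negligible share (~9% here) of the corpus — the
saturation effect described in `docs/methods.md`. `screening_log.csv`
accounts for every input report (24,178 in, 2,165 duplicate versions and 13
out-of-window reports removed), and `descriptive.csv` tabulates the target
reports by sex, age band, reporter, country, year and outcome, e.g. 996
female reports = 49.80% of the 2,000 target reports.

The same pipeline runs on real quarterly files by replacing `simulate:`
with an `input:` section naming the four table files and a `meddra_map:`
CSV (`pt, soc_name, soc_code`).

## Library surface

```python
import pvsignals as pv

raw, truth = pv.generate(pv.SimConfig(planted_signals=[("PT_001", 5.0)], seed=1))
cases, _ = pv.assemble_cases(raw)
screened = pv.screen(cases, pv.ScreeningConfig())
rows = pv.score_all(pv.build_pt_tables(screened))
print(pv.scores_frame(rows).head())
```

`truth_tables(truth)` computes the same contingency tables directly from
the generator's ground truth, an independent counting path used by the test
suite as an oracle.

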