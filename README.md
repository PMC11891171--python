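# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports.

Post-marketing drug-safety surveillance screens the FDA Adverse Event
Reporting System (FAERS) for drug–event pairs that are reported more often
than the background would predict.  `faersig` implements that workflow as a
tested, reusable pipeline for pharmacoepidemiologists and biostatisticians:

1. **Ingest** FAERS quarterly ASCII tables (dollar-delimited DEMO, DRUG,
   REAC, OUTC, THER, INDI) with strict field-count validation and a rejects
   log;
2. **Deduplicate** case versions by the FDA rule — per CASEID keep the most
   recent FDA_DT, ties broken by the highest PRIMARYID;
3. **Assemble the cohort** of reports naming the target drug (normalized
   substring match on drug name / active ingredient) as primary suspect,
   with configurable indication-PT exclusion;
4. **Screen** every event at MedDRA PT and SOC level with four estimators
   on the 2×2 table (a, b, c, d; N = a+b+c+d):

   | algorithm | statistic | signal criterion |
   |---|---|---|
   | ROR   | ad/(bc), CI = e^(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | N ≥ 3 and CI low > 1 |
   | PRR   | a(c+d)/(c(a+b)), Pearson χ² | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
   | BCPNN | IC = log₂(aN/((a+c)(a+b))) | IC025 > 0 |
   | MGPS  | EBGM = aN/((a+c)(a+b)) | EBGM05 > 2 |

   plus the four-way **consensus** flag (all criteria at once);
5. **Summarize** demographics, annual report counts and time to onset.

A synthetic FAERS generator with known ground truth (true reporting-rate
ratios, duplicate lineage, designated dedup survivors) makes the whole
pipeline testable without downloading FAERS.  Real MedDRA cannot be
redistributed, so PT→SOC mappings are user-supplied (or synthetic).

## Worked example

Simulate 20,000 reports with one true association seeded (nausea reported
8× more often under the target drug), then analyze:

```sh
faersig simulate --n-reports 20000 --seed 1 --signal "nausea=8" --out demo/data
faersig analyze --input-dir demo/data --dict demo/data/meddra_like.txt \
    --drug-name trintellix --drug-name vortioxetine --min-cases 20 --out demo/out
```

The analysis logs its stage counts:

```
stage counts: {'demo_rows_in': 20996, 'rejected_rows': 0,
 'deduplicated_reports': 20000, 'cohort_reports': 986,
 'cohort_event_pairs': 2113, 'indication_pairs_removed': 53,
 'pt_events': 52, 'soc_events': 13, 'pt_consensus_signals': 1,
 'tto_evaluable': 570}
```

20,996 demographic rows collapse to 20,000 cases after deduplication; 986
reports name the target drug as primary suspect.  `demo/out/report_pt.tsv`
then shows exactly one consensus signal — the seeded one:

```
 event   n        ROR (95% CI)    PRR (chi2) EBGM (EBGM05)  IC (IC025)  consensus
nausea 149 8.37 (6.88 - 10.18) 7.85 (639.35)   5.86 (4.82) 2.55 (2.26)       True
```

149 cohort reports mention nausea; every null PT (e.g. seizure,
ROR 1.03 [0.87–1.22]) stays unflagged.  `tto_summary.csv` recovers the
generator's onset distribution:

```
n_evaluable  n_excluded  median_days  q1  q3  frac_within_30d
        570         416            7   3  21         0.840351
```

The same run also writes contingency-table audits, full-precision signal
tables, a forest-plot-ready file, demographic blocks, annual counts, a
rejects log and a JSON manifest (input checksums, config echo, stage
counts) for reproducibility.

For real data, point `--input-dir` at a directory of FAERS quarterly files
(`DEMO23Q1.txt`, …) and `--dict` at a two-level PT→SOC mapping file.

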