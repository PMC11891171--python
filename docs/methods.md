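# Methods

## Problem setting

Spontaneous adverse-event databases such as the FDA Adverse Event Reporting
System (FAERS) collect unsolicited safety reports for marketed drugs.
Because there is no denominator of exposed patients, drug–event associations
are screened by *disproportionality*: for each event, the 2×2 table

|            | target event | other events |
|------------|--------------|--------------|
| target drug (cohort) | a | b |
| all other drugs      | c | d |

is compared against independence.  `faersig` implements the full screening
workflow — quarterly-file ingestion, case deduplication, suspect-drug cohort
assembly, four disproportionality estimators at MedDRA PT (preferred term)
and SOC (system organ class) level, and the descriptive summaries that
conventionally accompany such analyses — together with a synthetic FAERS
generator used to validate every stage against known ground truth.

## Deduplication

FAERS carries multiple versions of a case (same CASEID, different
PRIMARYID).  Following the FDA-recommended procedure, the pipeline retains,
per CASEID, the version with the most recent FDA_DT, breaking exact date
ties by the highest PRIMARYID.  PRIMARYIDs are compared numerically when
both parse as integers, lexicographically otherwise.  Rows whose FDA_DT is
unparseable are excluded from deduplication and logged.  Rows with a
*partial* FDA_DT (`YYYY` or `YYYYMM`) participate only when the case has no
fully-dated version; for ordering they are imputed to the end of their
stated period (Dec 31 / month end).  The operation is deterministic and
idempotent.

## Cohort definition

Target-drug matching is normalized substring containment: a drug row
matches when any target name (trimmed, case-folded, internal whitespace
collapsed) is contained in the row's `drugname` or `prod_ai`.  Containment
rather than equality is used because verbatim FAERS drug names carry salts
and strengths ("VORTIOXETINE HYDROBROMIDE 10MG").  Only rows with the
required role code (primary suspect, `PS`, by default) qualify, so reports
that mention the target drug as concomitant or secondary suspect fall into
the comparator universe.  The comparator is all deduplicated reports in the
ingested window that are not in the cohort.

Reaction PTs on the indication-exclusion list (default: *major depressive
disorder*, *depression*, *depressive symptom*; overridable) are removed from
the event-level analysis.  A report whose every PT is excluded disappears
from the signal tables but remains in the report-level demographics; all
removals are counted.

## Counting unit

Contingency tables count distinct report–event pairs: a report contributes
once per distinct PT and, at SOC level, once per SOC regardless of how many
of its PTs map there.  `a+b` is therefore the cohort's total pair count,
not its report count.  This is standard FAERS practice; with multi-event
reports it makes the proportional reporting ratio of a strongly seeded
signal slightly conservative (the signal inflates the exposed pair total),
an effect visible in the synthetic calibration below.

## Estimators

All four statistics are the closed, non-shrunk forms with N = a+b+c+d:

- **ROR** = ad/(bc); 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  Signal: a ≥ 3 and CI lower bound > 1.
- **PRR** = a(c+d)/(c(a+b)) with Pearson's χ² (no continuity correction).
  Signal: PRR ≥ 2, χ² ≥ 4, a ≥ 3.
- **IC** = log₂(aN/((a+c)(a+b))); IC025 = IC − 2√V(IC).  Signal: IC025 > 0.
- **EBGM** = aN/((a+c)(a+b)); EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)).
  Signal: EBGM05 > 2.

In these closed forms IC ≡ log₂(EBGM), which the tests assert exactly.  A
*consensus* signal satisfies all four criteria simultaneously; combining
algorithms damps the idiosyncrasies of any single rule.  No multiplicity
adjustment is applied — conventional in this screening setting, and a
documented limitation rather than a hidden choice.

Numerical conventions:

- **Zero cells.**  Any statistic whose formula touches a zero cell is
  undefined (NaN) and fails its signal flag.  An optional Haldane +0.5
  correction (applied to all four cells of affected tables) can be enabled;
  it is off by default.
- **V(IC).**  The delta-method variance V(IC) = (1/a+1/b+1/c+1/d)/ln(2)² is
  the default.  Some published tables show an IC−IC025 gap that is constant
  across rows (≈1.66), which no delta-method variance reproduces; a
  fixed-offset mode (IC025 = IC − κ, κ configurable, default 1.66) is
  provided for comparability with such tables.  Neither mode is claimed to
  be what any particular publication used.
- **Rounding.**  Presentation tables round half-up to 2 decimals;
  percentages to 1 decimal.  Full-precision values are always emitted in
  the machine-readable signal tables.

The full Bayesian BCPNN (Dirichlet priors, posterior IC) and the true
gamma-Poisson shrinkage behind MGPS EB05 are deliberately not implemented;
the closed forms above are what this package computes.

## Descriptives

Percentages use the full cohort (missing included) as denominator.  Age
bins implement <18, [18, 65), [65, 85), ≥85 years plus missing; ages are
normalized from FAERS unit codes (DEC, YR, MON, WK, DY, HR — unknown codes
become missing).  Weight bins are <50, [50, 100], >100 kg plus missing.
Each report receives one outcome, the most severe of its outcome rows
(priority DE > LT > DS > HO > CA > RI > OT); reports with no outcome row
are "missing", so the block sums to the cohort size.

Time to onset (TTO) is EVENT_DT minus the earliest START_DT among the
report's target-drug therapy rows, in days.  Only fully-dated, non-negative
differences are evaluable; partial dates, missing dates and negative
differences are excluded and counted, and evaluable + excluded always
equals the cohort size.  Quantiles use linear interpolation (type 7); the
"within the first month" share uses TTO ≤ 30 days.

## Synthetic generator

The generator emulates the structure the pipeline touches, with every
recovered quantity controlled:

- **Event process.**  Baseline per-PT probabilities follow a log-uniform
  shape over [10⁻⁴, 10⁻²] (events are rare, as in spontaneous reporting),
  rescaled by a common factor so the expected number of Bernoulli events
  per report equals `mean_pts_per_report` (default 2.0, typical of FAERS
  multi-event reports); each probability is capped at 0.5.  Exposed reports
  (target drug as primary suspect; 5% of reports by default) multiply
  seeded PTs by the configured reporting-rate ratio ρ before the cap.  A
  report drawing no event receives one PT from the normalized weight
  vector, since real reports always carry a reaction; this fallback and the
  pair-count denominator attenuate recovered ratios by a few percent at the
  defaults.
- **Duplicates.**  A configurable fraction of cases (default 5%) is
  re-submitted under a fresh PRIMARYID with FDA_DT shifted 1–89 days later;
  a configurable share of those (default 20%) keeps the identical FDA_DT to
  exercise the PRIMARYID tie-break.  PRIMARYIDs are a random permutation,
  so the later version is not systematically the larger number.  The
  ground-truth sidecar designates each case's survivor under the FDA rule.
- **Demographics and dates.**  Sex/age/weight missingness defaults (13%,
  56%, 79%) mirror the heavy missingness of real FAERS demographic fields;
  a third of missing sexes are coded "U" rather than blank.  TTO is
  log-normal with median 7 days and σ = 0.5·ln(41/4) ≈ 1.5 on the log
  scale; 25% of event/start dates are degraded to partial (`YYYYMM`,
  `YYYY`) or missing to exercise date validation.
- **Not emulated.**  Reporting heterogeneity across drugs, secular trends,
  masking/competition bias, real MedDRA granularity (the bundled
  vocabulary has 53 PTs in 13 SOCs), duplicate cases that mutate content
  between versions, and the very heavy TTO tail seen in real data (a
  single log-normal cannot have median 7 d and only 60% of mass below
  30 d).  Passing tests therefore demonstrate correctness of the pipeline's
  logic and calibration under a faithful null, not robustness to every
  real-world reporting artifact.

## Validation scale

The test suite validates signal recovery at 50,000 synthetic reports: under
an all-null configuration (every ρ = 1) each algorithm flags fewer than 5%
of PTs and the four-way consensus fewer than 1%; with ρ = 6 seeded on three
PTs whose expected case count is at least 20, the consensus flag fires for
more than 90% of seeded PTs across 20 seeds.  Deduplication is checked
against ground truth across 20 further seeds including deliberate date
ties.  `scripts/acceptance.py` re-runs the same experiments from scratch at
the same sizes.

## Known limitations

- Disproportionality quantifies reporting association, not causation or
  incidence; all the usual spontaneous-reporting caveats apply.
- The comparator universe is "all other deduplicated reports", so signals
  are relative to the background mix of drugs in the ingested window.
- CASEID identity is the only linkage; probabilistic record linkage across
  manufacturers' case versions is out of scope.
- E2B XML ingestion and legacy LAERS layouts are not supported.
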