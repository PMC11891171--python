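"""Report-level descriptive summaries of a deduplicated cohort.

Covers the standard pharmacovigilance summary blocks: sex, age bins
(<18, 18–64.9, 65–85, >85), weight bins (<50, 50–100, >100 kg), reporter
occupation, top reporter countries, outcome codes, the annual report
distribution by receipt year, and the time-to-onset (TTO) analysis.

Percentages are taken against the full cohort size (missing included in the
denominator) and rounded half-up to one decimal, the convention used in
published FAERS summary tables.  TTO is the difference in days between the
adverse-event onset date (EVENT_DT) and the earliest therapy start date
(START_DT) of the report's target-drug rows; records with partial, missing
or negative differences are excluded and counted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, match_target
from .io import parse_date

AGE_BIN_LABELS = ["<18", "18-64.9", "65-85", ">85", "missing"]
WEIGHT_BIN_LABELS = ["<50 kg", "50-100 kg", ">100 kg", "missing"]
OCCP_LABELS = {
    "MD": "Physician", "PH": "Pharmacist", "CN": "Consumer",
    "HP": "Health Professional", "OT": "Other health-professional",
}
OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life-Threatening", "HO": "Hospitalization",
    "DS": "Disability", "CA": "Congenital Anomaly",
    "RI": "Required Intervention", "OT": "Other Serious",
}
#: severity order used to assign a single outcome per report
OUTCOME_PRIORITY = ["DE", "LT", "DS", "HO", "CA", "RI", "OT"]

TTO_HIST_BINS = [0, 7, 14, 30, 60, 90, 180, 360, np.inf]
TTO_HIST_LABELS = ["0-7", "8-14", "15-30", "31-60", "61-90", "91-180",
                   "181-360", ">360"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 dp rounds to 0.1, never 0.0)."""
    if isinstance(x, float) and np.isnan(x):
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """100·count/total, half-up at *ndigits*; defined as 0 for an empty total."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


@dataclass
class DemographicsSummary:
    """Counts and percentages by block; each block sums to the cohort size."""

    total: int
    sex: pd.DataFrame
    age: pd.DataFrame
    weight: pd.DataFrame
    reporter: pd.DataFrame
    country: pd.DataFrame
    outcome: pd.DataFrame

    def blocks(self) -> dict[str, pd.DataFrame]:
        return {"sex": self.sex, "age": self.age, "weight": self.weight,
                "reporter": self.reporter, "country": self.country,
                "outcome": self.outcome}

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, df in self.blocks().items():
            part = df.copy()
            part.insert(0, "block", name)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def _block(counts: pd.Series, total: int) -> pd.DataFrame:
    return pd.DataFrame({
        "category": counts.index.astype(str),
        "count": counts.to_numpy(dtype=int),
        "pct": [percentage(int(v), total) for v in counts.to_numpy()],
    })


def summarize_demographics(cohort: Cohort, top_countries: int = 5
                           ) -> DemographicsSummary:
    """Table of counts/percentages for sex, age, weight, reporter, country, outcome.

    Every record lands in exactly one bin per block, with an explicit
    ``missing`` bin, so each block's counts sum to the cohort size.
    """
    demo = cohort.demo
    total = len(demo)

    if total == 0:
        empty = pd.DataFrame(columns=["category", "count", "pct"])
        return DemographicsSummary(0, empty, empty, empty, empty, empty, empty)

    sex = demo["sex"].where(demo["sex"].isin(["F", "M"]), "missing")
    sex_counts = sex.value_counts().reindex(["F", "M", "missing"], fill_value=0)

    age_bin = pd.cut(demo["age_yr"], bins=[-np.inf, 18, 65, 85, np.inf],
                     right=False, labels=AGE_BIN_LABELS[:4]).astype(object)
    age_counts = pd.Series(np.where(demo["age_yr"].isna(), "missing", age_bin)) \
        .value_counts().reindex(AGE_BIN_LABELS, fill_value=0)

    w = demo["wt_kg"]
    wt_bin = np.select(
        [w < 50, (w >= 50) & (w <= 100), w > 100],
        WEIGHT_BIN_LABELS[:3], default="missing")
    wt_counts = pd.Series(wt_bin).value_counts() \
        .reindex(WEIGHT_BIN_LABELS, fill_value=0)

    occ = demo["occp_cod"].map(OCCP_LABELS).fillna("missing")
    occ_counts = occ.value_counts()
    occ_counts = occ_counts.reindex(
        [v for v in list(OCCP_LABELS.values()) + ["missing"]
         if v in occ_counts.index], fill_value=0)

    country = demo["reporter_country"].replace("", pd.NA).fillna("missing")
    top = country.value_counts().head(top_countries)
    other = total - int(top.sum())
    country_counts = pd.concat([top, pd.Series({"other/missing": other})])

    # one outcome per report, most severe first; reports without any outcome
    # row are "missing" — so the block sums to the cohort size
    sev = {c: i for i, c in enumerate(OUTCOME_PRIORITY)}
    outc = cohort.outcomes
    if len(outc):
        best = (outc.assign(_sev=outc["outc_cod"].map(sev))
                .sort_values("_sev", kind="stable")
                .groupby("primaryid").head(1))
        per_report = best.set_index("primaryid")["outc_cod"]
    else:
        per_report = pd.Series(dtype=object)
    outcome = demo["primaryid"].map(per_report).map(OUTCOME_LABELS).fillna("missing")
    order = [OUTCOME_LABELS[c] for c in OUTCOME_PRIORITY] + ["missing"]
    outcome_counts = outcome.value_counts().reindex(order, fill_value=0)

    return DemographicsSummary(
        total=total,
        sex=_block(sex_counts, total),
        age=_block(age_counts, total),
        weight=_block(wt_counts, total),
        reporter=_block(occ_counts, total),
        country=_block(country_counts, total),
        outcome=_block(outcome_counts, total),
    )


def annual_distribution(cohort: Cohort) -> pd.Series:
    """Report counts by receipt year (FDA_DT), ascending; unparseable dropped."""
    years = cohort.demo["fda_dt"].astype(str).str[:4]
    ok = years.str.fullmatch(r"\d{4}")
    counts = years[ok].astype(int).value_counts().sort_index()
    counts.name = "reports"
    counts.index.name = "year"
    return counts


@dataclass
class TTOSummary:
    """Time-to-onset distribution among evaluable reports."""

    n_evaluable: int
    n_excluded: int
    median_days: float
    q1: float
    q3: float
    frac_within_30d: float
    histogram: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def is_empty(self) -> bool:
        return self.n_evaluable == 0


def time_to_onset(cohort: Cohort, config: CohortConfig) -> TTOSummary:
    """TTO = EVENT_DT − earliest target-drug START_DT, in days.

    Only fully-dated, non-negative differences are evaluable; everything
    else (partial or missing dates, event before start) is excluded and
    counted.  Quantiles use linear interpolation; ``frac_within_30d`` is the
    share of evaluable onsets at ≤30 days.
    """
    demo = cohort.demo
    n_cohort = len(demo)
    if n_cohort == 0:
        return TTOSummary(0, 0, np.nan, np.nan, np.nan, np.nan)

    target_rows = cohort.drugs[match_target(cohort.drugs, config)]
    ther = cohort.therapy.merge(
        target_rows[["primaryid", "drug_seq"]].drop_duplicates(),
        on=["primaryid", "drug_seq"], how="inner")
    starts = ther.assign(_start=pd.to_datetime(ther["start_dt"].map(parse_date))) \
        .dropna(subset=["_start"]).groupby("primaryid")["_start"].min()

    events = pd.to_datetime(demo.set_index("primaryid")["event_dt"].map(parse_date))
    joined = pd.DataFrame({"event": events}).join(starts.rename("start"), how="left")
    tto = (joined["event"] - joined["start"]).dt.days
    evaluable = tto.dropna()
    evaluable = evaluable[evaluable >= 0]
    n_eval = len(evaluable)
    if n_eval == 0:
        return TTOSummary(0, n_cohort, np.nan, np.nan, np.nan, np.nan)

    q1, med, q3 = np.quantile(evaluable.to_numpy(), [0.25, 0.5, 0.75])
    hist = pd.cut(evaluable, bins=TTO_HIST_BINS, labels=TTO_HIST_LABELS,
                  include_lowest=True).value_counts().reindex(TTO_HIST_LABELS)
    histogram = pd.DataFrame({"interval": TTO_HIST_LABELS,
                              "count": hist.to_numpy(dtype=int)})
    return TTOSummary(
        n_evaluable=n_eval,
        n_excluded=n_cohort - n_eval,
        median_days=float(med),
        q1=float(q1),
        q3=float(q3),
        frac_within_30d=float((evaluable <= 30).mean()),
        histogram=histogram,
    )
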