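"""Case deduplication and suspect-drug cohort assembly.

FAERS carries multiple versions of the same safety report: manufacturers
re-submit cases, so one CASEID can map to several PRIMARYIDs across
quarters.  Following the FDA-recommended rule, :func:`deduplicate` keeps,
per CASEID, the record with the most recent FDA_DT, breaking ties by the
highest PRIMARYID.

The cohort is then the set of deduplicated reports in which the target drug
(matched case-insensitively by normalized substring containment against
``drugname`` and ``prod_ai`` — verbatim FAERS names carry salts and
strengths) appears with the required role code (primary suspect by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FaersTables, date_precision

logger = logging.getLogger(__name__)

#: PTs removed from the event-level analysis because they plausibly describe
#: the indication rather than an adverse event.  Config-overridable.
DEFAULT_INDICATION_EXCLUSIONS = (
    "major depressive disorder", "depression", "depressive symptom",
)


def normalize_name(name: str) -> str:
    """Trim, case-fold and collapse internal whitespace."""
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


@dataclass
class CohortConfig:
    """How the analysis cohort is selected from the deduplicated reports."""

    target_names: tuple[str, ...]
    required_role: str = "PS"
    indication_exclusion_pts: tuple[str, ...] = DEFAULT_INDICATION_EXCLUSIONS
    date_window: tuple[str, str] | None = None  # (first, last) quarter labels

    def __post_init__(self) -> None:
        if not self.target_names:
            raise ValueError("target_names must not be empty")
        if self.required_role not in {"PS", "SS", "C", "I"}:
            raise ValueError(f"invalid role code: {self.required_role!r}")


@dataclass
class DedupResult:
    """Survivors of the FDA deduplication rule plus bookkeeping counts."""

    survivors: pd.DataFrame          # one DEMO row per caseid
    n_rows_in: int
    n_cases: int
    n_dropped_versions: int
    n_excluded_unparseable: int
    n_partial_date_rows: int

    @property
    def surviving_primaryids(self) -> set[str]:
        return set(self.survivors["primaryid"])


def _primaryid_sort_key(pid: pd.Series) -> pd.Series:
    """Sortable key: numeric PRIMARYIDs compare numerically, others lexically."""
    num = pd.to_numeric(pid, errors="coerce")
    key = pid.astype(str).copy()
    ok = num.notna()
    key[ok] = num[ok].astype("int64").astype(str).str.zfill(20)
    return key


def _effective_date(fda_dt: pd.Series) -> tuple[pd.Series, pd.Series]:
    """(sortable date, precision) with partial dates imputed to period end.

    ``YYYY`` → Dec 31, ``YYYYMM`` → month end; unparseable → NaT.
    """
    s = fda_dt.astype(str)
    prec = s.map(date_precision)
    full = pd.to_datetime(s.where(prec == "full"), format="%Y%m%d",
                          errors="coerce")
    month = pd.to_datetime(s.where(prec == "month"), format="%Y%m",
                           errors="coerce") + pd.offsets.MonthEnd(0)
    year = pd.to_datetime(s.where(prec == "year"), format="%Y",
                          errors="coerce") + pd.offsets.YearEnd(0)
    eff = full.fillna(month).fillna(year)
    return eff, prec


def deduplicate(demo: pd.DataFrame) -> DedupResult:
    """Keep one report version per CASEID: latest FDA_DT, then highest PRIMARYID.

    Rows whose FDA_DT does not parse at all are excluded from deduplication
    and logged.  Rows with a partial FDA_DT take part only when their case
    has no fully-dated sibling; for ordering they are imputed to the end of
    their stated period.  Deterministic and idempotent.
    """
    eff, prec = _effective_date(demo["fda_dt"])
    unparseable = eff.isna()
    n_unparseable = int(unparseable.sum())
    if n_unparseable:
        logger.warning("deduplicate: excluded %d rows with unparseable fda_dt",
                       n_unparseable)
    work = demo.loc[~unparseable].copy()
    work["_eff"] = eff[~unparseable]
    work["_full"] = (prec[~unparseable] == "full")
    n_partial = int((~work["_full"]).sum())
    if n_partial:
        logger.info("deduplicate: %d rows carry partial fda_dt "
                    "(imputed to period end for ordering)", n_partial)

    # partial-dated versions are out-ranked whenever a full-dated sibling exists
    has_full = work.groupby("caseid")["_full"].transform("any")
    work = work[work["_full"] | ~has_full]

    work["_pidkey"] = _primaryid_sort_key(work["primaryid"])
    work = work.sort_values(["caseid", "_eff", "_pidkey"], kind="stable")
    surv = work.groupby("caseid", sort=True).tail(1)
    surv = surv.drop(columns=["_eff", "_full", "_pidkey"]).reset_index(drop=True)
    return DedupResult(
        survivors=surv,
        n_rows_in=len(demo),
        n_cases=len(surv),
        n_dropped_versions=len(demo) - n_unparseable - len(surv),
        n_excluded_unparseable=n_unparseable,
        n_partial_date_rows=n_partial,
    )


def match_target(drug: pd.DataFrame, config: CohortConfig) -> pd.Series:
    """Boolean mask over drug rows: target name present with the required role.

    A row matches when any normalized target name is contained in the
    normalized ``drugname`` or ``prod_ai`` AND ``role_cod`` equals
    ``config.required_role``.
    """
    targets = [normalize_name(t) for t in config.target_names]
    dn = drug["drugname"].fillna("").map(normalize_name)
    ai = drug["prod_ai"].fillna("").map(normalize_name)
    name_hit = pd.Series(False, index=drug.index)
    for t in targets:
        name_hit |= dn.str.contains(t, regex=False) | ai.str.contains(t, regex=False)
    return name_hit & (drug["role_cod"] == config.required_role)


def target_primaryids(drug: pd.DataFrame, config: CohortConfig) -> set[str]:
    """PRIMARYIDs of reports containing a matching target-drug row."""
    return set(drug.loc[match_target(drug, config), "primaryid"])


@dataclass
class IndicationExclusionResult:
    reactions: pd.DataFrame
    n_pairs_removed: int
    n_reports_emptied: int
    removed_per_pt: dict[str, int] = field(default_factory=dict)


def exclude_indications(reac: pd.DataFrame, config: CohortConfig
                        ) -> IndicationExclusionResult:
    """Drop reaction PTs that appear on the indication exclusion list.

    A report keeps its remaining PTs; a report whose every PT is excluded
    disappears from the event-level analysis (it stays in the report-level
    demographics, which are computed from DEMO).  Removal counts are logged.
    """
    excl = {normalize_name(p) for p in config.indication_exclusion_pts}
    if not excl or not len(reac):
        return IndicationExclusionResult(reac.copy(), 0, 0, {})
    norm = reac["pt"].map(normalize_name)
    hit = norm.isin(excl)
    removed = reac[hit]
    kept = reac[~hit].copy()
    emptied = set(reac["primaryid"]) - set(kept["primaryid"])
    counts = removed.groupby(norm[hit]).size().to_dict()
    if len(removed):
        logger.info("exclude_indications: removed %d report-PT pairs (%s); "
                    "%d reports left without events",
                    len(removed), counts, len(emptied))
    return IndicationExclusionResult(
        reactions=kept.reset_index(drop=True),
        n_pairs_removed=int(hit.sum()),
        n_reports_emptied=len(emptied),
        removed_per_pt={str(k): int(v) for k, v in counts.items()},
    )


@dataclass
class Cohort:
    """Deduplicated target-drug reports plus the comparator universe."""

    demo: pd.DataFrame            # surviving cohort DEMO rows
    reactions: pd.DataFrame       # cohort (primaryid, pt) after indication excl.
    drugs: pd.DataFrame
    outcomes: pd.DataFrame
    therapy: pd.DataFrame
    comparator_reactions: pd.DataFrame  # (primaryid, pt) of non-cohort survivors
    n_universe: int               # all deduplicated reports in the window
    dedup: DedupResult = None
    indication_exclusion: IndicationExclusionResult = None

    @property
    def size(self) -> int:
        return len(self.demo)


def build_cohort(tables: FaersTables, config: CohortConfig) -> Cohort:
    """Dedup → target match → indication exclusion, returning the cohort.

    Successive filters are monotone non-increasing in report count; every
    exclusion is counted on the returned object.
    """
    dedup = deduplicate(tables.demo)
    surv_ids = dedup.surviving_primaryids

    if config.date_window is not None and "quarter" in dedup.survivors.columns:
        lo, hi = config.date_window
        keep = dedup.survivors["quarter"].between(lo, hi)
        surv_demo = dedup.survivors[keep]
        surv_ids = set(surv_demo["primaryid"])
    else:
        surv_demo = dedup.survivors

    drug = tables.drug[tables.drug["primaryid"].isin(surv_ids)]
    cohort_ids = target_primaryids(drug, config)

    demo = surv_demo[surv_demo["primaryid"].isin(cohort_ids)].reset_index(drop=True)
    reac_all = tables.reac[tables.reac["primaryid"].isin(surv_ids)]
    reac_cohort = reac_all[reac_all["primaryid"].isin(cohort_ids)]
    excl = exclude_indications(reac_cohort, config)

    comparator = reac_all[~reac_all["primaryid"].isin(cohort_ids)]
    return Cohort(
        demo=demo,
        reactions=excl.reactions,
        drugs=tables.drug[tables.drug["primaryid"].isin(cohort_ids)].reset_index(drop=True),
        outcomes=tables.outc[tables.outc["primaryid"].isin(cohort_ids)].reset_index(drop=True),
        therapy=tables.ther[tables.ther["primaryid"].isin(cohort_ids)].reset_index(drop=True),
        comparator_reactions=comparator.reset_index(drop=True),
        n_universe=len(surv_demo),
        dedup=dedup,
        indication_exclusion=excl,
    )
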