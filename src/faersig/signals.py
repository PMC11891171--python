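"""Disproportionality statistics for drug–event 2×2 contingency tables.

For one drug–event pair the spontaneous-report universe collapses to

====  =============================  ==========================
       target event                   other events
====  =============================  ==========================
drug   a                              b
other  c                              d
====  =============================  ==========================

and four frequentist/empirical-Bayes style estimators are computed in their
closed (non-shrunk) forms, each with its conventional signal criterion:

* ROR  = ad/(bc),  95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  signal when N=a ≥ 3 and the CI lower bound > 1.
* PRR  = a(c+d)/(c(a+b)) with Pearson χ² (no continuity correction);
  signal when PRR ≥ 2, χ² ≥ 4 and N ≥ 3.
* IC   = log₂(a·N/((a+c)(a+b))), IC025 = IC − 2·√V(IC);
  signal when IC025 > 0.  The identity IC = log₂(EBGM) holds exactly.
* EBGM = a·N/((a+c)(a+b)), EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d));
  signal when EBGM05 > 2.

Two IC variance conventions are provided: the delta-method
``V(IC) = (1/a+1/b+1/c+1/d)/ln(2)²`` (default) and a fixed-offset mode
``IC025 = IC − κ`` seen in some published signal tables.  Statistics whose
formula touches a zero cell are undefined (NaN) by default; an optional
Haldane +0.5 continuity correction can be enabled.  The full Bayesian BCPNN
posterior and the gamma-Poisson shrinkage behind true EBGM are intentionally
not implemented: these are the closed-form variants only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DictionaryMap

logger = logging.getLogger(__name__)

_LN2_SQ = np.log(2.0) ** 2


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 counts for one drug–event pair.

    ``a``: reports with target drug and target event; ``b``: target drug,
    other events; ``c``: other drugs, target event; ``d``: other drugs,
    other events.
    """

    a: int
    b: int
    c: int
    d: int
    event_name: str = ""
    event_code: str = ""
    level: str = "PT"

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {cell} must be a non-negative integer")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm signal thresholds (defaults are the conventional ones)."""

    min_cases: int = 3          # N >= 3 (shared by ROR and PRR rules)
    ror_ci_low_gt: float = 1.0  # ROR CI lower bound > 1
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


# --------------------------------------------------------------------------
# Array-level estimators (the scalar operations below delegate here)
# --------------------------------------------------------------------------

def _cells(a, b, c, d, zero_correction: float = 0.0):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if zero_correction:
        any_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a = np.where(any_zero, a + zero_correction, a)
        b = np.where(any_zero, b + zero_correction, b)
        c = np.where(any_zero, c + zero_correction, c)
        d = np.where(any_zero, d + zero_correction, d)
    return a, b, c, d


def _log_se(a, b, c, d):
    with np.errstate(divide="ignore"):
        return np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def ror_arrays(a, b, c, d, zero_correction: float = 0.0):
    """(ror, ci_low, ci_high); NaN wherever a cell needed is zero."""
    a, b, c, d = _cells(a, b, c, d, zero_correction)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        bad = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        ror = np.where(bad, np.nan, ror)
        se = _log_se(a, b, c, d)
        lo = np.exp(np.log(ror) - 1.96 * se)
        hi = np.exp(np.log(ror) + 1.96 * se)
    return ror, lo, hi


def prr_arrays(a, b, c, d, zero_correction: float = 0.0):
    """(prr, chi2).  chi2 is Pearson's statistic without continuity correction."""
    a, b, c, d = _cells(a, b, c, d, zero_correction)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a * (c + d)) / (c * (a + b))
        prr = np.where((c == 0) | (a + b == 0), np.nan, prr)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = ((a * d - b * c) ** 2) * n / denom
        chi2 = np.where(denom == 0, np.nan, chi2)
    return prr, chi2


def ebgm_arrays(a, b, c, d, zero_correction: float = 0.0):
    """(ebgm, ebgm05).  ebgm needs a>0 and both margins; the bound needs all cells."""
    a, b, c, d = _cells(a, b, c, d, zero_correction)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        ebgm = (a * n) / ((a + c) * (a + b))
        ebgm = np.where((a == 0) | (a + c == 0) | (a + b == 0), np.nan, ebgm)
        se = _log_se(a, b, c, d)
        ebgm05 = np.exp(np.log(ebgm) - 1.96 * se)
        ebgm05 = np.where((b == 0) | (c == 0) | (d == 0), np.nan, ebgm05)
    return ebgm, ebgm05


def ic_arrays(a, b, c, d, variance: str = "delta", kappa: float = 1.66,
              zero_correction: float = 0.0):
    """(ic, ic025) with IC = log₂(EBGM) exactly.

    ``variance="delta"`` uses V(IC) = (1/a+1/b+1/c+1/d)/ln(2)² and
    IC025 = IC − 2·√V; ``variance="fixed"`` uses IC025 = IC − κ.
    """
    ebgm, _ = ebgm_arrays(a, b, c, d, zero_correction)
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = np.log2(ebgm)
    if variance == "delta":
        aa, bb, cc, dd = _cells(a, b, c, d, zero_correction)
        with np.errstate(divide="ignore"):
            v = (1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd) / _LN2_SQ
        ic025 = ic - 2.0 * np.sqrt(v)
        ic025 = np.where(np.isinf(ic025), np.nan, ic025)
    elif variance == "fixed":
        ic025 = ic - kappa
    else:
        raise ValueError(f"unknown IC variance mode: {variance!r}")
    return ic, ic025


def ic_from_ebgm(ebgm) -> np.ndarray | float:
    """The internal identity linking the two Bayesian-style closed forms."""
    return np.log2(ebgm)


# --------------------------------------------------------------------------
# Scalar operations on one table
# --------------------------------------------------------------------------

def ror(table: ContingencyTable, zero_correction: float = 0.0
        ) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% CI; NaN triple if any cell is zero."""
    r, lo, hi = ror_arrays(table.a, table.b, table.c, table.d, zero_correction)
    return float(r), float(lo), float(hi)


def prr_chi2(table: ContingencyTable, zero_correction: float = 0.0
             ) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson χ² (no continuity correction)."""
    p, x2 = prr_arrays(table.a, table.b, table.c, table.d, zero_correction)
    return float(p), float(x2)


def bcpnn_ic(table: ContingencyTable, variance: str = "delta",
             kappa: float = 1.66, zero_correction: float = 0.0
             ) -> tuple[float, float]:
    """Information component and its lower bound IC025."""
    ic, ic025 = ic_arrays(table.a, table.b, table.c, table.d,
                          variance=variance, kappa=kappa,
                          zero_correction=zero_correction)
    return float(ic), float(ic025)


def mgps_ebgm(table: ContingencyTable, zero_correction: float = 0.0
              ) -> tuple[float, float]:
    """Empirical Bayes geometric mean (closed form) and EBGM05."""
    e, e05 = ebgm_arrays(table.a, table.b, table.c, table.d, zero_correction)
    return float(e), float(e05)


# --------------------------------------------------------------------------
# Table construction
# --------------------------------------------------------------------------

def build_tables(target_pairs: pd.DataFrame, comparator_pairs: pd.DataFrame,
                 dictionary: DictionaryMap | None = None, level: str = "PT"
                 ) -> pd.DataFrame:
    """Build one 2×2 table per observed event at PT or SOC level.

    Inputs are report–event pair frames with columns ``primaryid`` and
    ``pt``.  The counting unit is the distinct report–event pair: a report
    counts once per distinct PT, and at SOC level once per SOC no matter how
    many of its PTs map there.  Events observed only among comparators get
    a=0 rows so margins reconcile.

    Returns a DataFrame with columns ``event, event_code, level, a, b, c, d``;
    the number of pairs whose PT was missing from the dictionary is stored in
    ``result.attrs["unresolved_pairs"]``.

    Raises ``ValueError`` for an empty target cohort or unknown level.
    """
    if level not in {"PT", "SOC"}:
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    if not len(target_pairs):
        raise ValueError("empty cohort: no target report-event pairs")
    if level == "SOC" and dictionary is None:
        raise ValueError("SOC-level tables need a PT->SOC dictionary")

    unresolved = 0
    code_map: dict[str, str] = {}

    def to_events(pairs: pd.DataFrame) -> pd.DataFrame:
        nonlocal unresolved
        ev = pairs[["primaryid", "pt"]].copy()
        if level == "SOC":
            soc = ev["pt"].map(dictionary.pt_to_soc)
            missing = soc.isna()
            unresolved += int(missing.sum())
            ev = ev[~missing]
            ev["event"] = soc[~missing]
        else:
            ev["event"] = ev["pt"]
        return ev[["primaryid", "event"]].drop_duplicates()

    tgt = to_events(target_pairs)
    cmp_ = to_events(comparator_pairs)
    if unresolved:
        logger.warning("build_tables: %d report-event pairs dropped "
                       "(PT not in dictionary)", unresolved)

    a = tgt.groupby("event").size()
    c = cmp_.groupby("event").size()
    events = a.index.union(c.index)
    a = a.reindex(events, fill_value=0)
    c = c.reindex(events, fill_value=0)
    n_tgt, n_cmp = len(tgt), len(cmp_)

    if dictionary is not None:
        code_map = dictionary.soc_code if level == "SOC" else dictionary.pt_code

    out = pd.DataFrame({
        "event": events,
        "event_code": [code_map.get(e, "") for e in events],
        "level": level,
        "a": a.to_numpy(dtype=int),
        "b": (n_tgt - a).to_numpy(dtype=int),
        "c": c.to_numpy(dtype=int),
        "d": (n_cmp - c).to_numpy(dtype=int),
    }).sort_values("a", ascending=False, kind="stable").reset_index(drop=True)
    out.attrs["unresolved_pairs"] = unresolved
    return out


def tables_to_records(tables: pd.DataFrame) -> list[ContingencyTable]:
    """View a table frame as a list of :class:`ContingencyTable`."""
    return [
        ContingencyTable(a=int(r.a), b=int(r.b), c=int(r.c), d=int(r.d),
                         event_name=r.event, event_code=r.event_code,
                         level=r.level)
        for r in tables.itertuples(index=False)
    ]


# --------------------------------------------------------------------------
# Full statistics frame and signal flags
# --------------------------------------------------------------------------

def compute_signals(tables: pd.DataFrame,
                    criteria: SignalCriteria = SignalCriteria(),
                    ic_variance: str = "delta", ic_kappa: float = 1.66,
                    zero_correction: float = 0.0) -> pd.DataFrame:
    """All four estimators, CIs and flags for every table row.

    Undefined statistics (NaN) fail their flag; ``consensus`` is the
    conjunction of the four per-algorithm flags.
    """
    a, b, c, d = (tables[k].to_numpy() for k in "abcd")
    out = tables.copy()
    out["n"] = out["a"]
    out["ror"], out["ror_ci_low"], out["ror_ci_high"] = ror_arrays(
        a, b, c, d, zero_correction)
    out["prr"], out["chi2"] = prr_arrays(a, b, c, d, zero_correction)
    out["ebgm"], out["ebgm05"] = ebgm_arrays(a, b, c, d, zero_correction)
    out["ic"], out["ic025"] = ic_arrays(
        a, b, c, d, variance=ic_variance, kappa=ic_kappa,
        zero_correction=zero_correction)
    return flag_signals(out, criteria)


def flag_signals(stats: pd.DataFrame,
                 criteria: SignalCriteria = SignalCriteria()) -> pd.DataFrame:
    """Apply the per-algorithm criteria and the four-way consensus rule."""
    out = stats.copy()
    n = out["n"]
    with np.errstate(invalid="ignore"):
        out["ror_pos"] = ((n >= criteria.min_cases)
                          & (out["ror_ci_low"] > criteria.ror_ci_low_gt)).fillna(False)
        out["prr_pos"] = ((n >= criteria.min_cases)
                          & (out["prr"] >= criteria.prr_min)
                          & (out["chi2"] >= criteria.chi2_min)).fillna(False)
        out["bcpnn_pos"] = (out["ic025"] > criteria.ic025_gt).fillna(False)
        out["mgps_pos"] = (out["ebgm05"] > criteria.ebgm05_gt).fillna(False)
    out["consensus"] = (out["ror_pos"] & out["prr_pos"]
                        & out["bcpnn_pos"] & out["mgps_pos"])
    return out


def forest_plot_frame(stats: pd.DataFrame) -> pd.DataFrame:
    """Long-format (label, estimate, low, high, level) frame for forest plots."""
    return pd.DataFrame({
        "label": stats["event"],
        "estimate": stats["ror"],
        "low": stats["ror_ci_low"],
        "high": stats["ror_ci_high"],
        "level": stats["level"],
        "n": stats["n"],
    })
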