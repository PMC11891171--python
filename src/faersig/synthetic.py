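"""Synthetic FAERS-like data with known ground truth.

Spontaneous-report databases cannot be bundled (and MedDRA is licensed), so
this module fabricates quarterly DEMO/DRUG/REAC/OUTC/THER/INDI file sets in
the FAERS ASCII dialect together with a two-level PT→SOC dictionary and a
ground-truth sidecar.  The generator controls the quantities the analysis
pipeline is supposed to recover:

* per-PT true reporting-rate ratios ρ between reports exposed to the target
  drug (present as primary suspect) and all other reports — ρ=1 is the null;
* a duplicate-case process: a configurable fraction of cases is re-submitted
  under a new PRIMARYID with a later (or deliberately tied) FDA_DT, so the
  FDA deduplication rule has a known designated survivor;
* demographics with FAERS-like heavy missingness, partial dates, age-unit
  codes, and reporter occupations;
* therapy start / event dates whose difference (time to onset) is log-normal
  with a configurable median.

Event probabilities follow a log-uniform baseline shape over [1e-4, 1e-2],
rescaled by a common factor so the expected number of drawn PTs per report
equals ``mean_pts_per_report`` (each probability capped at 0.5); exposed
reports multiply seeded PTs by ρ before the cap.  A report that draws no
event receives a single PT from the normalized weight vector, since real
reports always carry at least one reaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PARSED_COLUMNS, TABLE_KINDS, quarter_label, write_table

# --------------------------------------------------------------------------
# Default event vocabulary (MedDRA-style PT -> SOC, invented terms drawn from
# common antidepressant pharmacovigilance findings)
# --------------------------------------------------------------------------

DEFAULT_VOCABULARY: list[tuple[str, str]] = [
    ("nausea", "gastrointestinal disorders"),
    ("vomiting", "gastrointestinal disorders"),
    ("dry mouth", "gastrointestinal disorders"),
    ("diarrhoea", "gastrointestinal disorders"),
    ("constipation", "gastrointestinal disorders"),
    ("retching", "gastrointestinal disorders"),
    ("suicidal ideation", "psychiatric disorders"),
    ("insomnia", "psychiatric disorders"),
    ("irritability", "psychiatric disorders"),
    ("anger", "psychiatric disorders"),
    ("apathy", "psychiatric disorders"),
    ("agitation", "psychiatric disorders"),
    ("mood swings", "psychiatric disorders"),
    ("libido decreased", "psychiatric disorders"),
    ("anxiety", "psychiatric disorders"),
    ("panic attack", "psychiatric disorders"),
    ("mania", "psychiatric disorders"),
    ("abnormal dreams", "psychiatric disorders"),
    ("nightmare", "psychiatric disorders"),
    ("restlessness", "psychiatric disorders"),
    ("depression", "psychiatric disorders"),
    ("headache", "nervous system disorders"),
    ("dizziness", "nervous system disorders"),
    ("somnolence", "nervous system disorders"),
    ("tremor", "nervous system disorders"),
    ("serotonin syndrome", "nervous system disorders"),
    ("disturbance in attention", "nervous system disorders"),
    ("hypersomnia", "nervous system disorders"),
    ("akathisia", "nervous system disorders"),
    ("seizure", "nervous system disorders"),
    ("pruritus", "skin and subcutaneous tissue disorders"),
    ("rash", "skin and subcutaneous tissue disorders"),
    ("hyperhidrosis", "skin and subcutaneous tissue disorders"),
    ("urticaria", "skin and subcutaneous tissue disorders"),
    ("fatigue", "general disorders and administration site conditions"),
    ("feeling abnormal", "general disorders and administration site conditions"),
    ("crying", "general disorders and administration site conditions"),
    ("malaise", "general disorders and administration site conditions"),
    ("weight increased", "investigations"),
    ("weight decreased", "investigations"),
    ("blood sodium decreased", "investigations"),
    ("hyperphagia", "metabolism and nutrition disorders"),
    ("decreased appetite", "metabolism and nutrition disorders"),
    ("sexual dysfunction", "reproductive system and breast disorders"),
    ("erectile dysfunction", "reproductive system and breast disorders"),
    ("tinnitus", "ear and labyrinth disorders"),
    ("vertigo", "ear and labyrinth disorders"),
    ("urinary retention", "renal and urinary disorders"),
    ("palpitations", "cardiac disorders"),
    ("tachycardia", "cardiac disorders"),
    ("alcohol use", "social circumstances"),
    ("muscle twitching", "musculoskeletal and connective tissue disorders"),
]

DEFAULT_TARGET_NAMES = ("trintellix", "vortioxetine")

_OTHER_INDICATIONS = ("hypertension", "diabetes mellitus", "pain", "asthma")
_TARGET_INDICATIONS = ("major depressive disorder", "depression")

_COUNTRIES = np.array(["US", "JP", "FR", "GB", "CA", "DE", "BR"])
_COUNTRY_P = np.array([0.78, 0.05, 0.04, 0.04, 0.03, 0.03, 0.03])
_OCCP = np.array(["CN", "MD", "OT", "HP", "PH"])
_OCCP_P = np.array([0.50, 0.26, 0.12, 0.07, 0.05])
_OUTC = np.array(["OT", "HO", "DE", "LT", "DS", "RI", "CA"])
_OUTC_P = np.array([0.60, 0.25, 0.05, 0.04, 0.035, 0.022, 0.003])


# --------------------------------------------------------------------------
# Configuration and ground truth
# --------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the synthetic reporting stream.

    ``signal_spec`` maps PT names to their true reporting-rate ratio ρ
    (exposed vs non-exposed reports); any PT not listed has ρ=1.
    """

    n_reports: int
    n_quarters: int = 8
    target_drug_names: tuple[str, ...] = DEFAULT_TARGET_NAMES
    n_other_drugs: int = 50
    pt_vocabulary: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_VOCABULARY))
    signal_spec: dict[str, float] = field(default_factory=dict)
    exposed_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    duplicate_tie_fraction: float = 0.2
    missing_sex_frac: float = 0.13
    missing_age_frac: float = 0.56
    missing_weight_frac: float = 0.79
    missing_date_frac: float = 0.25
    mean_pts_per_report: float = 2.0
    tto_median_days: float = 7.0
    tto_sigma: float = 1.5
    start_year: int = 2016
    start_quarter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be >= 1")
        if not self.pt_vocabulary:
            raise ValueError("pt_vocabulary must not be empty")
        names = [pt for pt, _ in self.pt_vocabulary]
        if len(set(names)) != len(names):
            raise ValueError("duplicate PT names in pt_vocabulary")
        unknown = set(self.signal_spec) - set(names)
        if unknown:
            raise ValueError(f"signal_spec PTs not in vocabulary: {sorted(unknown)}")
        if any(rho < 0 for rho in self.signal_spec.values()):
            raise ValueError("reporting-rate ratios must be >= 0")
        for frac_name in ("duplicate_fraction", "duplicate_tie_fraction",
                          "exposed_fraction", "missing_sex_frac",
                          "missing_age_frac", "missing_weight_frac",
                          "missing_date_frac"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.mean_pts_per_report <= 0:
            raise ValueError("mean_pts_per_report must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for verifying the pipeline.

    ``survivors`` designates, per CASEID, the PRIMARYID that the FDA rule
    (latest FDA_DT, then highest PRIMARYID) must retain.
    """

    pt_rho: dict[str, float]
    baseline_p: dict[str, float]
    case_lineage: dict[str, list[str]]
    survivors: dict[str, str]
    exposed_caseids: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# Dictionary
# --------------------------------------------------------------------------

@dataclass
class DictionaryMap:
    """Two-level MedDRA-style mapping: PT -> SOC with 8-digit codes."""

    frame: pd.DataFrame  # columns: pt, pt_code, soc, soc_code

    @property
    def pt_to_soc(self) -> dict[str, str]:
        return dict(zip(self.frame["pt"], self.frame["soc"]))

    @property
    def pt_code(self) -> dict[str, str]:
        return dict(zip(self.frame["pt"], self.frame["pt_code"]))

    @property
    def soc_code(self) -> dict[str, str]:
        return dict(zip(self.frame["soc"], self.frame["soc_code"]))

    def save(self, path: str | Path) -> None:
        lines = ["pt$pt_code$soc$soc_code"]
        for row in self.frame.itertuples(index=False):
            lines.append(f"{row.pt}${row.pt_code}${row.soc}${row.soc_code}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DictionaryMap":
        rows = []
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            pt, pt_code, soc, soc_code = line.split("$")
            rows.append((pt, pt_code, soc, soc_code))
        return cls(pd.DataFrame(rows, columns=["pt", "pt_code", "soc", "soc_code"]))


def make_dictionary(config: SyntheticConfig) -> DictionaryMap:
    """Build a PT→SOC dictionary with unique 8-digit numeric codes.

    Raises ``ValueError`` on duplicate PT names (a PT belongs to exactly one
    SOC in a MedDRA-style hierarchy).
    """
    names = [pt for pt, _ in config.pt_vocabulary]
    if len(set(names)) != len(names):
        raise ValueError("duplicate PT names in vocabulary")
    socs: list[str] = []
    for _, soc in config.pt_vocabulary:
        if soc not in socs:
            socs.append(soc)
    soc_codes = {soc: f"{20000000 + i:08d}" for i, soc in enumerate(socs)}
    rows = [
        (pt, f"{10000000 + i:08d}", soc, soc_codes[soc])
        for i, (pt, soc) in enumerate(config.pt_vocabulary)
    ]
    return DictionaryMap(pd.DataFrame(rows, columns=["pt", "pt_code", "soc", "soc_code"]))


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _quarter_bounds(config: SyntheticConfig) -> list[tuple[pd.Timestamp, pd.Timestamp, str]]:
    """(start, end, label) for each generated quarter."""
    out = []
    year, q = config.start_year, config.start_quarter
    for _ in range(config.n_quarters):
        start = pd.Timestamp(year=year, month=3 * (q - 1) + 1, day=1)
        end = start + pd.offsets.QuarterEnd(startingMonth=3)
        out.append((start, end, quarter_label(year % 100, q)))
        q += 1
        if q == 5:
            q, year = 1, year + 1
    return out


def _event_probabilities(config: SyntheticConfig, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-PT event probabilities for (non-exposed, exposed) reports."""
    V = len(config.pt_vocabulary)
    raw = 10.0 ** rng.uniform(-4.0, -2.0, size=V)
    scale = config.mean_pts_per_report / raw.sum()
    p_base = np.minimum(raw * scale, 0.5)
    rho = np.ones(V)
    names = [pt for pt, _ in config.pt_vocabulary]
    for pt, r in config.signal_spec.items():
        rho[names.index(pt)] = r
    p_exp = np.minimum(p_base * rho, 0.5)
    return p_base, p_exp


def _dates_to_str(dates: pd.Series | np.ndarray) -> np.ndarray:
    return pd.DatetimeIndex(dates).strftime("%Y%m%d").to_numpy()


def _degrade_dates(dates: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Replace a fraction of full dates with partial (YYYYMM/YYYY) or empty."""
    out = dates.astype(object).copy()
    hit = rng.random(len(out)) < frac
    kind = rng.integers(0, 3, size=len(out))  # 0: month, 1: year, 2: missing
    for i in np.nonzero(hit)[0]:
        if kind[i] == 0:
            out[i] = out[i][:6]
        elif kind[i] == 1:
            out[i] = out[i][:4]
        else:
            out[i] = ""
    return out


def generate_frames(config: SyntheticConfig
                    ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate the six tables in memory (with a ``quarter`` column) plus truth.

    Bit-reproducible for a fixed config: the same seed yields identical
    frames and therefore identical files.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    names = [pt for pt, _ in config.pt_vocabulary]
    p_base, p_exp = _event_probabilities(config, rng)

    if n == 0:
        empty = {
            kind.lower(): pd.DataFrame(columns=PARSED_COLUMNS[kind] + ["quarter"])
            for kind in TABLE_KINDS
        }
        truth = GroundTruth(
            pt_rho={pt: float(config.signal_spec.get(pt, 1.0)) for pt in names},
            baseline_p={pt: float(p) for pt, p in zip(names, p_base)},
            case_lineage={}, survivors={}, exposed_caseids=[])
        return empty, truth

    bounds = _quarter_bounds(config)
    q_idx = rng.integers(0, config.n_quarters, size=n)
    q_start = np.array([b[0].value for b in bounds])
    q_days = np.array([(b[1] - b[0]).days for b in bounds])
    day_off = (rng.random(n) * (q_days[q_idx] + 1)).astype(int)
    fda_dt = pd.to_datetime(q_start[q_idx]) + pd.to_timedelta(day_off, unit="D")

    exposed = rng.random(n) < config.exposed_fraction

    # reactions: Bernoulli per PT, one categorical draw for empty reports
    probs = np.where(exposed[:, None], p_exp[None, :], p_base[None, :])
    hits = rng.random((n, len(names))) < probs
    empty_rows = ~hits.any(axis=1)
    if empty_rows.any():
        w = probs[empty_rows]
        w = w / w.sum(axis=1, keepdims=True)
        cdf = np.cumsum(w, axis=1)
        u = rng.random(empty_rows.sum())
        choice = (u[:, None] > cdf).sum(axis=1)
        hits[np.nonzero(empty_rows)[0], choice] = True

    caseid = np.char.add("6", np.char.zfill(np.arange(n).astype(str), 7))
    # primaryids are a random permutation so a case's later version is not
    # always the numerically larger id (exercises the tie-break both ways)
    n_dup_pool = n
    pid_pool = 100000000 + rng.permutation(2 * n_dup_pool)

    pid = pid_pool[:n].astype(str)

    # demographics
    sex = np.where(rng.random(n) < 0.63, "F", "M")
    sex_missing = rng.random(n) < config.missing_sex_frac
    sex_raw = sex.astype(object)
    # a third of missing sexes are coded "U" rather than blank
    u_code = sex_missing & (rng.random(n) < 1 / 3)
    sex_raw[sex_missing] = ""
    sex_raw[u_code] = "U"
    age = np.clip(rng.normal(46, 18, size=n), 1, 95).round(1)
    age[rng.random(n) < config.missing_age_frac] = np.nan
    wt = np.clip(rng.normal(75, 16, size=n), 35, 160).round(1)
    wt[rng.random(n) < config.missing_weight_frac] = np.nan
    occp = rng.choice(_OCCP, size=n, p=_OCCP_P)
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)

    # onset dates: event precedes receipt; therapy start precedes event by TTO
    report_lag = rng.integers(0, 30, size=n)
    tto = np.maximum(
        np.rint(rng.lognormal(np.log(config.tto_median_days), config.tto_sigma, n)),
        0).astype(int)
    event_dt = fda_dt - pd.to_timedelta(report_lag, unit="D")
    start_dt = event_dt - pd.to_timedelta(tto, unit="D")

    fda_s = _dates_to_str(fda_dt)
    event_s = _degrade_dates(_dates_to_str(event_dt), config.missing_date_frac, rng)
    start_s = _degrade_dates(_dates_to_str(start_dt), config.missing_date_frac, rng)

    demo = pd.DataFrame({
        "primaryid": pid, "caseid": caseid, "fda_dt": fda_s, "event_dt": event_s,
        "age_yr": age, "sex": pd.array(np.where(sex_raw == "", pd.NA, sex_raw)),
        "wt_kg": wt, "occp_cod": occp, "reporter_country": country,
        "quarter": np.array([bounds[i][2] for i in q_idx]),
    })
    demo["sex"] = demo["sex"].where(demo["sex"].isin(["F", "M"]), pd.NA)
    demo["_sex_raw"] = sex_raw  # written to file, then dropped

    # drugs
    target_variants = [t.upper() for t in config.target_drug_names]
    target_variants += [config.target_drug_names[-1].upper() + " HYDROBROMIDE",
                        config.target_drug_names[-1].upper() + " HYDROBROMIDE 10MG"]
    other_names = np.array(
        [f"COMPOUND {k:03d}" for k in range(config.n_other_drugs)])
    drug_rows: list[tuple[str, str, int, str, str, str, str]] = []
    ther_rows: list[tuple[str, str, int, object, str]] = []
    indi_rows: list[tuple[str, str, int, str, str]] = []
    primary_name = np.where(
        exposed,
        np.array(target_variants)[rng.integers(0, len(target_variants), n)],
        other_names[rng.integers(0, config.n_other_drugs, n)])
    primary_ai = np.where(exposed, config.target_drug_names[-1].upper(), "")
    # a slice of non-exposed reports mention the target in a non-PS role
    bystander = (~exposed) & (rng.random(n) < 0.02)
    n_conco = rng.poisson(0.7, size=n)
    conco_roles = np.array(["C", "SS"])
    qlab = demo["quarter"].to_numpy()
    for i in range(n):
        drug_rows.append((pid[i], caseid[i], 1, "PS",
                          primary_name[i], primary_ai[i], qlab[i]))
        ther_rows.append((pid[i], caseid[i], 1, start_s[i], qlab[i]))
        if exposed[i]:
            ind = _TARGET_INDICATIONS[int(rng.integers(0, len(_TARGET_INDICATIONS)))]
        else:
            ind = _OTHER_INDICATIONS[int(rng.integers(0, len(_OTHER_INDICATIONS)))]
        indi_rows.append((pid[i], caseid[i], 1, ind, qlab[i]))
        seq = 2
        if bystander[i]:
            drug_rows.append((pid[i], caseid[i], seq,
                              conco_roles[int(rng.integers(0, 2))],
                              target_variants[int(rng.integers(0, len(target_variants)))],
                              config.target_drug_names[-1].upper(), qlab[i]))
            seq += 1
        for _ in range(n_conco[i]):
            drug_rows.append((pid[i], caseid[i], seq,
                              conco_roles[int(rng.integers(0, 2))],
                              other_names[int(rng.integers(0, config.n_other_drugs))],
                              "", qlab[i]))
            seq += 1

    drug = pd.DataFrame(drug_rows, columns=[
        "primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai",
        "quarter"])
    ther = pd.DataFrame(ther_rows, columns=[
        "primaryid", "caseid", "drug_seq", "start_dt", "quarter"])
    indi = pd.DataFrame(indi_rows, columns=[
        "primaryid", "caseid", "drug_seq", "indi_pt", "quarter"])

    rep_idx, pt_idx = np.nonzero(hits)
    reac = pd.DataFrame({
        "primaryid": pid[rep_idx], "caseid": caseid[rep_idx],
        "pt": np.array(names)[pt_idx], "quarter": qlab[rep_idx],
    })

    has_outc = rng.random(n) < 0.35
    outc_code = rng.choice(_OUTC, size=n, p=_OUTC_P)
    outc = pd.DataFrame({
        "primaryid": pid[has_outc], "caseid": caseid[has_outc],
        "outc_cod": outc_code[has_outc], "quarter": qlab[has_outc],
    })

    # duplicate-case process: re-submissions with a new PRIMARYID
    is_dup = rng.random(n) < config.duplicate_fraction
    dup_src = np.nonzero(is_dup)[0]
    n_dup = len(dup_src)
    last_end = bounds[-1][1]
    dup_pids = pid_pool[n: n + n_dup].astype(str)
    tie = rng.random(n_dup) < config.duplicate_tie_fraction
    delta = rng.integers(1, 90, size=max(n_dup, 1))[:n_dup]
    new_fda = pd.DatetimeIndex(fda_dt[dup_src]) + pd.to_timedelta(
        np.where(tie, 0, delta), unit="D")
    new_fda = pd.DatetimeIndex(np.minimum(new_fda.to_numpy(),
                                          np.datetime64(last_end)))
    q_starts = np.array([np.datetime64(b[0]) for b in bounds])
    new_q_idx = np.searchsorted(q_starts, new_fda.to_numpy(), side="right") - 1
    new_q = np.array([bounds[i][2] for i in new_q_idx])

    tables = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
              "ther": ther, "indi": indi}
    if n_dup:
        old_to_new = dict(zip(pid[dup_src], dup_pids))
        old_to_q = dict(zip(pid[dup_src], new_q))
        for kind, df in list(tables.items()):
            rows = df[df["primaryid"].isin(old_to_new)].copy()
            if kind == "demo":
                rows["fda_dt"] = rows["primaryid"].map(
                    dict(zip(pid[dup_src], new_fda.strftime("%Y%m%d"))))
            rows["quarter"] = rows["primaryid"].map(old_to_q)
            rows["primaryid"] = rows["primaryid"].map(old_to_new)
            tables[kind] = pd.concat([df, rows], ignore_index=True)

    lineage: dict[str, list[str]] = {c: [p] for c, p in zip(caseid, pid)}
    survivors: dict[str, str] = dict(zip(caseid, pid))
    old_fda = pd.DatetimeIndex(fda_dt[dup_src])
    for j, i in enumerate(dup_src):
        lineage[caseid[i]] = [pid[i], dup_pids[j]]
        # FDA rule: latest FDA_DT wins, ties broken by highest PRIMARYID
        if new_fda[j] > old_fda[j] or (new_fda[j] == old_fda[j]
                                       and int(dup_pids[j]) > int(pid[i])):
            survivors[caseid[i]] = dup_pids[j]

    for kind in tables:
        tables[kind] = tables[kind].sort_values(
            ["quarter", "primaryid"], kind="stable").reset_index(drop=True)

    truth = GroundTruth(
        pt_rho={pt: float(config.signal_spec.get(pt, 1.0)) for pt in names},
        baseline_p={pt: float(p) for pt, p in zip(names, p_base)},
        case_lineage=lineage,
        survivors=survivors,
        exposed_caseids=[caseid[i] for i in np.nonzero(exposed)[0]],
    )
    return tables, truth


def write_quarterly_files(tables: dict[str, pd.DataFrame], outdir: str | Path,
                          config: SyntheticConfig) -> list[Path]:
    """Write one dollar-delimited file per table per quarter."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    labels = [lab for _, _, lab in _quarter_bounds(config)]
    for kind in TABLE_KINDS:
        df = tables[kind.lower()]
        for lab in labels:
            sub = df[df.get("quarter", pd.Series(dtype=str)) == lab] if len(df) \
                else df
            path = outdir / f"{kind}{lab}.txt"
            out = sub.drop(columns=["quarter"], errors="ignore").copy()
            if kind == "DEMO" and "_sex_raw" in out.columns:
                # preserve the raw sex coding ("U" vs blank) in the file
                out["sex"] = out["_sex_raw"]
                out = out.drop(columns=["_sex_raw"])
                out = out.rename(columns={"age_yr": "age", "wt_kg": "wt"})
                out["age_cod"] = np.where(out["age"].notna(), "YR", "")
                out["wt_cod"] = np.where(out["wt"].notna(), "KG", "")
                _write_raw(out, path, kind)
            else:
                write_table(out, path, kind)
            paths.append(path)
    return paths


def _write_raw(df: pd.DataFrame, path: Path, kind: str) -> None:
    from .io import DELIMITER, TABLE_COLUMNS

    cols = TABLE_COLUMNS[kind]
    lines = [DELIMITER.join(cols)]

    def fmt(v) -> str:
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            return ""
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    if len(df):
        body = df[cols].map(fmt)
        lines.extend(DELIMITER.join(row) for row in body.itertuples(index=False))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate(config: SyntheticConfig, outdir: str | Path
             ) -> tuple[list[Path], GroundTruth]:
    """Generate and write a full synthetic quarterly file set.

    Writes the six tables per quarter, the PT→SOC dictionary
    (``meddra_like.txt``) and a ground-truth sidecar
    (``ground_truth.json``); returns the file list and the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise NotADirectoryError(str(outdir))
    tables, truth = generate_frames(config)
    paths = write_quarterly_files(tables, outdir, config)
    dictionary = make_dictionary(config)
    dictionary.save(outdir / "meddra_like.txt")
    truth.to_json(outdir / "ground_truth.json")
    return paths, truth
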