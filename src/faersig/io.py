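"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as a set of dollar-delimited text files, one
per table (DEMO, DRUG, REAC, OUTC, THER, INDI), with a header row naming the
columns.  Embedded delimiters are never escaped in the real dialect, so a row
is parsed by splitting on ``$`` and checking the field count against the
header; rows that fail structural or type validation are quarantined in a
rejects table (file, line, reason) rather than silently dropped.

Parsed tables are returned as :class:`pandas.DataFrame` objects with
normalized columns: dates stay as digit strings (full ``YYYYMMDD``, partial
``YYYYMM``/``YYYY``, or empty), ages are converted to years (``age_yr``),
weights to kilograms (``wt_kg``), and unknown codes map to missing values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Table dialect
# --------------------------------------------------------------------------

DELIMITER = "$"

#: Columns written (and required on read) for each table kind.  Extra columns
#: in an input file are ignored; order is discovered from the header.
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "wt_cod", "occp_cod", "reporter_country",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

TABLE_KINDS = tuple(TABLE_COLUMNS)

#: Columns of the parsed (normalized) in-memory representation.
PARSED_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age_yr", "sex",
        "wt_kg", "occp_cod", "reporter_country",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "drug_seq", "start_dt"],
    "INDI": ["primaryid", "caseid", "drug_seq", "indi_pt"],
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_CODES = frozenset({"F", "M"})
OCCP_CODES = frozenset({"MD", "PH", "OT", "CN", "HP", "LW", "RN"})

# age-unit code -> factor converting to years
_AGE_FACTORS = {
    "DEC": 10.0, "YR": 1.0, "YEAR": 1.0, "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25, "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
}
# weight-unit code -> factor converting to kilograms
_WT_FACTORS = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}

_FULL_DATE_RE = re.compile(r"^\d{8}$")
_PARTIAL_DATE_RE = re.compile(r"^\d{4}(\d{2})?$")


def parse_date(value: str | float | None) -> pd.Timestamp | None:
    """Parse an 8-digit ``YYYYMMDD`` string to a Timestamp; None otherwise."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not _FULL_DATE_RE.match(s):
        return None
    ts = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    return None if pd.isna(ts) else ts


def date_precision(value: str | None) -> str:
    """Classify a FAERS date string: 'full', 'month', 'year', or 'missing'.

    An 8-digit string that is not a real calendar date counts as missing.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    s = str(value).strip()
    if not s:
        return "missing"
    if _FULL_DATE_RE.match(s):
        return "full" if parse_date(s) is not None else "missing"
    if _PARTIAL_DATE_RE.match(s):
        if len(s) == 6:
            return "month" if 1 <= int(s[4:6]) <= 12 else "missing"
        return "year"
    return "missing"


@dataclass
class TableReadResult:
    """A parsed table plus its quarantined rows."""

    records: pd.DataFrame
    rejects: pd.DataFrame  # columns: file, line, reason

    @property
    def n_rows_in(self) -> int:
        return len(self.records) + len(self.rejects)


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=["file", "line", "reason"])


def _read_lines(path: Path) -> list[str]:
    # real FAERS files mix encodings: try UTF-8, fall back to latin-1
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    return text.splitlines()


def read_table(path: str | Path, table_kind: str) -> TableReadResult:
    """Read one dollar-delimited quarterly file into typed records.

    Column order is discovered from the header (case-insensitive).  Rows with
    the wrong field count or failing type validation land in ``rejects`` with
    their 1-based line number and a reason; they are never silently dropped.

    Raises
    ------
    ValueError
        If *table_kind* is unknown or a mandatory column is absent.
    FileNotFoundError
        If *path* does not exist.
    """
    table_kind = table_kind.upper()
    if table_kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    path = Path(path)
    lines = _read_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty file (no header row)")

    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    required = TABLE_COLUMNS[table_kind]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    idx = {c: header.index(c) for c in required}
    n_fields = len(header)

    good_rows: list[list[str]] = []
    good_lines: list[int] = []
    rej_lines: list[int] = []
    rej_reasons: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) != n_fields:
            rej_lines.append(lineno)
            rej_reasons.append(f"expected {n_fields} fields, found {len(parts)}")
            continue
        good_rows.append([parts[idx[c]].strip() for c in required])
        good_lines.append(lineno)

    raw = pd.DataFrame(good_rows, columns=required, dtype=str)
    raw.index = pd.Index(good_lines, name="line")
    parsed, bad_mask, bad_reason = _validate(raw, table_kind)

    rejects = pd.DataFrame({
        "file": str(path),
        "line": rej_lines + list(raw.index[bad_mask]),
        "reason": rej_reasons + list(bad_reason[bad_mask]),
    }) if (rej_lines or bad_mask.any()) else _empty_rejects()
    rejects = rejects.sort_values("line").reset_index(drop=True) if len(rejects) else rejects

    records = parsed[~bad_mask].reset_index(drop=True)
    return TableReadResult(records=records, rejects=rejects)


def _validate(raw: pd.DataFrame, kind: str) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Normalize a raw string table; return (parsed, reject_mask, reasons)."""
    n = len(raw)
    bad = pd.Series(False, index=raw.index)
    reason = pd.Series("", index=raw.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        newly = mask & ~bad
        reason[newly] = why
        bad[newly] = True

    out = pd.DataFrame(index=raw.index)
    out["primaryid"] = raw["primaryid"]
    out["caseid"] = raw["caseid"] if "caseid" in raw else ""
    flag(out["primaryid"] == "", "empty primaryid")

    if kind == "DEMO":
        flag(out["caseid"] == "", "empty caseid")
        prec = raw["fda_dt"].map(date_precision)
        flag((raw["fda_dt"].str.len() == 8) & (prec == "missing"),
             "fda_dt is 8 digits but not a valid calendar date")
        out["fda_dt"] = raw["fda_dt"]
        out["event_dt"] = raw["event_dt"].where(
            raw["event_dt"].map(date_precision) != "missing", "")
        age = pd.to_numeric(raw["age"], errors="coerce")
        cod = raw["age_cod"].str.upper().replace("", "YR")
        factor = cod.map(_AGE_FACTORS)
        out["age_yr"] = (age * factor).astype(float)
        sex = raw["sex"].str.upper()
        out["sex"] = sex.where(sex.isin(SEX_CODES), other=pd.NA)
        wt = pd.to_numeric(raw["wt"], errors="coerce")
        wcod = raw["wt_cod"].str.upper().replace("", "KG")
        out["wt_kg"] = (wt * wcod.map(_WT_FACTORS)).astype(float)
        occ = raw["occp_cod"].str.upper()
        out["occp_cod"] = occ.where(occ.isin(OCCP_CODES), other=pd.NA)
        ctry = raw["reporter_country"]
        out["reporter_country"] = ctry.where(ctry != "", other=pd.NA)
    elif kind == "DRUG":
        seq = pd.to_numeric(raw["drug_seq"], errors="coerce")
        flag(seq.isna(), "drug_seq is not an integer")
        out["drug_seq"] = seq.fillna(-1).astype(int)
        role = raw["role_cod"].str.upper()
        flag(~role.isin(ROLE_CODES), "role_cod not in {PS,SS,C,I}")
        out["role_cod"] = role
        out["drugname"] = raw["drugname"]
        out["prod_ai"] = raw["prod_ai"]
    elif kind == "REAC":
        pt = raw["pt"].str.strip().str.replace(r"\s+", " ", regex=True)
        flag(pt == "", "empty pt")
        out["pt"] = pt
    elif kind == "OUTC":
        code = raw["outc_cod"].str.upper()
        flag(~code.isin(OUTCOME_CODES), "outc_cod not in {DE,LT,HO,DS,CA,RI,OT}")
        out["outc_cod"] = code
    elif kind == "THER":
        seq = pd.to_numeric(raw["dsg_drug_seq"], errors="coerce")
        flag(seq.isna(), "dsg_drug_seq is not an integer")
        out["drug_seq"] = seq.fillna(-1).astype(int)
        out["start_dt"] = raw["start_dt"].where(
            raw["start_dt"].map(date_precision) != "missing", "")
    elif kind == "INDI":
        seq = pd.to_numeric(raw["indi_drug_seq"], errors="coerce")
        flag(seq.isna(), "indi_drug_seq is not an integer")
        out["drug_seq"] = seq.fillna(-1).astype(int)
        out["indi_pt"] = raw["indi_pt"].str.strip().str.replace(r"\s+", " ", regex=True)

    if n == 0:
        out = pd.DataFrame(columns=PARSED_COLUMNS[kind])
        return out, pd.Series(dtype=bool), pd.Series(dtype=object)
    return out[PARSED_COLUMNS[kind]], bad, reason


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
        return ""
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def write_table(records: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write parsed records back to the dollar-delimited dialect.

    Normalized quantities are emitted in canonical units (age in years with
    ``age_cod=YR``, weight in kg with ``wt_cod=KG``), so write→read is the
    identity on parsed records.
    """
    table_kind = table_kind.upper()
    cols = TABLE_COLUMNS[table_kind]
    df = records.copy()
    if table_kind == "DEMO":
        df["age"], df["age_cod"] = df["age_yr"], "YR"
        df["wt"], df["wt_cod"] = df["wt_kg"], "KG"
        df.loc[df["age_yr"].isna(), "age_cod"] = ""
        df.loc[df["wt_kg"].isna(), "wt_cod"] = ""
    elif table_kind == "THER":
        df["dsg_drug_seq"] = df["drug_seq"]
    elif table_kind == "INDI":
        df["indi_drug_seq"] = df["drug_seq"]
    lines = [DELIMITER.join(cols)]
    if len(df):
        body = df[cols].map(_fmt)
        lines.extend(DELIMITER.join(row) for row in body.itertuples(index=False))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Quarterly file sets
# --------------------------------------------------------------------------

_QFILE_RE = re.compile(r"^(DEMO|DRUG|REAC|OUTC|THER|INDI)(\d{2})Q([1-4])\.txt$", re.I)


def quarter_label(yy: int, q: int) -> str:
    return f"{yy:02d}Q{q}"


def find_quarter_files(directory: str | Path) -> dict[str, dict[str, Path]]:
    """Scan a directory for ``<TABLE><YY>Q<N>.txt`` files.

    Returns ``{table_kind: {quarter_label: path}}``, quarters sorted.
    """
    directory = Path(directory)
    found: dict[str, dict[str, Path]] = {k: {} for k in TABLE_KINDS}
    for p in sorted(directory.iterdir()):
        m = _QFILE_RE.match(p.name)
        if m:
            kind = m.group(1).upper()
            found[kind][quarter_label(int(m.group(2)), int(m.group(3)))] = p
    return {k: dict(sorted(v.items())) for k, v in found.items()}


@dataclass
class FaersTables:
    """All six parsed tables for a set of quarters, plus the rejects log."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=_empty_rejects)

    def table(self, kind: str) -> pd.DataFrame:
        return getattr(self, kind.lower())

    @property
    def n_demo_rows(self) -> int:
        return len(self.demo)


def concat_quarters(per_quarter: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate one table kind across quarters, tagging provenance.

    *per_quarter* maps a quarter label to its parsed DataFrame.  All rows are
    retained (deduplication is a downstream step); each record carries its
    source quarter in a ``quarter`` column.

    Raises
    ------
    ValueError
        If the quarters disagree on columns for this table.
    """
    if not per_quarter:
        raise ValueError("need at least one quarter")
    frames = []
    ref_cols: list[str] | None = None
    for label, df in per_quarter.items():
        cols = [c for c in df.columns if c != "quarter"]
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise ValueError(
                f"inconsistent headers across quarters: {cols} vs {ref_cols}")
        tagged = df.copy()
        tagged["quarter"] = label
        frames.append(tagged)
    return pd.concat(frames, ignore_index=True)


def load_dataset(directory: str | Path) -> FaersTables:
    """Read every quarterly file in *directory* and concatenate by table."""
    files = find_quarter_files(directory)
    if not any(files[k] for k in TABLE_KINDS):
        raise FileNotFoundError(f"no quarterly FAERS files found in {directory}")
    out: dict[str, pd.DataFrame] = {}
    rejects: list[pd.DataFrame] = []
    for kind in TABLE_KINDS:
        per_quarter: dict[str, pd.DataFrame] = {}
        for label, path in files[kind].items():
            res = read_table(path, kind)
            per_quarter[label] = res.records
            if len(res.rejects):
                rejects.append(res.rejects)
        if per_quarter:
            out[kind.lower()] = concat_quarters(per_quarter)
        else:
            cols = PARSED_COLUMNS[kind] + ["quarter"]
            out[kind.lower()] = pd.DataFrame(columns=cols)
    rej = pd.concat(rejects, ignore_index=True) if rejects else _empty_rejects()
    return FaersTables(rejects=rej, **out)


def write_rejects(rejects: pd.DataFrame, path: str | Path) -> None:
    rejects.to_csv(path, sep="\t", index=False)
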