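"""End-to-end pipeline: ingest → dedup → cohort → signals → descriptives.

:func:`analyze_tables` is the in-memory core used by the CLI, the tests and
the acceptance harness; :func:`run` adds file I/O around it (reading a
quarterly directory or generating a synthetic one first) and writes every
output table plus a JSON run manifest with input checksums, a config echo
and per-stage record counts, so a run is auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortConfig, build_cohort
from .descriptives import (DemographicsSummary, TTOSummary, annual_distribution,
                           round_half_up, summarize_demographics, time_to_onset)
from .io import FaersTables, load_dataset, write_rejects
from .signals import (SignalCriteria, build_tables, compute_signals,
                      forest_plot_frame)
from .synthetic import DictionaryMap, SyntheticConfig, generate, make_dictionary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: exactly one of *input_dir* / *synthetic* is set."""

    cohort: CohortConfig
    output_dir: str | Path
    input_dir: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    dictionary_path: str | Path | None = None
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    ic_variance: str = "delta"
    ic_kappa: float = 1.66
    zero_correction: float = 0.0
    min_cases_for_report: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_dir / synthetic")
        if self.min_cases_for_report < 1:
            raise ValueError("min_cases_for_report must be >= 1")


@dataclass
class AnalysisResult:
    """Everything one analysis computes, in memory."""

    cohort: Cohort
    tables_pt: pd.DataFrame
    tables_soc: pd.DataFrame
    signals_pt: pd.DataFrame
    signals_soc: pd.DataFrame
    demographics: DemographicsSummary
    annual: pd.Series
    tto: TTOSummary
    stage_counts: dict[str, int]


def analyze_tables(tables: FaersTables, dictionary: DictionaryMap,
                   cohort_config: CohortConfig,
                   criteria: SignalCriteria = SignalCriteria(),
                   ic_variance: str = "delta", ic_kappa: float = 1.66,
                   zero_correction: float = 0.0) -> AnalysisResult:
    """Run the full analysis on already-parsed tables."""
    cohort = build_cohort(tables, cohort_config)
    counts = {
        "demo_rows_in": len(tables.demo),
        "rejected_rows": len(tables.rejects),
        "deduplicated_reports": cohort.n_universe,
        "cohort_reports": cohort.size,
        "cohort_event_pairs": len(cohort.reactions),
        "indication_pairs_removed": cohort.indication_exclusion.n_pairs_removed,
    }
    kw = dict(criteria=criteria, ic_variance=ic_variance, ic_kappa=ic_kappa,
              zero_correction=zero_correction)
    tab_pt = build_tables(cohort.reactions, cohort.comparator_reactions,
                          dictionary, level="PT")
    tab_soc = build_tables(cohort.reactions, cohort.comparator_reactions,
                           dictionary, level="SOC")
    sig_pt = compute_signals(tab_pt, **kw)
    sig_soc = compute_signals(tab_soc, **kw)
    counts["pt_events"] = len(sig_pt)
    counts["soc_events"] = len(sig_soc)
    counts["pt_consensus_signals"] = int(sig_pt["consensus"].sum())

    demographics = summarize_demographics(cohort)
    annual = annual_distribution(cohort)
    tto = time_to_onset(cohort, cohort_config)
    counts["tto_evaluable"] = tto.n_evaluable
    return AnalysisResult(cohort, tab_pt, tab_soc, sig_pt, sig_soc,
                          demographics, annual, tto, counts)


# --------------------------------------------------------------------------
# Report formatting
# --------------------------------------------------------------------------

def _fmt2(x: float) -> str:
    return "NA" if (x is None or np.isnan(x)) else f"{round_half_up(x, 2):.2f}"


def format_signal_report(stats: pd.DataFrame, min_cases: int = 3) -> pd.DataFrame:
    """Human-readable signal table (2-dp half-up), filtered to n >= min_cases."""
    keep = stats[stats["n"] >= min_cases].copy()
    out = pd.DataFrame({
        "event": keep["event"],
        "event_code": keep["event_code"],
        "level": keep["level"],
        "n": keep["n"],
        "ROR (95% CI)": [
            f"{_fmt2(r)} ({_fmt2(lo)} - {_fmt2(hi)})"
            for r, lo, hi in zip(keep["ror"], keep["ror_ci_low"],
                                 keep["ror_ci_high"])],
        "PRR (chi2)": [f"{_fmt2(p)} ({_fmt2(x)})"
                       for p, x in zip(keep["prr"], keep["chi2"])],
        "EBGM (EBGM05)": [f"{_fmt2(e)} ({_fmt2(e5)})"
                          for e, e5 in zip(keep["ebgm"], keep["ebgm05"])],
        "IC (IC025)": [f"{_fmt2(i)} ({_fmt2(i2)})"
                       for i, i2 in zip(keep["ic"], keep["ic025"])],
        "ror_pos": keep["ror_pos"], "prr_pos": keep["prr_pos"],
        "bcpnn_pos": keep["bcpnn_pos"], "mgps_pos": keep["mgps_pos"],
        "consensus": keep["consensus"],
    })
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# Orchestration with file I/O
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (Path,)):
            return str(obj)
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(config)


def run(config: RunConfig) -> dict:
    """Execute the whole pipeline and write all outputs plus the manifest.

    Returns the manifest dict.  Raises on any stage failure (the CLI maps
    that to a nonzero exit code).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        data_dir = outdir / "synthetic_data"
        logger.info("generating synthetic dataset (n=%d, seed=%d)",
                    config.synthetic.n_reports, config.synthetic.seed)
        paths, truth = generate(config.synthetic, data_dir)
        input_files = paths + [data_dir / "meddra_like.txt"]
        dictionary = make_dictionary(config.synthetic)
    else:
        data_dir = Path(config.input_dir)
        input_files = sorted(p for p in data_dir.iterdir() if p.is_file())
        if config.dictionary_path is None:
            raise ValueError("dictionary_path is required with input_dir")
        dictionary = DictionaryMap.load(config.dictionary_path)

    tables = load_dataset(data_dir)
    result = analyze_tables(
        tables, dictionary, config.cohort, criteria=config.criteria,
        ic_variance=config.ic_variance, ic_kappa=config.ic_kappa,
        zero_correction=config.zero_correction)

    # --- outputs ----------------------------------------------------------
    float_fmt = "%.10g"
    result.cohort.demo.to_csv(outdir / "cohort_reports.tsv", sep="\t",
                              index=False)
    write_rejects(tables.rejects, outdir / "rejects.tsv")
    for level, tab, sig in (("pt", result.tables_pt, result.signals_pt),
                            ("soc", result.tables_soc, result.signals_soc)):
        tab.to_csv(outdir / f"contingency_{level}.tsv", sep="\t", index=False)
        sig.to_csv(outdir / f"signals_{level}.tsv", sep="\t", index=False,
                   float_format=float_fmt)
        format_signal_report(sig, config.min_cases_for_report).to_csv(
            outdir / f"report_{level}.tsv", sep="\t", index=False)
    forest_plot_frame(
        result.signals_pt[result.signals_pt["n"] >= config.min_cases_for_report]
    ).to_csv(outdir / "forest_pt.tsv", sep="\t", index=False,
             float_format=float_fmt)
    result.demographics.to_frame().to_csv(outdir / "demographics.csv",
                                          index=False)
    result.annual.to_csv(outdir / "annual_counts.csv")
    tto = result.tto
    pd.DataFrame([{
        "n_evaluable": tto.n_evaluable, "n_excluded": tto.n_excluded,
        "median_days": tto.median_days, "q1": tto.q1, "q3": tto.q3,
        "frac_within_30d": tto.frac_within_30d,
    }]).to_csv(outdir / "tto_summary.csv", index=False, float_format=float_fmt)
    (tto.histogram if not tto.is_empty
     else pd.DataFrame(columns=["interval", "count"])
     ).to_csv(outdir / "tto_histogram.csv", index=False)

    manifest = {
        "faersig_version": __version__,
        "seed": config.seed if config.seed is not None
                else (config.synthetic.seed if config.synthetic else None),
        "config": _config_echo(config),
        "inputs": {str(p): _sha256(Path(p)) for p in input_files},
        "stage_counts": result.stage_counts,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    logger.info("run complete: %s", result.stage_counts)
    return manifest
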