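import pandas as pd
import pytest

from faersig import (CohortConfig, SyntheticConfig, analyze_tables, generate,
                     generate_frames, make_dictionary)
from faersig.io import FaersTables, PARSED_COLUMNS, TABLE_KINDS


def small_config(**overrides) -> SyntheticConfig:
    defaults = dict(
        n_reports=4000,
        n_quarters=8,
        seed=11,
        signal_spec={"nausea": 8.0, "insomnia": 5.0},
        duplicate_fraction=0.10,
        duplicate_tie_fraction=0.30,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def frames_to_tables(frames: dict[str, pd.DataFrame]) -> FaersTables:
    return FaersTables(**frames)


def tables_from_rows(**rows_by_kind) -> FaersTables:
    """Build a FaersTables from lists of row dicts (missing kinds empty)."""
    frames = {}
    for kind in TABLE_KINDS:
        key = kind.lower()
        rows = rows_by_kind.get(key, [])
        cols = PARSED_COLUMNS[kind] + ["quarter"]
        if rows:
            df = pd.DataFrame(rows)
            for c in cols:
                if c not in df.columns:
                    if c in ("age_yr", "wt_kg"):
                        df[c] = float("nan")
                    elif c in ("sex", "occp_cod", "reporter_country"):
                        df[c] = pd.NA
                    else:
                        df[c] = ""
            frames[key] = df[cols]
        else:
            frames[key] = pd.DataFrame(columns=cols)
    return FaersTables(**frames)


@pytest.fixture(scope="session")
def base_config():
    return small_config()


@pytest.fixture(scope="session")
def base_frames(base_config):
    return generate_frames(base_config)


@pytest.fixture(scope="session")
def base_analysis(base_config, base_frames):
    frames, _truth = base_frames
    dictionary = make_dictionary(base_config)
    cohort_config = CohortConfig(target_names=base_config.target_drug_names)
    return analyze_tables(frames_to_tables(frames), dictionary, cohort_config)


@pytest.fixture(scope="session")
def base_dataset_dir(tmp_path_factory, base_config):
    outdir = tmp_path_factory.mktemp("synthetic")
    paths, truth = generate(base_config, outdir)
    return outdir, truth
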