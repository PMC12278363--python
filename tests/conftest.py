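"""Shared fixtures: synthetic populations at several scales.

The expensive artefacts (the 50,000-case recovery benchmark and its full
pipeline run) are session-scoped so the recovery, calibration and
end-to-end tests share one computation.
"""

from __future__ import annotations

import pandas as pd
import pytest

from pvsignal.io import EventDefinition
from pvsignal.pipeline import RunConfig, run_pipeline
from pvsignal.synthetic import (DrugSpec, GeneratorConfig, generate_reports,
                                simulate_cases, standard_recovery_config,
                                write_tables)

TARGET_TERMS = frozenset({
    "Hypothyroidism", "Blood thyroid stimulating hormone increased"})


@pytest.fixture(scope="session")
def event_def() -> EventDefinition:
    return EventDefinition("thyroid_dysfunction", TARGET_TERMS)


@pytest.fixture(scope="session")
def standard_config() -> GeneratorConfig:
    return standard_recovery_config()


@pytest.fixture(scope="session")
def standard_sim(standard_config):
    """Case-level ground truth of the recovery benchmark (no file round trip)."""
    return simulate_cases(standard_config)


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory, standard_config, event_def):
    """Full pipeline run on the recovery benchmark; returns (outdir, report)."""
    outdir = tmp_path_factory.mktemp("standard_run")
    config = RunConfig(outdir=outdir, events=[event_def],
                       synth=standard_config, seed=standard_config.seed)
    report = run_pipeline(config)
    return outdir, report


@pytest.fixture(scope="session")
def small_quarter(tmp_path_factory):
    """A written 1,000-case quarter with 20% duplicate versions."""
    config = GeneratorConfig(
        n_cases=1000,
        drug_catalog=[DrugSpec("drugA", 0.10, 6.0),
                      DrugSpec("drugB", 0.05, 1.0)],
        baseline_event_prob=0.20, sex_effect_or=0.7,
        duplicate_rate=0.20, seed=11)
    tables = generate_reports(config)
    outdir = tmp_path_factory.mktemp("small_quarter")
    write_tables(tables, outdir)
    return outdir, tables, config


def pairs_from_exposures(exposures: pd.DataFrame) -> pd.DataFrame:
    """(caseid, drugname) pairs from a boolean case x drug matrix."""
    stacked = exposures.stack()
    pairs = stacked[stacked].reset_index()
    pairs.columns = ["caseid", "drugname", "_"]
    return pairs[["caseid", "drugname"]]
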