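"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

import yaml

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
TABLES_DIR = SCRATCH / "tables"


def load_config():
    with open(Path(__file__).parent / "config.yaml") as fh:
        return yaml.safe_load(fh)


def load_tables():
    from hypoburden.pipeline import read_tables
    if not TABLES_DIR.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    return read_tables(TABLES_DIR)


def load_cohort_frames():
    """Cohort, support intervals, exposures and outcomes from the raw tables."""
    from hypoburden.cohort import select_cohort
    from hypoburden.pipeline import attribute_outcomes, compute_exposures
    tables = load_tables()
    cohort, ledger, support = select_cohort(
        tables["stays"], tables["infusions"], tables["map_readings"],
        tables["transfusions"], tables["codes"])
    exposures = compute_exposures(cohort, tables["map_readings"],
                                  tables["infusions"], tables["baselines"], support)
    outcomes = attribute_outcomes(cohort, tables["deaths"])
    return tables, cohort, ledger, exposures, outcomes
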