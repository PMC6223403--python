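"""Generate the synthetic ICU cohort (raw MIMIC-like tables + planted truth).

Writes the seven raw event tables and sim_truth.csv under scratch/analysis/
tables/ for the downstream scripts, and prints the scale of what was made.
"""

from _common import TABLES_DIR, load_config

from hypoburden.pipeline import write_tables
from hypoburden.synthetic import SimConfig, simulate_cohort


def main():
    cfg = load_config()
    sim = SimConfig(n_stays=cfg["n_stays"], seed=cfg["seed"])
    tables, truth = simulate_cohort(sim)
    write_tables(tables, TABLES_DIR)
    truth.to_csv(TABLES_DIR / "sim_truth.csv", index=False, float_format="%.10g")
    print(f"simulated {len(tables['stays'])} ICU stays "
          f"({len(tables['map_readings'])} MAP readings, "
          f"{len(tables['infusions'])} infusion records, "
          f"{int(truth['icu_death'].sum())} planted ICU deaths) -> {TABLES_DIR}")


if __name__ == "__main__":
    main()
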