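"""Apply the distributive-shock inclusion/exclusion rules; write the ledger.

Prints the cohort flowchart (initial N, per-rule removals, final N) and
writes results/exclusion_ledger.csv.
"""

from _common import RESULTS, load_cohort_frames


def main():
    _, cohort, ledger, _, _ = load_cohort_frames()
    RESULTS.mkdir(parents=True, exist_ok=True)
    ledger.to_frame().to_csv(RESULTS / "exclusion_ledger.csv", index=False)
    print(ledger.flowchart())
    print(f"\ncohort written: {len(cohort)} stays; "
          f"ledger -> {RESULTS / 'exclusion_ledger.csv'}")


if __name__ == "__main__":
    main()
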