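"""Hypotension burden descriptives: prevalence by threshold x minimum duration.

Computes each stay's longest continuous below-threshold episode during
vasopressor support at 55/60/65/75/80 mmHg, then tabulates the share of the
cohort ever below and continuously below for >=2/4/8/12/16/20 h, overall and
stratified by the pre-/post-mid-2008 era. Writes one prevalence CSV per stratum.
"""

from _common import RESULTS, load_cohort_frames

from hypoburden import estimands as es


def main():
    _, cohort, _, exposures, _ = load_cohort_frames()
    era = cohort.set_index("stay_id")["era"].loc[exposures["stay_id"]]
    strata = es.stratify_era(exposures, era.reset_index(drop=True))
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name, tab in strata.items():
        if tab is None:
            continue
        path = RESULTS / f"prevalence_{name}.csv"
        tab.round(1).to_csv(path)
        print(f"\n== prevalence (%), stratum: {name} (n={len(exposures) if name == 'all' else (era == name).sum()}) ==")
        print(tab.round(1).to_string())
    print(f"\nwritten to {RESULTS}/prevalence_*.csv")


if __name__ == "__main__":
    main()
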