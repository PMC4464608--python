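"""Kaplan-Meier curves for time to first cessation and first relapse.

Reads the imputed episodes, estimates the two first-event gap-time
distributions with Greenwood 95% bands, and prints the 12-month /
5-year probabilities and median (IQR) in years.
"""

from pathlib import Path

import pandas as pd

from cessrel import lifegrid, survival
from cessrel.bands import CESSATION, RELAPSE

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_dir = ROOT / "cohort"
    eps_by = lifegrid.episodes_from_frame(pd.read_csv(cohort_dir / "episodes.csv"))
    for process in (CESSATION, RELAPSE):
        t, d = survival.first_event_dataset(eps_by, process)
        curve = survival.kaplan_meier(t, d)
        survival.write_km_outputs(curve, str(cohort_dir / f"km_{process}.csv"),
                                  str(cohort_dir / f"km_{process}.json"))
        s = survival.km_summary(curve)
        med = s["median_years"]
        iqr = (s["iqr_low_years"], s["iqr_high_years"])
        print(f"{process}: n={len(t)}, events={int(d.sum())}; "
              f"P(event<=12mo)={s['prob_event_12mo']:.2f}, "
              f"P(event<=5y)={s['prob_event_5yr']:.2f}; "
              f"median {med if med is None else round(med, 2)} y, "
              f"IQR ({iqr[0] if iqr[0] is None else round(iqr[0], 2)}, "
              f"{iqr[1] if iqr[1] is None else round(iqr[1], 2)})")


if __name__ == "__main__":
    main()
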