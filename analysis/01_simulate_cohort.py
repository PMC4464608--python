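"""Simulate the synthetic cohort and write its raw tables.

Generates 405 injecting careers under the default scenario (piecewise
exponential cessation/relapse hazards, default covariate effects,
frailty variances 0.90/0.57), coarsens them to annual life grids and
writes lifegrid/covariates/ost/true-episode CSVs under results/cohort/.
"""

import sys
from pathlib import Path

import cessrel as cr
from cessrel import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20150601


def main(seed: int = SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = cr.CareerParams()
    params.to_yaml(str(OUT / "scenario.yaml"))
    cohort = simulate.simulate_cohort(405, params, seed)
    tables = simulate.careers_to_tables(cohort, params)
    for name, df in tables.items():
        df.to_csv(OUT / f"{name}.csv", index=False)
    n_eps = len(tables["true_episodes"])
    print(f"simulated 405 careers (seed {seed}): {n_eps} true episodes, "
          f"{len(tables['lifegrid'])} life-grid year-rows -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
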