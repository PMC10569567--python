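"""Regress stance-phase outcomes on femoral geometry.

Loads the outcome table produced by 03_run_study.py (re-running the study
if it is absent) and fits, for every stance-mean outcome, the multiple
regression outcome ~ intercept + AVA + NSA.  Prints R^2, the overall F
test and per-predictor significance at alpha = 0.05, and writes the
summary to results/regressions.csv.

Run from the repository root:  python analysis/04_fit_regressions.py
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from femgait.study import (StudyConfig, fit_geometry_regression,
                           outcome_columns, regression_table, run_study)

ROOT = Path(__file__).resolve().parents[1]
OUTCOMES = ROOT / "results/study/outcomes.csv"
OUT = ROOT / "results/regressions.csv"


def main():
    if OUTCOMES.exists():
        rows = pd.read_csv(OUTCOMES)
        print(f"loaded {len(rows)} outcome rows from {OUTCOMES}")
    else:
        print("outcome table not found; running the study")
        rows = run_study(StudyConfig(seed=0)).rows

    regressions = []
    print(f"\n{'outcome':24s} {'R^2':>6s} {'F p':>10s}  significant "
          f"predictors (alpha 0.05)")
    for col in outcome_columns(rows):
        r = fit_geometry_regression(rows, col)
        regressions.append(r)
        sig = [k for k, v in r.significant.items()
               if v and k != "intercept"]
        print(f"{col:24s} {r.r_squared:6.2f} {r.f_pvalue:10.2e}  "
              f"{', '.join(sig) or '-'}")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    regression_table(regressions).to_csv(OUT, index=False)
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
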