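"""Synthesize the shared gait trial.

Generates the one-cycle healthy-adult walking trial every model of the
sweep consumes (73.1 kg, 1.71 m, 1.41 m/s, stance 60% of cycle), reports
its sanity numbers (stance-mean vertical GRF, angle ranges) and writes the
motion table plus an event sidecar under results/gait/.

Run from the repository root:  python analysis/01_synthesize_gait.py
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from femgait.gait import normalize_to_cycle, synthesize_trial
from femgait.motionio import write_motion

OUT = Path(__file__).resolve().parents[1] / "results/gait"


def main():
    trial = synthesize_trial(seed=0)
    cyc = normalize_to_cycle(trial)
    bw = trial.subject_mass * 9.81
    stance = trial.time < trial.foot_off
    print(f"cycle duration {trial.time[-1]:.3f} s, "
          f"stance fraction {cyc.stance_fraction:.2f}")
    print(f"stance-mean vertical GRF {trial.grf[stance, 1].mean():.0f} N "
          f"({trial.grf[stance, 1].mean() / bw:.2f} BW); "
          f"peak {trial.grf[:, 1].max() / bw:.2f} BW")
    for dof, w in trial.angles.items():
        print(f"  {dof:20s} range [{w.min():6.1f}, {w.max():6.1f}] deg")

    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({"time": trial.time, **trial.angles,
                          "grf_x": trial.grf[:, 0], "grf_y": trial.grf[:, 1],
                          "grf_z": trial.grf[:, 2],
                          "cop_x": trial.cop[:, 0], "cop_y": trial.cop[:, 1],
                          "cop_z": trial.cop[:, 2]})
    write_motion(OUT / "trial.sto", table, dialect="sto_mot", name="trial")
    (OUT / "events.json").write_text(json.dumps(
        {"foot_strike": trial.foot_strike, "foot_off": trial.foot_off,
         "next_foot_strike": trial.next_foot_strike,
         "subject_mass": trial.subject_mass,
         "walking_velocity": trial.walking_velocity}, indent=1))
    print(f"wrote {OUT / 'trial.sto'} and events.json")


if __name__ == "__main__":
    main()
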