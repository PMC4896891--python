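#!/usr/bin/env python
"""Occupancy trajectories and turning points from the packaged rate tables.

For each preset intensity: simulate the full light-on/light-off protocol,
export all four occupancy traces, and tabulate the turning points of each
state in both phases (off-phase times measured from light-off).  Writes to
results/occupancies/.
"""

import json
from pathlib import Path

from rckinetics import (DARK_ADAPTED, PRESET_INTENSITIES, preset_rates,
                        protocol_turning_points, simulate_protocol)

OUT = Path(__file__).resolve().parent.parent / "results" / "occupancies"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    summary = {}
    for intensity in PRESET_INTENSITIES:
        ox = preset_rates("oxidation", intensity)
        red = preset_rates("reduction", intensity)
        traj = simulate_protocol(ox, red, DARK_ADAPTED, 90.0, 300.0)
        traj.to_csv(OUT / f"occupancies_I{intensity:g}.csv")
        tps = {f"x{s}": protocol_turning_points(traj, s, ox, red)
               for s in (1, 2, 3, 4)}
        summary[f"{intensity:g}"] = tps
        for state, phases in tps.items():
            for phase, pts in phases.items():
                for t, kind in pts:
                    print(f"I={intensity:g} {state} [{phase}] "
                          f"{kind} at {t:.2f} s")
    with open(OUT / "turning_points.json", "w") as fh:
        json.dump(summary, fh, indent=1)


if __name__ == "__main__":
    main()
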