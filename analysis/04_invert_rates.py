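#!/usr/bin/env python
"""Inverse problem on the simulated noiseless traces: recover rate tables.

For each preset intensity: fit the oxidation phase from the dark-adapted
start, hand the fitted light-off state to the reduction fit, and collect
both fitted rate sets into a rates CSV in the printed column order.
Writes to results/inverse/.  Runtime: up to ~1 h — reduction fits at the
higher intensities descend a nearly flat valley (the third dark mode
carries no measurable amplitude there) and run into the cycle caps.
"""

import json
import time
from pathlib import Path

import numpy as np

from rckinetics import (DARK_ADAPTED, FitTrace, InverseConfig, KineticTrace,
                        OccupancyState, PRESET_INTENSITIES, preset_rates,
                        rates_table, solve_occupancies)
from rckinetics import fit_oxidation, fit_reduction

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "inverse"
OUT.mkdir(parents=True, exist_ok=True)

CFG = InverseConfig(n_starts=1)   # constructive mode-matched start


def main() -> None:
    records = []
    for intensity in PRESET_INTENSITIES:
        path = ROOT / "traces" / f"trace_I{intensity:g}_noiseless.csv"
        kt = KineticTrace.from_csv(path)
        t_on, v_on = kt.phase_slice("on")
        t_off, v_off = kt.phase_slice("off")

        t0 = time.time()
        ox_res = fit_oxidation(FitTrace(t_on, v_on), CFG)
        ic = OccupancyState.from_array(
            solve_occupancies(ox_res.rates, DARK_ADAPTED,
                              np.array([0.0, t_on[-1]])).states[-1])
        red_res = fit_reduction(FitTrace(t_off - t_on[-1], v_off), ic, CFG)
        print(f"I={intensity:g}: ox disp={ox_res.dispersion:.2e} "
              f"red disp={red_res.dispersion:.2e} "
              f"({time.time() - t0:.0f} s)")

        for process, res in (("oxidation", ox_res), ("reduction", red_res)):
            records.append({"intensity": intensity, "process": process,
                            "rates": res.rates.to_dict(),
                            "dispersion": res.dispersion})
            with open(OUT / f"inverse_{process}_I{intensity:g}.json",
                      "w") as fh:
                json.dump(res.to_json(), fh, indent=1)
    rates_table(records, OUT / "rates.csv")


if __name__ == "__main__":
    main()
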