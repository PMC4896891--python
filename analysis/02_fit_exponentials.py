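#!/usr/bin/env python
"""Multi-exponential decomposition of each simulated trace, per phase.

Reads results/traces/ (run 01_simulate_traces.py first) and writes one
model JSON per (intensity, noise level, phase) plus a summary CSV to
results/expfits/.
"""

from pathlib import Path

import pandas as pd

from rckinetics import FitTrace, KineticTrace, fit_multiexp

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "expfits"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    rows = []
    for path in sorted((ROOT / "traces").glob("trace_*.csv")):
        kt = KineticTrace.from_csv(path)
        for phase in ("on", "off"):
            t, v = kt.phase_slice(phase)
            if t.size < 12:
                continue
            model = fit_multiexp(FitTrace(t - t[0], v), max_terms=4)
            out = OUT / f"{path.stem}_{phase}.json"
            model.to_json(out)
            rows.append({"trace": path.stem, "phase": phase, "n": model.n,
                         "rmse": model.rmse,
                         "decrements": sorted(map(float, model.decrements),
                                              reverse=True)})
            print(f"{path.stem} [{phase}]: n={model.n} rmse={model.rmse:.2e}")
    pd.DataFrame(rows).to_csv(OUT / "summary.csv", index=False)


if __name__ == "__main__":
    main()
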