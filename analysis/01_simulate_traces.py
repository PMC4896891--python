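#!/usr/bin/env python
"""Simulate the study's measurement grid: one trace per preset intensity.

Writes noiseless and instrument-noise traces (90 s light on, 210 s dark,
0.01 s sampling) to results/traces/.
"""

from pathlib import Path

from rckinetics import (ExcitationProtocol, NoiseSpec, PRESET_INTENSITIES,
                        generate_trace, preset_rates)

OUT = Path(__file__).resolve().parent.parent / "results" / "traces"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    for intensity in PRESET_INTENSITIES:
        ox = preset_rates("oxidation", intensity)
        red = preset_rates("reduction", intensity)
        protocol = ExcitationProtocol(intensity, t_on=90.0, t_total=300.0)
        for label, sd in (("noiseless", 0.0), ("noisy", 5e-4)):
            trace = generate_trace(protocol, ox, red, NoiseSpec(sd, seed=0))
            path = OUT / f"trace_I{intensity:g}_{label}.csv"
            trace.to_csv(path)
            print(f"wrote {path} ({trace.times.size} samples)")


if __name__ == "__main__":
    main()
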