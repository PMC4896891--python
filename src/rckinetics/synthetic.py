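"""Instrument-like synthetic kinetic traces and published rate presets.

Emulates the absorption-kinetics measurement: normalized absorbance (= the
first-state occupancy x1, 1 in darkness) sampled at the instrument
resolution of 0.01 s, with iid Gaussian noise at the ~5e-4 per-sample
uncertainty of the spectrometer, under a light-on / light-off protocol with
excitation intensities of 0.2-6 mW/cm^2 and exposures of 10-100 s.

The published rate-constant tables for the oxidation (light-on, 12 rates)
and reduction (dark, 9 rates) processes at exposure 90 s are shipped as JSON
fixtures and exposed through :func:`preset_rates`.  The reduction presets
are keyed by the intensity of the *preceding* illumination.

Not modelled (instrument features absent from the generator): baseline
drift, bleaching-amplitude calibration, shot or 1/f noise components, and
measuring-pulse electronics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .model import DARK_ADAPTED, RateSet, Trajectory, simulate_protocol

#: Intensities (mW/cm^2) with published rate sets.
PRESET_INTENSITIES = (0.2, 0.5, 1.0, 2.0, 4.0, 6.0)

#: SHA-256 of the packaged fixture files; edits break the suite.
FIXTURE_SHA256 = {
    "oxidation_rates.json":
        "2e2c2cf0425cd96bcc4c541736781ec8491e0ae174afa48ea89468ece6b17d87",
    "reduction_rates.json":
        "76b45e7e81500d74b1b968dbb98b7c6ed88d56a55f9319c1a2156392df811dbe",
}


@dataclass(frozen=True)
class ExcitationProtocol:
    """Light-on/light-off excitation protocol of one measurement."""

    intensity: float            # mW/cm^2
    t_on: float                 # illumination duration, s
    t_total: float              # full record length, s
    dt: float = 0.01            # sampling resolution, s

    def __post_init__(self) -> None:
        if not (0 < self.t_on < self.t_total):
            raise ValueError("need 0 < t_on < t_total")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive iid Gaussian measurement noise; the seed is mandatory."""

    sd: float = 5e-4            # per-sample sd, signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class KineticTrace:
    """Sampled signal (normalized absorbance = x1) with phase labels."""

    times: np.ndarray
    signal: np.ndarray
    phases: np.ndarray
    meta: dict | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "signal": self.signal,
                             "phase": self.phases})

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.15g")
        if sidecar and self.meta is not None:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(self.meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "KineticTrace":
        df = pd.read_csv(path)
        phases = (df["phase"].to_numpy() if "phase" in df
                  else np.full(len(df), "on", dtype=object))
        return cls(df["time_s"].to_numpy(), df["signal"].to_numpy(), phases)

    def phase_slice(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.phases == phase
        return self.times[m], self.signal[m]


def _fixture_text(name: str) -> str:
    return resources.files("rckinetics.fixtures").joinpath(name).read_text()


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of the packaged fixture files as currently installed."""
    return {name: hashlib.sha256(_fixture_text(name).encode()).hexdigest()
            for name in FIXTURE_SHA256}


def preset_rates(process: str, intensity: float) -> RateSet:
    """Published rate constants for a process at a preset intensity.

    ``process`` is ``"oxidation"`` (light on) or ``"reduction"`` (dark
    phase after the stated illumination).  Values are returned verbatim
    from the packaged tables (exposure time 90 s).
    """
    if process not in ("oxidation", "reduction"):
        raise ValueError("process must be 'oxidation' or 'reduction'")
    table = json.loads(_fixture_text(f"{process}_rates.json"))
    for key, row in table.items():
        if abs(float(key) - float(intensity)) < 1e-9:
            return RateSet.from_dict(row)
    raise ValueError(
        f"no preset for intensity {intensity}; available: "
        f"{sorted(float(k) for k in table)}"
    )


def rates_from_intensity(intensity: float, base_rates: RateSet,
                         sigma: float) -> RateSet:
    """Scale the light-driven pumping rate with intensity: k12 = sigma * I.

    Convenience constructor using the observed near-proportionality of k12
    to excitation intensity; the published tables take precedence whenever a
    preset intensity is wanted (the printed k12 grows super-linearly at the
    top of the range).
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return base_rates.replace(k12=sigma * intensity)


def calibrate_sigma() -> float:
    """Least-squares slope of the published (I, k12) oxidation pairs."""
    table = json.loads(_fixture_text("oxidation_rates.json"))
    I = np.array([float(k) for k in table])
    k12 = np.array([table[k]["k12"] for k in table])
    return float(I @ k12 / (I @ I))


def generate_trace(protocol: ExcitationProtocol, ox: RateSet, red: RateSet,
                   noise: NoiseSpec) -> KineticTrace:
    """Simulate one measurement: protocol, observable x1, Gaussian noise."""
    traj = simulate_protocol(ox, red, DARK_ADAPTED, protocol.t_on,
                             protocol.t_total, protocol.dt)
    rng = np.random.default_rng(noise.seed)
    signal = traj.x1.copy()
    if noise.sd > 0:
        signal = signal + rng.normal(0.0, noise.sd, signal.size)
    meta = {
        "protocol": {"intensity_mw_cm2": protocol.intensity,
                     "t_on_s": protocol.t_on, "t_total_s": protocol.t_total,
                     "dt_s": protocol.dt},
        "rates_oxidation": ox.to_dict(),
        "rates_reduction": red.to_dict(),
        "noise_sd": noise.sd,
        "seed": noise.seed,
    }
    return KineticTrace(traj.times, signal, traj.phases, meta)


def double_pulse_trace(rates_on: RateSet, rates_off: RateSet,
                       noise: NoiseSpec, pulse_s: float = 100.0,
                       interval_s: float = 500.0, tail_s: float = 500.0,
                       dt: float = 0.01) -> KineticTrace:
    """Two successive light pulses separated by a dark interval, then a tail.

    Occupancies carry over continuously across all four segments.  With a
    dark interval much longer than the slowest relaxation time, the response
    to the second pulse reproduces the first (the pulses are independent);
    ``interval_s = 0`` degenerates to a single pulse of twice the length.
    """
    if interval_s < 0:
        raise ValueError("interval_s must be >= 0")
    segments = [(rates_on, pulse_s, "on")]
    if interval_s > 0:
        segments.append((rates_off, interval_s, "off"))
    segments += [(rates_on, pulse_s, "on"), (rates_off, tail_s, "off")]

    from .model import OccupancyState, solve_occupancies
    x = DARK_ADAPTED
    t0 = 0.0
    all_t, all_x1, all_ph = [], [], []
    for rates, dur, phase in segments:
        local = np.arange(0.0, dur + dt / 2, dt)
        traj = solve_occupancies(rates, x, local, phase=phase)
        sl = slice(1, None) if all_t else slice(None)
        all_t.append(t0 + local[sl])
        all_x1.append(traj.x1[sl])
        all_ph.append(traj.phases[sl])
        x = OccupancyState.from_array(traj.states[-1])
        t0 += dur
    times = np.concatenate(all_t)
    signal = np.concatenate(all_x1)
    phases = np.concatenate(all_ph)
    rng = np.random.default_rng(noise.seed)
    if noise.sd > 0:
        signal = signal + rng.normal(0.0, noise.sd, signal.size)
    meta = {"pulse_s": pulse_s, "interval_s": interval_s, "tail_s": tail_s,
            "dt_s": dt, "noise_sd": noise.sd, "seed": noise.seed,
            "rates_on": rates_on.to_dict(), "rates_off": rates_off.to_dict()}
    return KineticTrace(times, signal, phases, meta)
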