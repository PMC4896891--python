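"""Unit tests for the synthetic-trace generator and rate presets."""

import json

import numpy as np
import pytest

from rckinetics import (
    DARK_ADAPTED,
    PRESET_INTENSITIES,
    ExcitationProtocol,
    KineticTrace,
    NoiseSpec,
    RateSet,
    calibrate_sigma,
    decrements,
    double_pulse_trace,
    fixture_checksums,
    generate_trace,
    preset_rates,
    rates_from_intensity,
    simulate_protocol,
)
from rckinetics.synthetic import FIXTURE_SHA256


class TestFixtures:
    def test_checksums_pinned(self):
        """The packaged rate tables must not drift from the pinned hashes."""
        assert fixture_checksums() == FIXTURE_SHA256

    def test_all_preset_intensities_load(self):
        for I in PRESET_INTENSITIES:
            assert isinstance(preset_rates("oxidation", I), RateSet)
            assert isinstance(preset_rates("reduction", I), RateSet)

    def test_reduction_presets_are_dark(self):
        for I in PRESET_INTENSITIES:
            assert preset_rates("reduction", I).is_dark

    def test_oxidation_k12_increases_with_intensity(self):
        k12 = [preset_rates("oxidation", I).k12 for I in PRESET_INTENSITIES]
        assert np.all(np.diff(k12) > 0)

    def test_unknown_intensity_rejected(self):
        with pytest.raises(ValueError, match="no preset"):
            preset_rates("oxidation", 3.3)

    def test_unknown_process_rejected(self):
        with pytest.raises(ValueError):
            preset_rates("bleaching", 0.2)


class TestIntensityScaling:
    def test_k12_proportional(self):
        base = preset_rates("oxidation", 0.2)
        rs = rates_from_intensity(1.5, base, sigma=0.04)
        assert rs.k12 == pytest.approx(0.06)
        assert rs.k21 == base.k21

    def test_validation(self):
        base = RateSet(k21=1.0)
        with pytest.raises(ValueError):
            rates_from_intensity(-1.0, base, 0.1)
        with pytest.raises(ValueError):
            rates_from_intensity(1.0, base, 0.0)

    def test_calibrated_sigma_predicts_presets(self):
        """The fitted slope tracks the printed k12 values (Fig 9-style
        near-proportionality; the printed values bend at high intensity)."""
        sigma = calibrate_sigma()
        assert sigma > 0
        for I in PRESET_INTENSITIES:
            k12 = preset_rates("oxidation", I).k12
            assert 0.3 < (sigma * I) / k12 < 3.0


class TestProtocolValidation:
    def test_bad_times(self):
        with pytest.raises(ValueError):
            ExcitationProtocol(0.2, t_on=10.0, t_total=5.0)

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            ExcitationProtocol(0.2, t_on=1.0, t_total=2.0, dt=0.0)

    def test_negative_noise(self):
        with pytest.raises(ValueError):
            NoiseSpec(sd=-1e-4)


class TestGenerateTrace:
    def setup_method(self):
        self.ox = preset_rates("oxidation", 0.2)
        self.red = preset_rates("reduction", 0.2)
        self.protocol = ExcitationProtocol(0.2, t_on=10.0, t_total=30.0, dt=0.05)

    def test_noiseless_equals_model(self):
        kt = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(0.0, 0))
        traj = simulate_protocol(self.ox, self.red, DARK_ADAPTED, 10.0, 30.0,
                                 dt=0.05)
        assert np.allclose(kt.signal, traj.x1, atol=1e-14)

    def test_seed_determinism(self):
        a = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(5e-4, 42))
        b = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(5e-4, 42))
        c = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(5e-4, 43))
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_noise_magnitude(self):
        kt = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(5e-4, 0))
        clean = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(0.0, 0))
        sd = np.std(kt.signal - clean.signal)
        assert 0.8 * 5e-4 < sd < 1.2 * 5e-4

    def test_meta_records_provenance(self):
        kt = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(5e-4, 7))
        assert kt.meta["seed"] == 7
        assert kt.meta["noise_sd"] == 5e-4
        assert kt.meta["rates_oxidation"]["k12"] == self.ox.k12

    def test_csv_round_trip_with_sidecar(self, tmp_path):
        kt = generate_trace(self.protocol, self.ox, self.red, NoiseSpec(5e-4, 0))
        path = tmp_path / "trace.csv"
        kt.to_csv(path)
        back = KineticTrace.from_csv(path)
        assert np.allclose(back.signal, kt.signal, rtol=1e-14, atol=1e-18)
        assert np.array_equal(back.phases, kt.phases)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        assert meta["protocol"]["intensity_mw_cm2"] == 0.2
        with open(path) as fh:
            assert fh.readline().strip() == "time_s,signal,phase"


class TestDoublePulse:
    def test_pulses_independent_after_long_dark_interval(self):
        """With full dark recovery the second pulse repeats the first."""
        ox = preset_rates("oxidation", 0.2)
        red = preset_rates("reduction", 0.2)
        # 25 slowest-mode dark time constants guarantee recovery below 1e-10
        d = np.abs(np.real(decrements(red)))
        interval = 25.0 / np.min(d[d > 1e-9])
        kt = double_pulse_trace(ox, red, NoiseSpec(0.0, 0), pulse_s=50.0,
                                interval_s=interval, tail_s=50.0, dt=0.05)
        on = kt.phases == "on"
        t_on = kt.times[on]
        # the two on-phase segments, by time gap
        split = int(np.argmax(np.diff(t_on) > 1.0)) + 1
        first, second = kt.signal[on][:split], kt.signal[on][split:]
        # the boundary sample at the second onset belongs to the preceding
        # dark segment, so the second pulse starts one dt into the kinetics
        first = first[1:]
        n = min(first.size, second.size)
        assert np.max(np.abs(first[:n] - second[:n])) < 1e-6

    def test_continuity_across_segments(self):
        """No jumps at segment boundaries: steps bounded by the rate-limited
        slope (max total outflow ~0.5 s^-1 at this intensity)."""
        ox = preset_rates("oxidation", 0.2)
        red = preset_rates("reduction", 0.2)
        kt = double_pulse_trace(ox, red, NoiseSpec(0.0, 0), pulse_s=20.0,
                                interval_s=20.0, tail_s=20.0, dt=0.05)
        assert np.max(np.abs(np.diff(kt.signal))) < 0.05

    def test_negative_interval_rejected(self):
        ox = preset_rates("oxidation", 0.2)
        red = preset_rates("reduction", 0.2)
        with pytest.raises(ValueError):
            double_pulse_trace(ox, red, NoiseSpec(0.0, 0), interval_s=-1.0)
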