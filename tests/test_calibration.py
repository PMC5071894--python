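import numpy as np
import pytest

from aeroscatter.calibration import (CalibrationReference, EchoTarget,
                                     cross_pol_isolation, estimate_noise_floor,
                                     measure_rcs, peak_power, range_profile,
                                     substitution_calibrate, synth_background,
                                     synth_sweep, temporal_average, time_gate,
                                     unambiguous_range)
from aeroscatter.errors import ValidationError
from aeroscatter.mie import calibration_sphere_rcs

FREQS = 9.5e9 + np.arange(401) * 5e6           # 2-GHz span, 5-MHz step


class TestSynthSweep:
    def test_single_target_peak_at_range(self):
        rec = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS,
                          noise_floor_dbm=-300.0, n_repeats=1, seed=1)
        prof = range_profile(rec, "hh")
        assert abs(prof.peak_range() - 4.0) <= prof.ranges[1] - prof.ranges[0]

    def test_two_targets_resolved(self):
        """2-GHz bandwidth → 7.5-cm resolution; 1-m spacing is easily split."""
        rec = synth_sweep([EchoTarget(4.0, 2e-4), EchoTarget(5.0, 2e-4)],
                          FREQS, -300.0, 1, seed=1)
        assert rec.range_resolution == pytest.approx(0.0748, abs=1e-3)
        prof = range_profile(rec, "hh")
        p = prof.power
        thresh = p.max() * 0.25
        # two disjoint above-threshold clusters
        above = np.flatnonzero(p > thresh)
        gaps = np.diff(above) > 3
        assert gaps.sum() == 1

    def test_seed_determinism(self):
        a = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -103.0, 10, seed=42)
        b = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -103.0, 10, seed=42)
        for ch in a.s:
            assert np.array_equal(a.s[ch], b.s[ch])

    def test_target_beyond_unambiguous_range(self):
        with pytest.raises(ValidationError):
            synth_sweep([EchoTarget(40.0, 1e-4)], FREQS)   # r_ua = 30 m at 5 MHz


class TestTemporalAverage:
    def test_identical_records_unchanged(self):
        rec = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -300.0, 1, seed=3)
        stacked = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -300.0, 1, seed=3)
        stacked.s = {ch: np.repeat(arr, 10, axis=0) for ch, arr in stacked.s.items()}
        avg = temporal_average(stacked)
        for ch in rec.s:
            assert np.allclose(avg.s[ch], rec.s[ch])

    def test_noise_power_reduced_tenfold(self):
        """Averaging 10 repeats cuts incoherent noise power ≈ 10× (Monte Carlo)."""
        ratios = []
        for seed in range(5):
            bg = synth_background(FREQS, -103.0, n_repeats=10, seed=seed)
            single = np.mean(np.abs(bg.s["hh"][0]) ** 2)
            avg = temporal_average(bg)
            ratios.append(np.mean(np.abs(avg.s["hh"]) ** 2) / single)
        assert np.mean(ratios) == pytest.approx(0.1, rel=0.3)

    def test_single_repeat_identity(self):
        rec = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -103.0, 1, seed=5)
        avg = temporal_average(rec)
        for ch in rec.s:
            assert np.array_equal(avg.s[ch], rec.s[ch])


class TestNoiseFloor:
    def test_recovers_injected_floor(self):
        bg = synth_background(FREQS, -103.0, n_repeats=10, seed=9)
        assert estimate_noise_floor(bg) == pytest.approx(-103.0, abs=0.5)

    def test_constant_record_closed_form(self):
        from aeroscatter.calibration import SweepRecord

        rec = SweepRecord(FREQS, {"hh": np.full((1, len(FREQS)), 3.0 + 4.0j)})
        assert estimate_noise_floor(rec) == pytest.approx(10 * np.log10(25.0))


class TestTimeGate:
    def test_gate_removes_clutter_keeps_target(self):
        # on-bin ranges keep DFT leakage out of the comparison
        dr = 299792458.0 / (2 * 401 * 5e6)
        target, clutter = 53 * dr, 80 * dr          # ≈ 4.0 m and ≈ 6.0 m
        clean = synth_sweep([EchoTarget(target, 2e-4)], FREQS, -300.0, 1, seed=2)
        cluttered = synth_sweep([EchoTarget(target, 2e-4),
                                 EchoTarget(clutter, 50e-4)], FREQS, -300.0, 1,
                                seed=2)
        p_clean = peak_power(time_gate(range_profile(clean, "hh"), target, 0.15))
        p_gated = peak_power(time_gate(range_profile(cluttered, "hh"), target, 0.15))
        assert p_gated == pytest.approx(p_clean, rel=0.01)

    def test_gate_over_empty_region_zero(self):
        dr = 299792458.0 / (2 * 401 * 5e6)
        rec = synth_sweep([EchoTarget(53 * dr, 2e-4)], FREQS, -300.0, 1, seed=2)
        gated = time_gate(range_profile(rec, "hh"), 20.0, 0.15)
        assert gated.power.max() < 1e-12 * peak_power(range_profile(rec, "hh"))

    def test_bin_count_in_gate(self):
        rec = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -300.0, 1, seed=2)
        prof = range_profile(rec, "hh")
        dr = prof.ranges[1] - prof.ranges[0]           # ≈ 7.5 cm
        gated = time_gate(prof, 4.0, 0.15)
        kept = np.flatnonzero(np.abs(gated.amplitude) > 0)
        brute = np.flatnonzero((prof.ranges >= 4.0 - 0.075)
                               & (prof.ranges <= 4.0 + 0.075))
        assert np.array_equal(kept, brute)
        assert 2 <= len(kept) <= 3

    def test_gate_outside_span(self):
        rec = synth_sweep([EchoTarget(4.0, 2e-4)], FREQS, -300.0, 1, seed=2)
        with pytest.raises(ValidationError):
            time_gate(range_profile(rec, "hh"), 100.0, 0.15)


class TestSubstitutionCalibration:
    def test_identity_and_linearity(self):
        ref = CalibrationReference(0.01582, 3e-4, measured_peak_power=2.0)
        assert substitution_calibrate(2.0, ref) == pytest.approx(3e-4)
        assert substitution_calibrate(4.0, ref) == pytest.approx(6e-4)

    def test_scale_invariance(self):
        """A common receiver gain cancels out of the calibrated σ."""
        sigma = 2e-4
        scene = synth_sweep([EchoTarget(4.0, sigma)], FREQS, -300.0, 1, seed=4)
        sphere = synth_sweep([EchoTarget(4.0, 5e-4)], FREQS, -300.0, 1, seed=5)
        est1 = measure_rcs(scene, sphere, 4.0, 0.01582)
        for rec in (scene, sphere):
            rec.s = {ch: arr * (0.3 - 1.7j) for ch, arr in rec.s.items()}
        est2 = measure_rcs(scene, sphere, 4.0, 0.01582)
        assert est2 == pytest.approx(est1, rel=1e-9)

    def test_full_round_trip_at_30db_snr(self):
        """sweep → average 10 → gate 15 cm → calibrate recovers σ within 5%."""
        sigma_true = 2.0e-4                       # 2.0 cm²
        floor = 10 * np.log10(sigma_true) - 30.0  # 30 dB SNR
        sphere_d = 0.01582
        sig_sphere = calibration_sphere_rcs(sphere_d, float(FREQS.mean()))
        ests = []
        for seed in range(3):
            scene = synth_sweep([EchoTarget(4.0, sigma_true),
                                 EchoTarget(7.0, 30e-4)],   # ground multipath
                                FREQS, floor, 10, seed=seed)
            sphere = synth_sweep([EchoTarget(4.0, sig_sphere)], FREQS, floor,
                                 10, seed=100 + seed)
            ests.append(measure_rcs(scene, sphere, 4.0, sphere_d))
        assert np.mean(ests) == pytest.approx(sigma_true, rel=0.05)


class TestCrossPolIsolation:
    def test_ideal_sphere_infinite(self):
        rec = synth_sweep([EchoTarget(4.0, 3e-4)], FREQS, -400.0, 1, seed=6)
        rec.s["hv"] = np.zeros_like(rec.s["hv"])
        assert cross_pol_isolation(rec, 4.0) == np.inf

    def test_24db_leakage(self):
        """Cross-pol injected at 1/251 of the co-pol power → ≈ 24 dB."""
        gains = {"hh": 1.0, "vv": 1.0, "hv": np.sqrt(1 / 251.0), "vh": 0.0}
        rec = synth_sweep([EchoTarget(4.0, 3e-4, gains)], FREQS, -400.0, 1, seed=6)
        iso = cross_pol_isolation(rec, 4.0)
        assert iso == pytest.approx(10 * np.log10(251.0), abs=0.1)
        assert iso == pytest.approx(24.0, abs=0.1)

    def test_zero_co_pol_rejected(self):
        rec = synth_sweep([], FREQS, -400.0, 1, seed=6)
        rec.s["hh"] = np.zeros_like(rec.s["hh"])
        with pytest.raises(ValidationError):
            cross_pol_isolation(rec, 4.0)


class TestUnambiguousRange:
    def test_reference_step(self):
        """The 0.561-MHz step reproduces the ≈267-m alias-free limit."""
        assert unambiguous_range(0.561e6) == pytest.approx(267.0, abs=0.5)

    def test_relation_against_aliasing_simulation(self):
        """A target just beyond r_ua aliases back to r − r_ua."""
        step = 5e6
        r_ua = unambiguous_range(step)
        freqs = 9.5e9 + np.arange(401) * step
        target = r_ua + 2.0
        # build the sweep by hand (generator refuses out-of-range targets)
        k = 2 * np.pi * freqs / 299792458.0
        sig = np.sqrt(2e-4) * np.exp(-2j * k * target)
        from aeroscatter.calibration import SweepRecord

        rec = SweepRecord(freqs, {"hh": sig[None, :]})
        prof = range_profile(rec, "hh")
        assert prof.peak_range() == pytest.approx(2.0, abs=prof.ranges[1] * 2)
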