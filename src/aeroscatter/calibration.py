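"""Synthetic controlled RCS measurements and their processing chain.

Emulates a vector-network-analyzer measurement of a suspended target:
frequency sweeps containing the target echo, multipath clutter at other
ranges, and additive receiver noise.  The processing steps mirror
standard anechoic/outdoor RCS practice: temporal averaging over repeat
sweeps, transformation to a range profile, a narrow time/range gate
around the target, substitution calibration against a conducting sphere
of analytically known RCS (Mie), and a cross-polar isolation check.

No instrument I/O: the fixture generator is the data source, which makes
every number in the pipeline traceable to known injected values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .mie import SPEED_OF_LIGHT, calibration_sphere_rcs

__all__ = [
    "SweepRecord",
    "RangeProfile",
    "CalibrationReference",
    "EchoTarget",
    "synth_sweep",
    "synth_background",
    "temporal_average",
    "estimate_noise_floor",
    "range_profile",
    "time_gate",
    "peak_power",
    "substitution_calibrate",
    "cross_pol_isolation",
    "unambiguous_range",
    "measure_rcs",
]

CHANNELS = ("hh", "hv", "vh", "vv")


def unambiguous_range(frequency_step: float) -> float:
    """Alias-free range c/(2Δf) of a stepped-frequency sweep.

    A 0.561-MHz step puts the aliasing limit at ≈ 267 m.
    """
    if frequency_step <= 0:
        raise ValidationError("frequency step must be > 0")
    return SPEED_OF_LIGHT / (2.0 * frequency_step)


@dataclass(frozen=True)
class EchoTarget:
    """One point echo in the synthetic scene."""

    range_m: float
    sigma_m2: float
    channel_gains: Dict[str, float] = field(
        default_factory=lambda: {"hh": 1.0, "vv": 1.0, "hv": 0.0, "vh": 0.0})


@dataclass
class SweepRecord:
    """Stepped-frequency transmission coefficients per polarization pair.

    ``s[channel]`` has shape (n_repeats, n_freqs); units are linear
    voltage-like amplitudes whose absolute scale cancels in substitution
    calibration.
    """

    frequencies: np.ndarray
    s: Dict[str, np.ndarray]

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) < 2:
            raise ValidationError("a sweep needs at least 2 frequency points")
        df = np.diff(self.frequencies)
        if not np.allclose(df, df[0], rtol=1e-9):
            raise ValidationError("frequency grid must be uniform")
        for ch in self.s:
            self.s[ch] = np.atleast_2d(np.asarray(self.s[ch], dtype=complex))
            if self.s[ch].shape[1] != len(self.frequencies):
                raise ValidationError(f"channel {ch}: length mismatch with grid")

    @property
    def frequency_step(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def bandwidth(self) -> float:
        return self.frequency_step * len(self.frequencies)

    @property
    def n_repeats(self) -> int:
        return next(iter(self.s.values())).shape[0]

    @property
    def unambiguous_range(self) -> float:
        return unambiguous_range(self.frequency_step)

    @property
    def range_resolution(self) -> float:
        return SPEED_OF_LIGHT / (2.0 * self.bandwidth)


@dataclass
class RangeProfile:
    """Complex echo amplitude versus range (inverse DFT of one sweep channel)."""

    ranges: np.ndarray
    amplitude: np.ndarray
    unambiguous_range: float

    def __post_init__(self):
        self.ranges = np.asarray(self.ranges, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.ranges.shape != self.amplitude.shape:
            raise ValidationError("ranges and amplitude must match")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def peak_range(self) -> float:
        return float(self.ranges[int(np.argmax(self.power))])


@dataclass(frozen=True)
class CalibrationReference:
    """Substitution standard: a conducting sphere of known RCS."""

    sphere_diameter: float
    sigma_true: float
    measured_peak_power: float

    def __post_init__(self):
        if self.sigma_true <= 0 or self.measured_peak_power <= 0:
            raise ValidationError("calibration reference needs positive σ and power")

    @classmethod
    def from_sphere(cls, diameter: float, frequency: float,
                    measured_peak_power: float) -> "CalibrationReference":
        return cls(diameter, calibration_sphere_rcs(diameter, frequency),
                   measured_peak_power)


def synth_sweep(targets: Sequence[EchoTarget], frequencies: Sequence[float],
                noise_floor_dbm: float = -103.0, n_repeats: int = 10,
                seed: Optional[int] = None) -> SweepRecord:
    """Generate a synthetic VNA sweep of a point-target scene.

    Each target contributes amplitude ``g·√σ·e^{−j2kR}`` per channel
    (two-way propagation phase; range attenuation is absorbed into the
    calibration constant and omitted), plus circular complex Gaussian
    noise with total power ``10^(floor/10)`` (dBm re 1 mW, the package's
    arbitrary linear power unit) independently per repeat, channel and
    frequency.  Deterministic under ``seed``.
    """
    freqs = np.asarray(frequencies, dtype=float)
    rec_probe = SweepRecord(freqs, {ch: np.zeros((1, len(freqs)), complex)
                                    for ch in CHANNELS})
    r_max = rec_probe.unambiguous_range
    for t in targets:
        if t.range_m >= r_max:
            raise ValidationError(
                f"target at {t.range_m:g} m beyond the unambiguous range {r_max:g} m")
        if t.sigma_m2 < 0:
            raise ValidationError("target σ must be ≥ 0")
    rng = np.random.default_rng(seed)
    k = 2.0 * np.pi * freqs / SPEED_OF_LIGHT
    noise_power = 10.0 ** (noise_floor_dbm / 10.0)
    s: Dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        signal = np.zeros(len(freqs), dtype=complex)
        for t in targets:
            g = t.channel_gains.get(ch, 0.0)
            signal += g * np.sqrt(t.sigma_m2) * np.exp(-2j * k * t.range_m)
        noise = rng.normal(scale=np.sqrt(noise_power / 2.0),
                           size=(n_repeats, len(freqs), 2))
        s[ch] = signal[None, :] + noise[..., 0] + 1j * noise[..., 1]
    return SweepRecord(freqs, s)


def synth_background(frequencies: Sequence[float], noise_floor_dbm: float = -103.0,
                     n_repeats: int = 10, seed: Optional[int] = None) -> SweepRecord:
    """Target-free scene: receiver noise only (for noise-floor characterization)."""
    return synth_sweep([], frequencies, noise_floor_dbm, n_repeats, seed)


def temporal_average(record: SweepRecord) -> SweepRecord:
    """Coherent (complex) mean over the repeat dimension.

    Averaging n repeats leaves coherent echoes untouched and reduces
    incoherent noise power by ≈ n.
    """
    return SweepRecord(record.frequencies,
                       {ch: arr.mean(axis=0, keepdims=True)
                        for ch, arr in record.s.items()})


def estimate_noise_floor(background: SweepRecord) -> float:
    """Mean power of a background record in dBm (10·log10 P, P in mW units)."""
    if not background.s:
        raise ValidationError("estimate_noise_floor: record has no channels")
    p = np.mean([np.mean(np.abs(arr) ** 2) for arr in background.s.values()])
    if p <= 0:
        raise ValidationError("estimate_noise_floor: zero-power record")
    return float(10.0 * np.log10(p))


def range_profile(record: SweepRecord, channel: str = "hh",
                  window: str = "rectangular") -> RangeProfile:
    """Inverse-DFT range profile of one (repeat-averaged) channel.

    ``window``: "rectangular" (default) or "hann" applied across the
    frequency samples before the transform.
    """
    if channel not in record.s:
        raise ValidationError(f"channel {channel!r} not in record")
    x = record.s[channel].mean(axis=0)
    n = len(x)
    if window == "hann":
        w = np.hanning(n)
        x = x * (w / w.mean())
    elif window != "rectangular":
        raise ValidationError(f"unknown window {window!r}")
    # e^{-j2kR} maps to the +n bin of the inverse DFT
    amp = np.fft.ifft(x)
    dr = SPEED_OF_LIGHT / (2.0 * record.bandwidth)
    ranges = np.arange(n) * dr
    return RangeProfile(ranges=ranges, amplitude=amp,
                        unambiguous_range=record.unambiguous_range)


def time_gate(profile: RangeProfile, center: float, width: float = 0.15) -> RangeProfile:
    """Zero the profile outside [center − width/2, center + width/2].

    The narrow default gate (15 cm) keeps only echoes from the target's
    position, suppressing ground multipath and rig clutter.
    """
    if width <= 0:
        raise ValidationError("gate width must be > 0")
    lo, hi = center - width / 2.0, center + width / 2.0
    if hi < profile.ranges.min() or lo > profile.ranges.max():
        raise ValidationError("time gate lies outside the range profile span")
    keep = (profile.ranges >= lo) & (profile.ranges <= hi)
    amp = np.where(keep, profile.amplitude, 0.0)
    return RangeProfile(ranges=profile.ranges, amplitude=amp,
                        unambiguous_range=profile.unambiguous_range)


def peak_power(profile: RangeProfile) -> float:
    """Peak |amplitude|² of a (gated) profile."""
    return float(profile.power.max())


def substitution_calibrate(target_power: float,
                           reference: CalibrationReference) -> float:
    """σ_target = σ_sphere_true · (P_target / P_sphere).

    The substitution technique: the sphere is measured in the target's
    place, so all system gains cancel in the power ratio.
    """
    if target_power <= 0:
        raise ValidationError("substitution_calibrate: target power must be > 0")
    return reference.sigma_true * target_power / reference.measured_peak_power


def cross_pol_isolation(record: SweepRecord, target_range: float,
                        gate_width: float = 0.15,
                        co: str = "hh", cross: str = "hv") -> float:
    """Co/cross power ratio (dB) at the gated sphere position.

    A sphere has no cross-polar backscatter, so this ratio measures the
    instrument's polarization isolation.  Returns +inf when the
    cross-polar channel is identically zero.
    """
    avg = temporal_average(record)
    p_co = peak_power(time_gate(range_profile(avg, co), target_range, gate_width))
    p_cross = peak_power(time_gate(range_profile(avg, cross), target_range, gate_width))
    if p_co <= 0:
        raise ValidationError("cross_pol_isolation: co-polar power is zero")
    if p_cross == 0:
        return float("inf")
    return float(10.0 * np.log10(p_co / p_cross))


def measure_rcs(scene: SweepRecord, sphere_scene: SweepRecord,
                target_range: float, sphere_diameter: float,
                gate_width: float = 0.15, channel: str = "hh") -> float:
    """Full measurement chain: average → gate → substitution-calibrate.

    Both records must come from the same (synthetic) instrument; the
    sphere is assumed at the target's position, as in a substitution
    measurement.  Returns the calibrated σ in m² for ``channel``.
    """
    f_center = float(np.mean(scene.frequencies))
    p_t = peak_power(time_gate(range_profile(temporal_average(scene), channel),
                               target_range, gate_width))
    p_s = peak_power(time_gate(range_profile(temporal_average(sphere_scene), channel),
                               target_range, gate_width))
    ref = CalibrationReference.from_sphere(sphere_diameter, f_center, p_s)
    return substitution_calibrate(p_t, ref)
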