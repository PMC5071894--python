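"""Radar-facing transforms on polarimetric patterns.

dB conversions, differential RCS (plain and simultaneous-transmit SHV),
dynamic-range clipping, circular median filtering, sector statistics in
the head-on / side-on / tail-on windows, and the pattern-comparison
metrics (Pearson r on linear RCS, RMSE, and the wavelength-to-bodylength
size-ratio curve).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "RadarEmulationConfig",
    "SectorStats",
    "SizeRatioCurve",
    "SECTORS",
    "to_dbsm",
    "from_dbsm",
    "differential_rcs",
    "shv_differential_rcs",
    "clip_dynamic_range",
    "circular_median_filter",
    "sector_stats",
    "pearson_linear",
    "rmse_pattern",
    "size_ratio_analysis",
    "equivalence_threshold",
]

#: Floor applied to σ before dB conversion inside pattern-level helpers,
#: so deep interference nulls do not produce −inf.
SIGMA_FLOOR = 1e-10   # m²

#: 90°-wide aspect sectors, half-open [lo, hi) and wrapping modulo 360.
SECTORS: Dict[str, Tuple[float, float]] = {
    "head_on": (315.0, 45.0),     # −45° … +45°
    "side_on": (45.0, 135.0),
    "tail_on": (135.0, 225.0),
    "off_side": (225.0, 315.0),   # the implied fourth sector
}


@dataclass(frozen=True)
class RadarEmulationConfig:
    """How a simultaneous-transmit weather radar samples differential RCS.

    ``dynamic_range_limit`` clamps the differential series (±8 dB is the
    receiver limit of the X-band system emulated here);
    ``median_halfwidth`` smooths over heading spread in an ensemble of
    animals (±15° default); ``mode`` selects plain alternate-transmit
    differential RCS or the SHV co+cross coherent sum.
    """

    dynamic_range_limit: float = 8.0    # dB
    median_halfwidth: float = 15.0      # degrees
    mode: str = "shv"                   # "plain" | "shv"

    def __post_init__(self):
        if self.dynamic_range_limit <= 0:
            raise ValidationError("dynamic_range_limit must be > 0")
        if self.median_halfwidth < 0:
            raise ValidationError("median_halfwidth must be ≥ 0")
        if self.mode not in ("plain", "shv"):
            raise ValidationError(f"mode must be 'plain' or 'shv', got {self.mode!r}")


@dataclass(frozen=True)
class SectorStats:
    """Per-sector mean/median linear RCS per channel.

    ``linear`` maps sector → channel → (mean_m2, median_m2); the cm² and
    dBsm views are derived from the unrounded linear aggregates.
    """

    linear: Dict[str, Dict[str, Tuple[float, float]]]

    def cm2(self, sector: str, channel: str) -> Tuple[float, float]:
        mean, med = self.linear[sector][channel]
        return mean * 1e4, med * 1e4

    def dbsm(self, sector: str, channel: str) -> Tuple[float, float]:
        mean, med = self.linear[sector][channel]
        return to_dbsm(mean), to_dbsm(med)


@dataclass(frozen=True)
class SizeRatioCurve:
    """Similarity between two bodies' patterns vs wavelength/body-length."""

    ratios: np.ndarray          # λ / body length, ascending
    pearson_r: np.ndarray
    rmse: np.ndarray
    rmse_scale: str = "db"

    def __len__(self):
        return len(self.ratios)


def to_dbsm(sigma):
    """10·log10(σ / 1 m²).  Raises on non-positive input."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError("to_dbsm: σ must be > 0 (apply a floor first if needed)")
    out = 10.0 * np.log10(sigma)
    return float(out) if out.ndim == 0 else out


def from_dbsm(db):
    db = np.asarray(db, dtype=float)
    out = 10.0 ** (db / 10.0)
    return float(out) if out.ndim == 0 else out


def differential_rcs(sigma_hh, sigma_vv):
    """Differential RCS 10·log10(σ_HH/σ_VV), the single-scatterer Z_DR."""
    sigma_hh = np.asarray(sigma_hh, dtype=float)
    sigma_vv = np.asarray(sigma_vv, dtype=float)
    if np.any(sigma_hh <= 0) or np.any(sigma_vv <= 0):
        raise ValidationError("differential_rcs: both channels must be > 0")
    out = 10.0 * np.log10(sigma_hh / sigma_vv)
    return float(out) if out.ndim == 0 else out


def shv_differential_rcs(s_hh, s_vv, s_hv=0.0, s_vh=0.0):
    """Differential RCS under simultaneous H+V transmission.

    A radar transmitting both polarizations at once receives, in each
    co-polar channel, the coherent sum of the co- and cross-polar
    backscatter amplitudes, so

        Z_DR = 10·log10( |S_HH + S_HV|² / |S_VV + S_VH|² ).

    Reduces to the plain differential RCS when the cross-polar terms
    vanish; nonzero cross-pol skews the polar diagram asymmetrically.
    Accepts scalars or matched arrays (e.g. a whole azimuth series).
    """
    num = np.abs(np.asarray(s_hh, complex) + np.asarray(s_hv, complex)) ** 2
    den = np.abs(np.asarray(s_vv, complex) + np.asarray(s_vh, complex)) ** 2
    if np.any(den == 0) or np.any(num == 0):
        raise ValidationError("shv_differential_rcs: coherent channel sum vanished")
    out = 10.0 * np.log10(num / den)
    return float(out) if out.ndim == 0 else out


def clip_dynamic_range(values_db, config: RadarEmulationConfig = RadarEmulationConfig()):
    """Clamp a dB series to ±dynamic_range_limit."""
    lim = config.dynamic_range_limit
    return np.clip(np.asarray(values_db, dtype=float), -lim, lim)


def circular_median_filter(values, halfwidth_deg: float, step_deg: Optional[float] = None):
    """Median filter on a closed 360° grid.

    Each output sample is the median of all input samples within
    ±halfwidth (endpoints included), indices wrapping modulo 360°.
    ``step_deg`` defaults to 360/n for a full-circle series.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValidationError("circular_median_filter: empty series")
    step = 360.0 / n if step_deg is None else float(step_deg)
    if halfwidth_deg < step:
        if halfwidth_deg > 0:
            warnings.warn("median halfwidth below the grid step; filter is a no-op")
        return v.copy()
    w = int(np.floor(halfwidth_deg / step + 1e-9))
    offsets = np.arange(-w, w + 1)
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    return np.median(v[idx], axis=1)


def _sector_mask(azimuths: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # half-open [lo, hi) with wrap-around
    a = np.mod(azimuths - lo, 360.0)
    span = np.mod(hi - lo, 360.0)
    return a < span


def sector_stats(azimuth_deg: Sequence[float],
                 channels: Dict[str, Sequence[float]]) -> SectorStats:
    """Mean/median of *linear* σ over the four 90° aspect sectors.

    ``channels`` maps channel names ("hh", "vv", ...) to σ series in m²
    on the given azimuth grid; the grid must cover the full circle.
    """
    az = np.mod(np.asarray(azimuth_deg, dtype=float), 360.0)
    if len(az) < 4 or (az.max() - az.min()) < 270.0 - 1e-9:
        raise ValidationError("sector_stats: pattern must cover the full circle")
    out: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for name, (lo, hi) in SECTORS.items():
        mask = _sector_mask(az, lo, hi)
        if not mask.any():
            raise ValidationError(f"sector_stats: no samples in sector {name}")
        out[name] = {}
        for ch, series in channels.items():
            s = np.asarray(series, dtype=float)[mask]
            out[name][ch] = (float(s.mean()), float(np.median(s)))
    return SectorStats(linear=out)


def pearson_linear(series_a, series_b) -> float:
    """Pearson r between two matched σ series in linear units."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("pearson_linear: series shapes differ")
    if len(a) < 3:
        raise ValidationError("pearson_linear: need at least 3 samples")
    da, db_ = a - a.mean(), b - b.mean()
    va, vb = np.dot(da, da), np.dot(db_, db_)
    if va == 0 or vb == 0:
        raise ValidationError("pearson_linear: zero variance, correlation undefined")
    return float(np.dot(da, db_) / np.sqrt(va * vb))


def rmse_pattern(series_a, series_b, scale: str = "db") -> float:
    """RMS difference between matched patterns, on the dBsm (default) or linear scale."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rmse_pattern: series shapes differ")
    if scale == "db":
        a = 10.0 * np.log10(np.maximum(a, SIGMA_FLOOR))
        b = 10.0 * np.log10(np.maximum(b, SIGMA_FLOOR))
    elif scale != "linear":
        raise ValidationError("rmse_pattern: scale must be 'db' or 'linear'")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def size_ratio_analysis(wavelengths: Sequence[float],
                        patterns_a: Sequence[Sequence[float]],
                        patterns_b: Sequence[Sequence[float]],
                        body_length: float,
                        rmse_scale: str = "db") -> SizeRatioCurve:
    """Similarity of two bodies' H-pol patterns as a function of size ratio.

    For each wavelength, computes ratio = λ / body_length, Pearson r and
    RMSE between the two σ_HH azimuth series.  Sorted by ascending ratio.
    """
    if len(wavelengths) != len(patterns_a) or len(wavelengths) != len(patterns_b):
        raise ValidationError("size_ratio_analysis: mismatched frequency lists")
    if len(wavelengths) == 0:
        raise ValidationError("size_ratio_analysis: empty frequency list")
    if body_length <= 0:
        raise ValidationError("size_ratio_analysis: body_length must be > 0")
    ratios = np.asarray(wavelengths, dtype=float) / body_length
    order = np.argsort(ratios)
    r = np.array([pearson_linear(patterns_a[i], patterns_b[i]) for i in order])
    e = np.array([rmse_pattern(patterns_a[i], patterns_b[i], rmse_scale) for i in order])
    return SizeRatioCurve(ratios=ratios[order], pearson_r=r, rmse=e,
                          rmse_scale=rmse_scale)


def equivalence_threshold(curve: SizeRatioCurve, r_min: float = 0.9) -> Optional[float]:
    """Smallest size ratio from which r ≥ r_min is sustained.

    Operationalizes the "equivalent ellipsoid above a size ratio of ≈ 4"
    rule: the first ratio at which the correlation reaches ``r_min`` and
    stays there at every larger ratio.  None if never sustained.
    """
    ok = curve.pearson_r >= r_min
    for i in range(len(ok)):
        if ok[i:].all():
            return float(curve.ratios[i])
    return None
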