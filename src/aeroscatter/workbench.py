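"""Scenario runner: configuration, logging, and end-to-end computations.

Ties the modules together into the three canonical studies:

* ``run_sweep`` — solve a body's azimuth pattern and write it as CSV;
* ``run_compare`` — compare two patterns the way controlled measurements
  are compared with models (sector table, Pearson r, RMSE, and the
  clipped + median-filtered simultaneous-transmit differential series);
* ``run_size_ratio`` — sweep frequency and chart how well an equivalent
  ellipsoid reproduces a winged body as λ/bodylength grows.

Configs are YAML mappings validated before any compute; each run writes
the resolved config beside its outputs so every bundle is reproducible.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .errors import ValidationError
from .geometry import (DipoleLattice, EllipsoidSpec, ToyOrganismSpec,
                       bat_equivalent_ellipsoid, make_ellipsoid_lattice,
                       make_toy_organism, read_mesh, voxelize_mesh)
from .materials import tissue_default
from .mie import SPEED_OF_LIGHT
from .polarimetry import (RadarEmulationConfig, SECTORS, circular_median_filter,
                          clip_dynamic_range, equivalence_threshold,
                          pearson_linear, rmse_pattern, sector_stats,
                          shv_differential_rcs, size_ratio_analysis, to_dbsm)
from .solver import PolarPattern, azimuth_sweep, default_spacing

log = logging.getLogger("aeroscatter")

_GEOMETRY_KINDS = ("ellipsoid", "toy_organism", "mesh")


@dataclass
class RunConfig:
    """Validated scenario description (all lengths meters, angles degrees)."""

    scenario: str = "sweep"
    geometry: str = "ellipsoid"                  # ellipsoid | toy_organism | mesh
    mesh_path: Optional[str] = None
    semi_axes: Tuple[float, float, float] = (0.025, 0.01156, 0.0079)
    wing_span: float = 0.08
    wing_chord: float = 0.025
    wing_thickness: float = 0.001
    material: str = "bat_effective"
    frequency: float = 10.0e9                    # Hz
    frequencies: Optional[List[float]] = None    # Hz, for size-ratio sweeps
    plane_tilt_deg: float = 0.0
    azimuth_step_deg: float = 10.0
    spacing: Optional[float] = None              # None → λ/(10|m|) capped by thin features
    points_per_wavelength: float = 10.0
    tolerance: float = 1e-3
    polarizability_model: str = "icd"
    precision: str = "double"
    fill_fractions: bool = True
    exploit_mirror_symmetry: bool = False
    emulation: RadarEmulationConfig = field(default_factory=RadarEmulationConfig)
    unit_scale: float = 1e-3
    body_length: Optional[float] = None          # for size-ratio; default from geometry
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in _GEOMETRY_KINDS:
            raise ValidationError(f"geometry must be one of {_GEOMETRY_KINDS}")
        if self.geometry == "mesh" and not self.mesh_path:
            raise ValidationError("geometry 'mesh' requires mesh_path")
        if self.frequency <= 0:
            raise ValidationError("frequency must be > 0")
        if self.azimuth_step_deg <= 0 or 360.0 % self.azimuth_step_deg > 1e-9:
            raise ValidationError("azimuth_step_deg must divide 360")
        if not isinstance(self.emulation, RadarEmulationConfig):
            self.emulation = RadarEmulationConfig(**dict(self.emulation))

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "semi_axes" in raw:
            raw["semi_axes"] = tuple(raw["semi_axes"])
        return cls(**raw)

    def resolved(self) -> dict:
        out = asdict(self)
        out["emulation"] = asdict(self.emulation) if isinstance(
            self.emulation, RadarEmulationConfig) else self.emulation
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)


def build_lattice(config: RunConfig, frequency: Optional[float] = None,
                  spacing: Optional[float] = None) -> DipoleLattice:
    """Materialize the configured geometry at the spacing the run needs."""
    f = frequency or config.frequency
    lam = SPEED_OF_LIGHT / f
    mat = tissue_default(config.material)
    cap = config.wing_thickness if config.geometry == "toy_organism" else None
    d = spacing or config.spacing or default_spacing(
        mat.epsilon_r, lam, config.points_per_wavelength, cap=cap)
    if config.geometry == "ellipsoid":
        spec = EllipsoidSpec(*config.semi_axes)
        return make_ellipsoid_lattice(spec, d, mat,
                                      fill_fractions=config.fill_fractions)
    if config.geometry == "toy_organism":
        spec = ToyOrganismSpec(body=EllipsoidSpec(*config.semi_axes),
                               wing_span=config.wing_span,
                               wing_chord=config.wing_chord,
                               wing_thickness=config.wing_thickness)
        mesh = make_toy_organism(spec)
        return voxelize_mesh(mesh, d, mat, fill_fractions=config.fill_fractions)
    mesh = read_mesh(config.mesh_path, unit_scale=config.unit_scale)
    return voxelize_mesh(mesh, d, mat, fill_fractions=config.fill_fractions)


def run_sweep(config: RunConfig) -> str:
    """Solve the configured azimuth sweep; returns the pattern CSV path."""
    os.makedirs(config.output_dir, exist_ok=True)
    lam = SPEED_OF_LIGHT / config.frequency
    lattice = build_lattice(config)
    log.info("sweep: %d dipoles at d=%.3g m, λ=%.3g m",
             len(lattice), lattice.spacing, lam)
    pattern = azimuth_sweep(lattice, lam, config.plane_tilt_deg,
                            config.azimuth_step_deg, config.tolerance,
                            config.polarizability_model,
                            exploit_mirror_symmetry=config.exploit_mirror_symmetry,
                            precision=config.precision)
    out = os.path.join(config.output_dir, f"{config.scenario}_pattern.csv")
    pattern.write_csv(out)
    config.write(os.path.join(config.output_dir, f"{config.scenario}_config.yaml"))
    log.info("sweep: wrote %s", out)
    return out


def compare_report(pattern_a: PolarPattern, pattern_b: PolarPattern,
                   emulation: RadarEmulationConfig = RadarEmulationConfig()) -> dict:
    """Sector table, correlation/RMSE, and emulated differential-RCS series."""
    if len(pattern_a) != len(pattern_b) or not np.allclose(
            pattern_a.azimuth_deg, pattern_b.azimuth_deg):
        raise ValidationError("patterns are on different azimuth grids")
    report = {"sectors": {}, "full_circle": {}}
    for tag, pat in (("a", pattern_a), ("b", pattern_b)):
        st = sector_stats(pat.azimuth_deg, {"hh": pat.sigma_hh, "vv": pat.sigma_vv})
        tbl = {}
        for sec in SECTORS:
            tbl[sec] = {}
            for ch in ("hh", "vv"):
                mean_cm2, med_cm2 = st.cm2(sec, ch)
                mean_db, med_db = st.dbsm(sec, ch)
                tbl[sec][ch] = {"mean_cm2": mean_cm2, "median_cm2": med_cm2,
                                "mean_dbsm": mean_db, "median_dbsm": med_db}
        report["sectors"][tag] = tbl
        report["full_circle"][tag] = {
            ch: {"mean_cm2": float(pat.channel(ch).mean() * 1e4),
                 "mean_dbsm": to_dbsm(float(pat.channel(ch).mean()))}
            for ch in ("hh", "vv")}
    report["pearson_r"] = {
        ch: pearson_linear(pattern_a.channel(ch), pattern_b.channel(ch))
        for ch in ("hh", "vv")}
    report["rmse_db"] = {
        ch: rmse_pattern(pattern_a.channel(ch), pattern_b.channel(ch), "db")
        for ch in ("hh", "vv")}
    # emulated differential-RCS polar series for pattern a
    report["differential_series"] = {
        "azimuth_deg": pattern_a.azimuth_deg.tolist(),
        "zdr_db": emulated_differential_series(pattern_a, emulation).tolist(),
    }
    return report


def emulated_differential_series(pattern: PolarPattern,
                                 emulation: RadarEmulationConfig) -> np.ndarray:
    """SHV (or plain) differential RCS, clipped and circular-median filtered."""
    if emulation.mode == "shv" and pattern.s_matrices is not None:
        s = pattern.s_matrices
        zdr = shv_differential_rcs(s[:, 0, 0], s[:, 1, 1], s[:, 0, 1], s[:, 1, 0])
    else:
        from .polarimetry import SIGMA_FLOOR
        zdr = 10.0 * np.log10(np.maximum(pattern.sigma_hh, SIGMA_FLOOR)
                              / np.maximum(pattern.sigma_vv, SIGMA_FLOOR))
    zdr = clip_dynamic_range(zdr, emulation)
    step = 360.0 / len(pattern)
    return circular_median_filter(zdr, emulation.median_halfwidth, step)


def run_compare(pattern_a_path: str, pattern_b_path: str,
                config: Optional[RunConfig] = None) -> dict:
    """Compare two pattern CSVs; writes and returns the JSON report."""
    config = config or RunConfig(scenario="compare")
    a = PolarPattern.read_csv(pattern_a_path)
    b = PolarPattern.read_csv(pattern_b_path)
    report = compare_report(a, b, config.emulation)
    os.makedirs(config.output_dir, exist_ok=True)
    out = os.path.join(config.output_dir, f"{config.scenario}_report.json")
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("compare: wrote %s", out)
    return report


def run_size_ratio(config: RunConfig,
                   frequencies: Optional[Sequence[float]] = None) -> dict:
    """Toy organism vs its equivalent ellipsoid across a frequency list.

    Uses the H-polarized azimuth patterns of both bodies at each
    frequency, the Pearson r / RMSE similarity curve against
    λ/body_length, and the sustained-correlation equivalence threshold.
    """
    freqs = list(frequencies or config.frequencies or [])
    if not freqs:
        raise ValidationError("run_size_ratio needs a frequency list")
    body_length = config.body_length or 2 * config.semi_axes[0]
    mat = tissue_default(config.material)
    toy_spec = ToyOrganismSpec(body=EllipsoidSpec(*config.semi_axes),
                               wing_span=config.wing_span,
                               wing_chord=config.wing_chord,
                               wing_thickness=config.wing_thickness)
    # surrogate: the toy's own equivalent ellipsoid (wings are scattering
    # tissue, so the lateral extent includes them)
    ell = toy_spec.equivalent_ellipsoid()
    toy_cfg = RunConfig(**{**config.resolved(), "geometry": "toy_organism",
                           "emulation": config.emulation})
    ell_axes = (ell.semi_axis_anteroposterior, ell.semi_axis_lateral,
                ell.semi_axis_dorsoventral)
    ell_cfg = RunConfig(**{**config.resolved(), "geometry": "ellipsoid",
                           "semi_axes": ell_axes,
                           "emulation": config.emulation})
    pats_toy, pats_ell, lams = [], [], []
    for f in sorted(freqs, reverse=True):
        lam = SPEED_OF_LIGHT / f
        lams.append(lam)
        for cfg, acc, mirror in ((toy_cfg, pats_toy, config.exploit_mirror_symmetry),
                                 (ell_cfg, pats_ell, config.exploit_mirror_symmetry)):
            lat = build_lattice(cfg, frequency=f)
            log.info("size-ratio: %s at %.3g GHz, %d dipoles",
                     cfg.geometry, f / 1e9, len(lat))
            acc.append(azimuth_sweep(lat, lam, cfg.plane_tilt_deg,
                                     cfg.azimuth_step_deg, cfg.tolerance,
                                     cfg.polarizability_model,
                                     keep_matrices=False,
                                     exploit_mirror_symmetry=mirror,
                                     precision=cfg.precision,
                                     incident_polarizations="h"))
    curve = size_ratio_analysis(lams,
                                [p.sigma_hh for p in pats_toy],
                                [p.sigma_hh for p in pats_ell],
                                body_length)
    thr = equivalence_threshold(curve)
    result = {
        "size_ratio": curve.ratios.tolist(),
        "pearson_r": curve.pearson_r.tolist(),
        "rmse_db": curve.rmse.tolist(),
        "equivalence_threshold": thr,
    }
    os.makedirs(config.output_dir, exist_ok=True)
    out = os.path.join(config.output_dir, f"{config.scenario}_size_ratio.csv")
    import pandas as pd

    pd.DataFrame({"size_ratio": curve.ratios, "pearson_r": curve.pearson_r,
                  "rmse_db": curve.rmse}).to_csv(out, index=False)
    log.info("size-ratio: wrote %s (threshold %s)", out, thr)
    return result
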