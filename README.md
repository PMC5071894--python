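# aeroscatter

Polarimetric radar cross sections (RCS) of airborne organisms, computed
from 3-D body models by an exact volume method-of-moments scattering
solver, with the calibration and radar-emulation machinery of radar
aeroecology around it.

Weather and research radars routinely see bats, birds and insects, but
quantitative biology on those echoes needs each animal's full
aspect-dependent, dual-polarization RCS — data that controlled
laboratory measurement yields only slowly and partially.  `aeroscatter`
computes it instead:

* **Geometry** — read STL/OBJ/PLY meshes, build parametric ellipsoids or
  a winged toy organism, and voxelize everything onto a cubic dipole
  lattice (with volume-fraction boundary weighting).
* **Solver** — the coupled-dipole method: the volume electric-field
  integral equation with one polarizable cell per lattice site,
  FFT-accelerated, yielding the complex 2×2 backscatter matrix
  S = [[S_HH, S_HV], [S_VH, S_VV]] (σ_pq = 4π|S_pq|²) at any look angle,
  wavelength and polarization.  Validated against the Mie series for
  spheres of the same high-loss tissue permittivity.
* **Mie** — series solutions for dielectric and conducting spheres: the
  calibration standard and the package's analytic oracle.
* **Polarimetry** — dBsm conversion, sector statistics (head-on /
  side-on / tail-on), differential RCS including the
  simultaneous-transmit (SHV) form 10·log10(|S_HH+S_HV|²/|S_VV+S_VH|²),
  ±8 dB dynamic-range clipping, ±15° circular median filtering, Pearson
  r / RMSE pattern comparison, and the wavelength-to-bodylength
  size-ratio analysis.
* **Calibration** — synthetic network-analyzer sweeps (target echo,
  multipath clutter, noise floor), temporal averaging, range gating, and
  substitution calibration against a conducting sphere of analytically
  known RCS.

The default material is the body-averaged tissue permittivity of a
Brazilian free-tailed bat at X band, ε_r = 29.29 − j12.89, and the
default equivalent body is its 50 × 23.12 × 15.8 mm torso ellipsoid.
See `docs/methods.md` for the model, numerics, and the scales at which
the packaged studies run.

## Worked example

Backscatter of the equivalent bat ellipsoid, head-on at 10 GHz:

```python
import aeroscatter as ae

lat = ae.make_ellipsoid_lattice(ae.bat_equivalent_ellipsoid(), 0.0008,
                                "bat_effective", fill_fractions=True)
S = ae.backscatter_matrix(lat, ae.PlaneWave(0.03, [-1, 0, 0]), tolerance=1e-3)
print(f"sigma_HH = {S.sigma_hh*1e4:.2f} cm^2  sigma_VV = {S.sigma_vv*1e4:.2f} cm^2")
```

prints (d = 0.8 mm pilot lattice, 20 860 dipoles)

```
sigma_HH = 1.16 cm^2  sigma_VV = 0.60 cm^2
```

— head-on, the horizontal field lies along the wide lateral axis, so
σ_HH exceeds σ_VV about twofold.  The head-on aspect still sits in a
pattern minimum: the full-circle mean at
this resolution is ≈ 2.2 cm² (HH) / 1.8 cm² (VV), and the side-on
sector mean ≈ 3.7 / 3.2 cm², within ±2 dB of the published
surface-MoM values for the same ellipsoid (4.04 / 3.48 cm² side-on,
full-circle 2.49 / 1.97 cm²).

The synthetic substitution-calibration round trip, from the command
line:

```
$ aeroscatter calibrate --seed 3
{
  "injected_sigma_m2": 0.0002,
  "recovered_sigma_m2": 0.00019976422394774902,
  "sphere_sigma_m2": 5.60464930048293e-05,
  "unambiguous_range_m": 29.9792458
}
```

A 2.0-cm² target in −67 dBm receiver noise (30 dB SNR) is recovered as
1.998 cm² after 10-sweep averaging, 15-cm gating, and substitution
against the 15.82-mm calibration sphere (whose Mie RCS at 10.5 GHz is
0.56 cm²).

Other CLI entry points: `aeroscatter sweep --config cfg.yaml` (azimuth
pattern → CSV), `aeroscatter mie`, `aeroscatter compare a.csv b.csv`,
`aeroscatter size-ratio --config cfg.yaml`, `aeroscatter fixtures`.

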