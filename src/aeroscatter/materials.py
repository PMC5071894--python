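"""Complex permittivity, effective-medium averaging, and dipole polarizability.

Conventions
-----------
The package uses the engineering time convention ``e^{+jωt}``, so a lossy
medium has permittivity ``ε = ε′ − jε″`` with ``ε″ ≥ 0`` and refractive
index ``m = √ε`` with ``Im(m) ≤ 0``.  (Physics texts with ``e^{-iωt}``
carry the opposite sign; all internal solver arithmetic conjugates in and
out consistently, so users only ever see the engineering sign.)

The default body material is the effective (body-averaged) permittivity
used for bat tissue at X band, ``ε_r = 29.29 − j12.89``: a single complex
constant standing in for the animal's heterogeneous tissue composition,
chosen so that internal dielectric boundaries need not be modeled.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import MaterialLookupError, NumericError, ValidationError

__all__ = [
    "Material",
    "Polarizability",
    "effective_permittivity",
    "refractive_index",
    "polarizability",
    "tissue_default",
    "TISSUE_TABLE",
]


@dataclass(frozen=True)
class Material:
    """A homogeneous dielectric, ``ε = ε′ − jε″`` (ε″ ≥ 0 for passive media)."""

    epsilon_r: complex
    name: str = ""

    def __post_init__(self):
        eps = complex(self.epsilon_r)
        if eps.imag > 1e-12:
            raise ValidationError(
                f"material {self.name!r}: ε = {eps} has gain under the "
                "ε = ε′ − jε″ convention (ε″ = −Im ε must be ≥ 0)"
            )
        object.__setattr__(self, "epsilon_r", eps)

    @property
    def loss(self) -> float:
        """ε″ (≥ 0)."""
        return -self.epsilon_r.imag


@dataclass(frozen=True)
class Polarizability:
    """Scalar dipole polarizability α (m³) for one lattice pitch and wavelength."""

    alpha: complex
    spacing: float
    wavelength: float
    model: str = "ldr"


def effective_permittivity(components: Sequence[Tuple[Material, float]],
                           name: str = "effective") -> Material:
    """Volume-weighted arithmetic mean of complex permittivities.

    This is the simplest homogenization rule consistent with a
    "body-averaged" permittivity; weights are normalized internally, so
    only their ratios matter.
    """
    if not components:
        raise ValidationError("effective_permittivity: empty component list")
    weights = np.array([w for _, w in components], dtype=float)
    if np.any(weights < 0):
        raise ValidationError("effective_permittivity: negative volume weight")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("effective_permittivity: all weights zero")
    eps = np.array([m.epsilon_r for m, _ in components], dtype=complex)
    return Material(epsilon_r=complex(np.dot(weights, eps) / total), name=name)


def refractive_index(material: Material) -> complex:
    """Principal complex index ``m = √ε`` with Re(m) > 0 and Im(m) ≤ 0."""
    m = np.sqrt(complex(material.epsilon_r))
    if m.real < 0:
        m = -m
    # numerical noise can leave a tiny positive imaginary part for real ε
    if m.imag > 0 and m.imag < 1e-14:
        m = complex(m.real, 0.0)
    return complex(m)


# Lattice-dispersion-relation coefficients (pulse-basis cubic lattice).
_LDR_B1 = -1.891531
_LDR_B2 = 0.1648469
_LDR_B3 = -1.7700004
# Orientation/polarization average of S = Σ_j (k̂_j ê_j)²; used when the
# incident geometry is not supplied.
_LDR_S_ISO = 0.2

_SELF_INTEGRAL_CACHE: dict = {}


def _dynamic_self_integral(kd: float, n: int = 24) -> complex:
    """M(kd) = ∫_cell (G_dyn − G_static) dV / d³ · d³ … scalar self-term.

    The dynamic part of the Green dyadic integrated over the dipole's own
    cubic cell (the static singularity cancels; the integrand is O(k²/r)
    and the midpoint rule on an n³ subgrid converges quickly).  By cube
    symmetry the tensor is isotropic, so a scalar suffices.  Depends on
    kd only; computed in the e^{-iωt} convention.
    """
    key = round(float(kd), 12)
    if key in _SELF_INTEGRAL_CACHE:
        return _SELF_INTEGRAL_CACHE[key]
    g = ((np.arange(n) + 0.5) / n - 0.5)          # unit cell, d = 1
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    u2 = (X / r) ** 2
    e = np.exp(1j * kd * r)
    val = ((3 * u2 - 1) * ((e * (1 - 1j * kd * r) - 1) / r**3)
           + kd**2 * e * (1 - u2) / r)
    M = complex(val.mean())            # per unit d³; scale-free in kd
    _SELF_INTEGRAL_CACHE[key] = M
    return M


def polarizability(material: Material, spacing: float, wavelength: float,
                   model: str = "ldr", k_hat=None, e_hat=None) -> Polarizability:
    """Per-dipole polarizability for the coupled-dipole solver.

    Models
    ------
    ``cm``
        Bare Clausius–Mossotti, ``α = (3d³/4π)(ε−1)/(ε+2)``.
    ``cm_rr``
        Clausius–Mossotti with the radiative-reaction correction; makes an
        isolated dipole satisfy the optical theorem.
    ``ldr``
        Lattice dispersion relation: the O((kd)²) lattice correction plus
        radiative reaction.  ``k_hat``/``e_hat`` (incident propagation and
        polarization) refine the anisotropic term; without them the
        orientation average is used.
    ``icd`` (default)
        Integrated coupled dipole: the self-term is corrected by the
        numerically integrated dynamic Green dyadic over the cell's own
        cube, which contains the radiative-reaction term and the real
        O((kd)²) self-shift consistently.  Pairs with the solver's
        cube-averaged near-field interactions.

    All corrections vanish as d → 0 at fixed λ, where α reduces to the
    Clausius–Mossotti value.
    """
    if spacing <= 0 or wavelength <= 0:
        raise ValidationError("polarizability: spacing and wavelength must be > 0")
    if model not in ("cm", "cm_rr", "ldr", "icd"):
        raise ValidationError(f"unknown polarizability model {model!r}")
    alpha = _alpha_internal(np.conj(material.epsilon_r), spacing,
                            2 * np.pi / wavelength, model, k_hat, e_hat)
    # convert from the internal e^{-iωt} convention back to e^{+jωt}
    return Polarizability(alpha=complex(np.conj(alpha)), spacing=spacing,
                          wavelength=wavelength, model=model)


def _alpha_internal(eps, d, k, model, k_hat=None, e_hat=None):
    """α in the e^{-iωt} convention (Im(ε) ≥ 0). Vectorized over ``eps``.

    Used directly by the solver; `polarizability` wraps it for users.
    """
    eps = np.asarray(eps, dtype=complex)
    denom = eps + 2.0
    if np.any(np.abs(denom) < 1e-14):
        raise NumericError("polarizability: ε = −2 is a Clausius–Mossotti pole")
    a_cm = (3.0 * d**3 / (4.0 * np.pi)) * (eps - 1.0) / denom
    if model == "cm":
        return a_cm
    kd = k * d
    rr = -(2.0 / 3.0) * 1j * kd**3
    if model == "cm_rr":
        return a_cm / (1.0 + (a_cm / d**3) * rr)
    if model == "icd":
        # 1/α = 1/α_CM − M/d³ with M the dynamic self-integral
        M = _dynamic_self_integral(kd)
        return a_cm / (1.0 - (a_cm / d**3) * M)
    if k_hat is not None and e_hat is not None:
        S = float(np.sum((np.asarray(k_hat) * np.asarray(e_hat)) ** 2))
    else:
        S = _LDR_S_ISO
    corr = (_LDR_B1 + eps * _LDR_B2 + eps * _LDR_B3 * S) * kd**2 + rr
    return a_cm / (1.0 + (a_cm / d**3) * corr)


#: Shipped single-frequency materials.  The skin entries are nominal
#: X-band (10 GHz) values from the Gabriel parametric tissue model that
#: underlies the public tissue-properties databases; the "bat_effective"
#: entry is the published body-averaged value for Brazilian free-tailed
#: bat tissue and is the default scatterer material throughout.
TISSUE_TABLE = {
    "vacuum": Material(1.0 + 0.0j, "vacuum"),
    "bat_effective": Material(29.29 - 12.89j, "bat_effective"),
    "skin_dry_10ghz": Material(31.29 - 13.84j, "skin_dry_10ghz"),
    "skin_wet_10ghz": Material(42.85 - 16.90j, "skin_wet_10ghz"),
    "water_10ghz": Material(62.0 - 29.0j, "water_10ghz"),
}


def tissue_default(name: str) -> Material:
    """Look up a shipped material by name."""
    try:
        return TISSUE_TABLE[name]
    except KeyError:
        raise MaterialLookupError(
            f"unknown material {name!r}; shipped: {sorted(TISSUE_TABLE)}"
        ) from None
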