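"""Dilute-limit hydrodynamics of triaxial ellipsoids.

Translational and rotational diffusion constants along/about each semi-axis
of a hydrated triaxial ellipsoid follow Perrin-type expressions written with
Carlson symmetric elliptic integrals, e.g. for the a-axis

    D_ta = kT/(6πη) (3 R_F(a'²,b'²,c'²) + R_D(b'²,c'²,a'²) a'²)/4,
    D_ra = kT/(8πη) (R_D(c'²,a'²,b'²) b'² + R_D(a'²,b'²,c'²) c'²)/(b'²+c'²),

where a', b', c' are the semi-axes dilated by a stationary hydration layer
δH (2.32 Å for structures without hydrogens, 2.30 Å with).  The orientation-
averaged (long-time) constants are the arithmetic axis means, and the
translational mean collapses to the shape-reduced identity

    D_t = kT/(6πη r') R_F(a'²/r'², b'²/r'², c'²/r'²),   r' = (a'b'c')^{1/3}.

Inputs are Å / K / mPa·s; outputs cm²/s and s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .shape_core import EquivalentEllipsoid

__all__ = [
    "BOLTZMANN_J_PER_K", "HYDRATION_NO_H", "HYDRATION_WITH_H",
    "HydroResult", "carlson_rf", "carlson_rd", "dilute_diffusion",
    "translational_mean_reduced", "scaling_law_fit", "cell_scaling_prefactor",
    "hydration_shell", "surface_point_diffusion", "semi_axes_from_shape",
]

BOLTZMANN_J_PER_K = 1.380649e-23
HYDRATION_NO_H = 2.32     # Å, for structures lacking hydrogens
HYDRATION_WITH_H = 2.30   # Å
BOUND_WATER_DENSITY = 1.104  # g/mL
WATER_MOLAR_MASS = 18.015    # g/mol
AVOGADRO = 6.02214076e23

_A2_TO_M2 = 1e-20   # Å² -> m²
_M2S_TO_CM2S = 1e4  # m²/s -> cm²/s


def carlson_rf(x: float, y: float, z: float) -> float:
    """Carlson symmetric elliptic integral of the first kind R_F(x, y, z).

    R_F = (1/2) ∫0∞ dλ / sqrt((x+λ)(y+λ)(z+λ)); homogeneous of degree -1/2.
    Arguments must be non-negative with at most one zero.
    """
    if min(x, y, z) < 0 or sorted((x, y, z))[1] == 0:
        raise ValueError("R_F requires nonnegative arguments, at most one zero")
    return float(special.elliprf(x, y, z))


def carlson_rd(x: float, y: float, z: float) -> float:
    """Carlson integral of the second kind R_D(x, y, z), degree -3/2.

    R_D = (3/2) ∫0∞ dλ / ((z+λ) sqrt((x+λ)(y+λ)(z+λ))); requires z > 0.
    """
    if x < 0 or y < 0 or z <= 0 or (x == 0 and y == 0):
        raise ValueError("R_D requires x,y >= 0 (not both 0) and z > 0")
    return float(special.elliprd(x, y, z))


@dataclass(frozen=True)
class HydroResult:
    """Dilute diffusion constants of a hydrated triaxial ellipsoid."""

    dt_axes: np.ndarray      # (3,) cm²/s, translation along a, b, c
    dr_axes: np.ndarray      # (3,) s⁻¹, rotation about a, b, c
    temperature: float       # K
    viscosity: float         # mPa·s
    delta_h: float           # Å
    hydrated_axes: np.ndarray  # (3,) Å: a', b', c'

    @property
    def dt_mean(self) -> float:
        """Orientation-averaged translational diffusion (cm²/s)."""
        return float(self.dt_axes.mean())

    @property
    def dr_mean(self) -> float:
        """Axis-mean rotational diffusion (s⁻¹)."""
        return float(self.dr_axes.mean())

    @property
    def r_prime(self) -> float:
        """Geometric-mean hydrated radius (a'b'c')^(1/3), Å."""
        return float(np.prod(self.hydrated_axes) ** (1.0 / 3.0))


def _perrin_constants(axes_A: np.ndarray, temperature: float, viscosity: float):
    """Per-axis D_t (cm²/s) and D_r (s⁻¹) for semi-axes in Å."""
    a2, b2, c2 = (np.asarray(axes_A, float) * 1e-10) ** 2   # m²
    kt = BOLTZMANN_J_PER_K * temperature
    eta = viscosity * 1e-3                                  # Pa·s
    rf = carlson_rf(a2, b2, c2)
    rd_a = carlson_rd(b2, c2, a2)
    rd_b = carlson_rd(c2, a2, b2)
    rd_c = carlson_rd(a2, b2, c2)
    dt = kt / (6.0 * math.pi * eta) * np.array([
        (3.0 * rf + rd_a * a2) / 4.0,
        (3.0 * rf + rd_b * b2) / 4.0,
        (3.0 * rf + rd_c * c2) / 4.0,
    ]) * _M2S_TO_CM2S
    dr = kt / (8.0 * math.pi * eta) * np.array([
        (rd_b * b2 + rd_c * c2) / (b2 + c2),
        (rd_c * c2 + rd_a * a2) / (c2 + a2),
        (rd_a * a2 + rd_b * b2) / (a2 + b2),
    ])
    return dt, dr


def dilute_diffusion(
    ell: EquivalentEllipsoid,
    delta_h: float | None = None,
    temperature: float = 293.15,
    viscosity: float = 1.0016,
    has_hydrogens: bool = False,
) -> HydroResult:
    """Hydrated dilute-limit diffusion constants of an equivalent ellipsoid.

    ``delta_h`` defaults to 2.30 Å when the source structure carried
    hydrogens and 2.32 Å otherwise.
    """
    if delta_h is None:
        delta_h = HYDRATION_WITH_H if has_hydrogens else HYDRATION_NO_H
    if delta_h < 0:
        raise ValueError("hydration layer must be nonnegative")
    axes = ell.semi_axes + delta_h
    dt, dr = _perrin_constants(axes, temperature, viscosity)
    return HydroResult(dt, dr, temperature, viscosity, delta_h, axes)


def translational_mean_reduced(
    alpha: float, beta: float, r_prime_A: float,
    temperature: float = 293.15, viscosity: float = 1.0016,
) -> float:
    """Mean D_t (cm²/s) from shape (α', β') and reduced radius r' directly.

    D_t = kT/(6πη r') R_F((α'^{2-β'})^{2/3}, (α'^{2β'-1})^{2/3}, (α'^{β'+1})^{-2/3});
    the independent code path used to cross-check the per-axis mean.
    """
    kt = BOLTZMANN_J_PER_K * temperature
    eta = viscosity * 1e-3
    rp = r_prime_A * 1e-10
    rf = carlson_rf(
        alpha ** (2.0 * (2.0 - beta) / 3.0),
        alpha ** (2.0 * (2.0 * beta - 1.0) / 3.0),
        alpha ** (-2.0 * (beta + 1.0) / 3.0),
    )
    return kt / (6.0 * math.pi * eta * rp) * rf * _M2S_TO_CM2S


def semi_axes_from_shape(alpha: float, beta: float, r_prime_A: float) -> np.ndarray:
    """Semi-axes (Å) of the ellipsoid with shape (α, β) and (abc)^{1/3} = r'."""
    c = r_prime_A * alpha ** (-(1.0 + beta) / 3.0)
    return np.array([c * alpha, c * alpha ** beta, c])


def scaling_law_fit(
    alpha: float = 1.65,
    beta: float = 0.34,
    volume_per_dalton: float = 2.39,
    temperature: float = 293.15,
    viscosity: float = 1.0016,
    mass_range_kda: tuple[float, float] = (10.0, 1000.0),
    n_masses: int = 40,
) -> dict:
    """Fit power-law mass scalings of dilute diffusion for a fixed shape.

    For each protein mass M_p on a log grid, the hydrated equivalent-ellipsoid
    volume is taken as (4π/3) r'³ = ``volume_per_dalton``·M_p Å³ with shape
    (α', β'); the Perrin means are fitted in log-log space to
    c_t·M_p^{-1/3} (translational) and c_r·M_p^{-1} (rotational).

    Returns prefactors ``ct`` in 1e-7 cm²/s·Da^{1/3} and ``cr`` in
    1e7 s⁻¹·Da, with the mass grid and predicted constants.
    """
    masses = np.logspace(math.log10(mass_range_kda[0] * 1e3),
                         math.log10(mass_range_kda[1] * 1e3), n_masses)
    r_primes = (3.0 * volume_per_dalton * masses / (4.0 * math.pi)) ** (1.0 / 3.0)
    dt = np.empty_like(masses)
    dr = np.empty_like(masses)
    for i, rp in enumerate(r_primes):
        axes = semi_axes_from_shape(alpha, beta, rp)
        ell = EquivalentEllipsoid.from_semi_axes(*axes)
        res = dilute_diffusion(ell, delta_h=0.0, temperature=temperature,
                               viscosity=viscosity)
        dt[i] = res.dt_mean
        dr[i] = res.dr_mean
    ct = math.exp(np.mean(np.log(dt) + np.log(masses) / 3.0))
    cr = math.exp(np.mean(np.log(dr) + np.log(masses)))
    return {
        "ct_1e-7cm2_s": ct / 1e-7,
        "cr_1e7_s": cr / 1e7,
        "masses_da": masses,
        "dt_cm2_s": dt,
        "dr_s": dr,
    }


def cell_scaling_prefactor(
    phi: float = 0.19,
    phi_c: float = 0.58,
    temperature: float = 310.15,
    viscosity: float = 0.6913,
    **scaling_kwargs,
) -> float:
    """Crowded in-cell prefactor of D_t ≈ c/M_p^{1/3} (1e-7 cm²/s units).

    The dilute prefactor at the given solvent conditions is attenuated by the
    long-time self-diffusion ratio at volume fraction ``phi`` with the given
    critical volume fraction ``phi_c`` (an explicit parameter: plausible
    values 0.58-0.64 move the attenuation between ~0.34 and ~0.37).
    """
    from .crowding import long_time_ratio
    dilute = scaling_law_fit(temperature=temperature, viscosity=viscosity,
                             **scaling_kwargs)["ct_1e-7cm2_s"]
    return dilute * long_time_ratio(phi, phi_c)


def hydration_shell(ell: EquivalentEllipsoid, delta_h: float = 2.3,
                    protein_mass_da: float | None = None) -> dict:
    """Hydration-shell volume, bound-water count, and hydration level.

    The shell is the dilated minus the dry equivalent-ellipsoid volume; water
    in the shell is taken at 1.104 g/mL.  ``grams_per_gram`` requires the
    protein mass.
    """
    shell = ell.dilate(delta_h).volume - ell.volume          # Å³
    mass_g = shell * 1e-24 * BOUND_WATER_DENSITY             # g
    waters = mass_g / WATER_MOLAR_MASS * AVOGADRO
    out = {"shell_volume_A3": shell, "n_waters": waters}
    if protein_mass_da is not None:
        out["grams_per_gram"] = mass_g / (protein_mass_da / AVOGADRO)
    return out


def surface_point_diffusion(
    ell: EquivalentEllipsoid,
    hydro: HydroResult,
    theta_deg: float,
    phi_deg: float,
) -> float:
    """Short-time effective translational diffusion of a surface point (cm²/s).

    D_tp ≈ D_t + (1/3)[D_ra(y²+z²) + D_rb(x²+z²) + D_rc(x²+y²)] for the
    body-frame surface point (x, y, z) at angles (θ, φ_s); rotation about
    each axis sweeps the point on a circle of the corresponding radius.
    """
    from .surface_mapping import surface_point
    x, y, z = surface_point(ell, theta_deg, phi_deg) * 1e-8   # Å -> cm
    dra, drb, drc = hydro.dr_axes
    return hydro.dt_mean + (dra * (y * y + z * z)
                            + drb * (x * x + z * z)
                            + drc * (x * x + y * y)) / 3.0
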