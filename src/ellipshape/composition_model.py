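"""Size and shape of globular proteins from sequence composition alone.

The equivalent-ellipsoid volume of a protein scales with chain length as
V ≈ 203·N Å³ and its surface area with the number of surface residues as
A ≈ 47·N_s Å².  N_s can be estimated from composition as Σ n_t·p_t with p_t
a per-type surface propensity.  Because the Knud Thomsen area model ties
(V, A) to a unique aspect ratio α for each β, the shape of a protein follows
from composition: chains keeping a fixed surface fraction f = N_s/N can only
stay quasi-spherical above a minimum length

    N_min = 36π v² / (f³ s³)   (= 270 for v = 203, s = 47, f = 0.55),

and longer chains must become elliptical.  A binary surface/core (HP-like)
model, whose modal composition is N_s = N/2, and the response of α to
surface/core insertions, deletions and swaps are also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .shape_core import surface_area_model

__all__ = [
    "VOLUME_PER_RESIDUE", "AREA_PER_SURFACE_RESIDUE", "DEFAULT_SURFACE_FRACTION",
    "SYNTHETIC_PROPENSITY", "CompositionProfile", "predict_size",
    "alpha_from_composition", "minimum_length", "hp_model",
    "mutation_accommodation",
]

VOLUME_PER_RESIDUE = 203.0        # Å³ per residue
AREA_PER_SURFACE_RESIDUE = 47.0   # Å² per surface residue
DEFAULT_SURFACE_FRACTION = 0.55   # modal N_s/N in globular proteins

#: Synthetic per-type surface propensities (probability a residue of the
#: type sits at the surface).  These are plausibility-ranked placeholder
#: values for fixture work, NOT a measured scale: polar/charged types high,
#: hydrophobic core types low, with 11 of the 20 types above 0.5 and an
#: average near 0.55.  Supply a measured table for real analyses.
SYNTHETIC_PROPENSITY = {
    "LYS": 0.85, "GLU": 0.82, "ASP": 0.78, "ARG": 0.75, "GLN": 0.72,
    "ASN": 0.70, "PRO": 0.68, "SER": 0.62, "THR": 0.60, "HIS": 0.58,
    "GLY": 0.55, "ALA": 0.48, "TYR": 0.45, "TRP": 0.35, "MET": 0.32,
    "LEU": 0.28, "CYS": 0.25, "VAL": 0.24, "ILE": 0.22, "PHE": 0.20,
}


@dataclass
class CompositionProfile:
    """Residue-type counts with surface propensities and size estimates."""

    counts: dict[str, int]
    propensity: dict[str, float] = field(default_factory=lambda: dict(SYNTHETIC_PROPENSITY))

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative residue counts")
        if any(not (0.0 <= p <= 1.0) for p in self.propensity.values()):
            raise ValueError("propensities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def n_surface(self) -> float:
        """N_s estimate: Σ counts_t × propensity_t."""
        missing = [t for t in self.counts if t not in self.propensity]
        if missing:
            raise KeyError(f"no propensity for residue types: {missing}")
        return sum(n * self.propensity[t] for t, n in self.counts.items())


def predict_size(profile: CompositionProfile) -> tuple[float, float]:
    """(V, A) in (Å³, Å²) from V = 203·N and A = 47·N_s."""
    if profile.n < 1:
        raise ValueError("empty composition")
    return (VOLUME_PER_RESIDUE * profile.n,
            AREA_PER_SURFACE_RESIDUE * profile.n_surface)


def sphere_area(volume: float) -> float:
    return (36.0 * math.pi * volume ** 2) ** (1.0 / 3.0)


def alpha_from_composition(volume: float, area: float, beta: float = 0.34,
                           alpha_max: float = 50.0, tol: float = 1e-9) -> float:
    """Aspect ratio α of the ellipsoid with the given volume, area and β.

    Inverts the Knud Thomsen area model by bracketed root finding on
    α ∈ [1, alpha_max]; the area model is strictly increasing in α so the
    root is unique.  Areas below the equal-volume sphere are infeasible.
    """
    a_min = sphere_area(volume)
    if area < a_min * (1.0 - 1e-12):
        raise ValueError(f"sub-spherical area: A={area:.6g} < sphere {a_min:.6g}")
    if area <= a_min * (1.0 + 1e-12):
        return 1.0

    def f(alpha: float) -> float:
        return surface_area_model(alpha, beta, volume) - area

    if f(alpha_max) < 0:
        raise ValueError(f"area too large for alpha <= {alpha_max}")
    return float(brentq(f, 1.0, alpha_max, xtol=tol, rtol=8.9e-16))


def minimum_length(surface_fraction: float = DEFAULT_SURFACE_FRACTION,
                   v: float = VOLUME_PER_RESIDUE,
                   s: float = AREA_PER_SURFACE_RESIDUE) -> int:
    """Shortest chain able to stay spherical at a fixed surface fraction.

    N_min = 36π v²/(f³ s³): below this the predicted area 47·f·N falls short
    of the equal-volume sphere's area, so smaller proteins need a higher
    prevalence of surface-preferring residues.  Defaults give 270.
    """
    if not (0.0 < surface_fraction <= 1.0) or v <= 0 or s <= 0:
        raise ValueError("require f in (0,1] and positive constants")
    return round(36.0 * math.pi * v ** 2 / (surface_fraction ** 3 * s ** 3))


def minimum_length_exact(surface_fraction: float = DEFAULT_SURFACE_FRACTION,
                         v: float = VOLUME_PER_RESIDUE,
                         s: float = AREA_PER_SURFACE_RESIDUE) -> float:
    """Unrounded minimum chain length (see :func:`minimum_length`)."""
    return 36.0 * math.pi * v ** 2 / (surface_fraction ** 3 * s ** 3)


def hp_model(n: int, beta_grid=None) -> dict:
    """Binary surface(P)/core(H) chain model of protein shape.

    The binomial mode puts half the residues at the surface (N_s = N/2);
    the resulting (V, A) = (203 N, 47 N/2) fixes α for every β.  Chains
    shorter than the f = 0.5 minimum length are sub-spherical and flagged
    (α reported as NaN there).
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    if beta_grid is None:
        beta_grid = np.linspace(0.0, 1.0, 21)
    beta_grid = np.asarray(beta_grid, float)
    n_s = round(n / 2)
    volume = VOLUME_PER_RESIDUE * n
    area = AREA_PER_SURFACE_RESIDUE * n_s
    feasible = area >= sphere_area(volume) * (1.0 - 1e-12)
    alphas = np.full(beta_grid.size, np.nan)
    if feasible:
        for k, b in enumerate(beta_grid):
            alphas[k] = alpha_from_composition(volume, area, float(b))
    return {"n_surface": n_s, "volume": volume, "area": area,
            "beta": beta_grid, "alpha": alphas, "feasible": feasible}


def mutation_accommodation(n: int, n_s: float, edit: str, k: int,
                           beta: float = 0.34) -> dict:
    """Change in aspect ratio accommodating composition edits.

    ``edit`` is "surface" (insert/delete k surface residues; k may be
    negative), "core" (insert/delete buried residues), or "swap" (move k
    residues core→surface for k > 0, surface→core for k < 0; N fixed).
    Returns the new α and Δα, flagging infeasible (sub-spherical) outcomes.
    """
    if edit == "surface":
        n2, ns2 = n + k, n_s + k
    elif edit == "core":
        n2, ns2 = n + k, n_s
    elif edit == "swap":
        n2, ns2 = n, n_s + k
    else:
        raise ValueError("edit must be 'surface', 'core' or 'swap'")
    if n2 < 1 or not (0 <= ns2 <= n2):
        raise ValueError("edit leaves an impossible composition")
    v2 = VOLUME_PER_RESIDUE * n2
    a2 = AREA_PER_SURFACE_RESIDUE * ns2
    alpha0 = alpha_from_composition(VOLUME_PER_RESIDUE * n,
                                    AREA_PER_SURFACE_RESIDUE * n_s, beta)
    if a2 < sphere_area(v2) * (1.0 - 1e-12):
        return {"alpha": float("nan"), "delta_alpha": float("nan"),
                "feasible": False, "alpha_before": alpha0}
    alpha1 = alpha_from_composition(v2, a2, beta)
    return {"alpha": alpha1, "delta_alpha": alpha1 - alpha0,
            "feasible": True, "alpha_before": alpha0}
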