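"""Synthetic structural fixtures: ellipsoidal atom clouds, dimers, scalars.

Generates every input the pipeline needs without downloads: uniform-density
atom clouds filling a prescribed triaxial ellipsoid at protein-like packing
(~3.1 Å equivalent radius per residue at density 0.64), touching-ellipsoid
dimer pairs with known contact geometry, and per-residue scalar tables with
prescribed spatial patterns (uniform, low at a c-pole, radial gradient).
All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition_model import SYNTHETIC_PROPENSITY, VOLUME_PER_RESIDUE
from .structure_io import VDW_RADII, AtomCloud, ResidueScalarTable

__all__ = ["GeneratorSpec", "make_ellipsoid_cloud", "make_dimer",
           "make_residue_scalars", "ELEMENT_FREQUENCIES"]

#: Heavy-atom element mixture (roughly protein-like C:N:O:S).
ELEMENT_FREQUENCIES = {"C": 0.62, "N": 0.17, "O": 0.20, "S": 0.01}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic ellipsoidal atom cloud."""

    semi_axes: tuple[float, float, float]   # Å, a >= b >= c
    n_residues: int = 125
    atoms_per_residue: int = 8
    density: float = 0.64                   # packing fraction emulated
    residue_types: tuple[str, ...] = tuple(SYNTHETIC_PROPENSITY)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        if not (0.0 < self.density <= 0.74):
            raise ValueError("density must be in (0, 0.74]")
        if self.n_residues < 1 or self.atoms_per_residue < 1:
            raise ValueError("need at least one residue and atom per residue")

    @property
    def n_atoms(self) -> int:
        return self.n_residues * self.atoms_per_residue

    @classmethod
    def for_protein(cls, n_residues: int, alpha: float = 1.65,
                    beta: float = 0.34, **kw) -> "GeneratorSpec":
        """Spec with protein-like volume V = 203·N and shape (α, β)."""
        volume = VOLUME_PER_RESIDUE * n_residues
        c = (3.0 * volume / (4.0 * math.pi * alpha ** (1.0 + beta))) ** (1.0 / 3.0)
        return cls((alpha * c, alpha ** beta * c, c), n_residues=n_residues, **kw)


def _uniform_in_ellipsoid(rng: np.random.Generator, n: int,
                          axes: np.ndarray) -> np.ndarray:
    """n points uniform in the ellipsoid with the given semi-axes."""
    g = rng.normal(size=(n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return g * r * axes


def make_ellipsoid_cloud(spec: GeneratorSpec, chain_id: str = "A",
                         centre=(0.0, 0.0, 0.0)) -> AtomCloud:
    """Uniform-density atom cloud filling the target ellipsoid.

    Elements are drawn from a protein-like C/N/O/S mixture; the first atom
    of each residue is a flagged Cα (carbon).  Residue types are drawn
    uniformly from ``spec.residue_types``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    coords = _uniform_in_ellipsoid(rng, n, np.asarray(spec.semi_axes, float))
    coords += np.asarray(centre, float)
    els = rng.choice(list(ELEMENT_FREQUENCIES), size=n,
                     p=list(ELEMENT_FREQUENCIES.values())).astype(object)
    res_index = np.repeat(np.arange(1, spec.n_residues + 1), spec.atoms_per_residue)
    is_ca = np.zeros(n, bool)
    is_ca[::spec.atoms_per_residue] = True
    els[is_ca] = "C"
    types = rng.choice(list(spec.residue_types), size=spec.n_residues)
    res_name = np.repeat(types, spec.atoms_per_residue).astype(object)
    radii = np.array([VDW_RADII[e] for e in els])
    return AtomCloud(els, coords, radii, res_index, res_name,
                     np.full(n, chain_id, dtype=object), is_ca,
                     source=f"synthetic ellipsoid {spec.semi_axes}")


def _surface_radius(axes, direction) -> float:
    """Distance from centre to surface along a unit direction."""
    d = np.asarray(direction, float)
    return 1.0 / math.sqrt(float(np.sum((d / np.asarray(axes)) ** 2)))


def make_dimer(spec_a: GeneratorSpec, spec_b: GeneratorSpec,
               contact_direction=(1.0, 0.0, 0.0)) -> tuple[AtomCloud, dict]:
    """Two touching ellipsoidal clouds (chains A and B) with known contact.

    Both bodies are axis-aligned; B's centre is placed along the requested
    body-frame direction of A at external tangency of the two target
    ellipsoids.  Returns the merged cloud and the ground-truth contact
    geometry ((θ, φ_s) on each body, centre separation).
    """
    d = np.asarray(contact_direction, float)
    d = d / np.linalg.norm(d)
    ta = _surface_radius(spec_a.semi_axes, d)
    tb = _surface_radius(spec_b.semi_axes, -d)
    centre_b = (ta + tb) * d
    cloud_a = make_ellipsoid_cloud(spec_a, chain_id="A")
    cloud_b = make_ellipsoid_cloud(
        GeneratorSpec(spec_b.semi_axes, spec_b.n_residues, spec_b.atoms_per_residue,
                      spec_b.density, spec_b.residue_types, spec_b.seed + 1),
        chain_id="B", centre=centre_b)
    res_b = cloud_b.res_index + spec_a.n_residues
    merged = AtomCloud(
        np.concatenate([cloud_a.elements, cloud_b.elements]),
        np.vstack([cloud_a.coords, cloud_b.coords]),
        np.concatenate([cloud_a.radii, cloud_b.radii]),
        np.concatenate([cloud_a.res_index, res_b]),
        np.concatenate([cloud_a.res_name, cloud_b.res_name]),
        np.concatenate([cloud_a.chain_id, cloud_b.chain_id]),
        np.concatenate([cloud_a.is_ca, cloud_b.is_ca]),
        source="synthetic dimer",
    )

    def angles(direction):
        r = float(np.linalg.norm(direction))
        theta = math.degrees(math.acos(max(-1.0, min(1.0, direction[0] / r))))
        phi = math.degrees(math.atan2(direction[2], direction[1])) % 360.0
        return theta, phi

    truth = {"theta_phi_A": angles(d), "theta_phi_B": angles(-d),
             "separation": ta + tb, "contact_point": ta * d}
    return merged, truth


def make_residue_scalars(
    cloud: AtomCloud,
    pattern: str = "uniform",
    seed: int = 0,
    surface_contrast: float = 2.0,
    core_contrast: float = 4.0,
    noise: float = 0.05,
    pole_radius_deg: float = 45.0,
    surface_m: float = 0.75,
) -> ResidueScalarTable:
    """Per-residue scalars with a prescribed spatial pattern.

    Patterns (values are relative rates; 1 is the baseline):

    - ``uniform``: all residues equal.
    - ``c-pole-low``: surface residues within ``pole_radius_deg`` of the
      c-pole at (θ=90°, φ_s=90°) carry 1/``surface_contrast`` of the other
      surface residues' value (emulating a conserved interface patch).
    - ``radial-gradient``: value rises linearly with fractional radial
      extent m from 1/``core_contrast`` at the centre to 1 at the surface
      (emulating slower-evolving cores).

    Multiplicative log-normal noise of width ``noise`` is applied
    (deterministic under ``seed``; set 0 to disable).
    """
    from .shape_core import ellipsoid_of_cloud, fractional_radial_extent
    rng = np.random.default_rng(seed)
    ell = ellipsoid_of_cloud(cloud)
    extent = fractional_radial_extent(cloud, ell)
    ca = cloud.ca_cloud()
    body = ell.to_body_frame(ca.coords)
    pole = np.array([0.0, 0.0, 1.0])   # c-pole direction (θ=90°, φ_s=90°)
    values = {}
    types = {}
    for k, idx in enumerate(ca.res_index):
        idx = int(idx)
        m = float(extent.values[idx])
        if pattern == "uniform":
            v = 1.0
        elif pattern == "c-pole-low":
            v = 1.0
            if m >= surface_m:
                direction = body[k] / max(np.linalg.norm(body[k]), 1e-12)
                ang = math.degrees(math.acos(max(-1.0, min(1.0, float(direction @ pole)))))
                if ang <= pole_radius_deg:
                    v = 1.0 / surface_contrast
        elif pattern == "radial-gradient":
            v = 1.0 / core_contrast + (1.0 - 1.0 / core_contrast) * min(m, 1.0)
        else:
            raise ValueError("pattern must be uniform, c-pole-low or radial-gradient")
        if noise > 0:
            v *= math.exp(rng.normal(0.0, noise))
        values[idx] = v
        types[idx] = str(ca.res_name[k])
    return ResidueScalarTable(pd.Series(values), res_types=types)
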