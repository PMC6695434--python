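"""Shape of atomic structures as equivalent steric ellipsoids.

A protein is modelled as a set of solid vdW spheres of unit density.  The
moment-of-inertia tensor of that body,

    I = (4π/3) Σ_i r_i³ [[y²+z²+(2/5)r², -xy, -xz], ...],

is diagonalised and matched to the uniform triaxial ellipsoid with the same
inertia — the *ellipsoid of equivalent steric volume* — whose semi-axes
a ≥ b ≥ c follow from the eigenvalues λ1 ≥ λ2 ≥ λ3 as

    a = sqrt(5 (λ1+λ2-λ3) / (2M)),   (and cyclic)

with M = Σ (4π/3) r_i³ the steric volume.  Shape is summarised by the pair
(α, β) with α = a/c and α^β = b/c, so β runs from 0 (prolate spheroid) to 1
(oblate spheroid).  The module also provides Feret (calliper) diameters over
a 1° rotation scan, the Knud Thomsen surface-area approximation in (α, β, V)
form, a nematic-style order parameter, fractional radial extents of alpha
carbons, and Gaussian-smoothed (α, β) shape distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .structure_io import AtomCloud, ResidueScalarTable

__all__ = [
    "EquivalentEllipsoid", "ShapeAB", "CalliperResult",
    "inertia_tensor", "steric_volume", "equivalent_ellipsoid",
    "ellipsoid_of_cloud", "shape_ab", "beta_boundary", "calliper",
    "surface_area_model", "isoperimetric_quotient", "order_parameter",
    "fractional_radial_extent", "shape_distribution",
    "CALLIPER_MAX_RELATIVE_ERROR",
]

#: Relative discretization error bound of the 1°-step calliper scan.
CALLIPER_MAX_RELATIVE_ERROR = 1.0 - math.cos(math.pi / 180.0)


@dataclass(frozen=True)
class EquivalentEllipsoid:
    """Uniform ellipsoid with the inertia of the vdW-sphere body.

    ``rotation`` is orthonormal with det +1; its *columns* are the principal
    axes in the world frame, a-axis first.  ``volume_m`` is the steric volume
    M = Σ (4π/3) r³ (Å³), which by construction equals (4π/3)abc.
    """

    a: float
    b: float
    c: float
    rotation: np.ndarray
    centroid: np.ndarray
    volume_m: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b >= self.c > 0):
            raise ValueError("require a >= b >= c > 0")
        R = np.asarray(self.rotation, float)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-8 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal and right-handed")

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def volume(self) -> float:
        """(4π/3)abc; equals volume_m by the equivalence identity."""
        return 4.0 * math.pi / 3.0 * self.a * self.b * self.c

    def to_body_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> body frame (x along a, y along b, z along c)."""
        return (np.atleast_2d(points) - self.centroid) @ self.rotation

    def to_world_frame(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.centroid

    def dilate(self, delta: float) -> "EquivalentEllipsoid":
        """Grow every semi-axis by ``delta`` Å (hydration layer)."""
        a, b, c = self.a + delta, self.b + delta, self.c + delta
        return EquivalentEllipsoid(a, b, c, self.rotation, self.centroid,
                                   4.0 * math.pi / 3.0 * a * b * c)

    @classmethod
    def from_semi_axes(cls, a: float, b: float, c: float) -> "EquivalentEllipsoid":
        """Axis-aligned ellipsoid at the origin (convenience constructor)."""
        return cls(a, b, c, np.eye(3), np.zeros(3), 4.0 * math.pi / 3.0 * a * b * c)


@dataclass(frozen=True)
class ShapeAB:
    """(α, β) shape descriptor: α = a/c, α^β = b/c."""

    alpha: float
    beta: float          # NaN for a sphere (undefined exponent)
    shape_class: str     # "prolate" | "oblate" | "sphere"


@dataclass(frozen=True)
class CalliperResult:
    """Max/min Feret diameters (Å) over the rotational scan."""

    max_diameter: float
    min_diameter: float

    @property
    def ratio(self) -> float:
        return self.max_diameter / self.min_diameter


def _weights(cloud: AtomCloud) -> np.ndarray:
    return 4.0 * math.pi / 3.0 * cloud.radii ** 3


def steric_volume(cloud: AtomCloud) -> float:
    """M = Σ (4π/3) r_i³ in Å³."""
    return float(_weights(cloud).sum())


def inertia_tensor(cloud: AtomCloud) -> np.ndarray:
    """Inertia of the unit-density vdW-sphere body about its centroid.

    Each atom contributes as a solid sphere: weight (4π/3)r³ times the
    point-mass dyadic plus the (2/5)r² diagonal self term.  Coordinates are
    re-centred to the volume-weighted centroid before evaluation.
    """
    if len(cloud) == 0:
        raise ValueError("empty AtomCloud")
    w = _weights(cloud)
    centroid = w @ cloud.coords / w.sum()
    x = cloud.coords - centroid
    r2 = np.einsum("ij,ij->i", x, x)
    tensor = np.einsum("i,ij,ik->jk", -w, x, x)
    diag = w @ (r2[:, None] + 0.4 * cloud.radii[:, None] ** 2)
    tensor[np.diag_indices(3)] += diag
    return tensor


def _canonical_axes(eigvecs_desc: np.ndarray) -> np.ndarray:
    """Columns [a, b, c] with a deterministic sign convention, det +1.

    a-axis is the eigenvector of the *smallest* eigenvalue, c of the largest.
    The first nonzero component of the a and b axes is made positive and the
    c axis completes a right-handed triad.
    """
    a_axis = eigvecs_desc[:, 2].copy()
    b_axis = eigvecs_desc[:, 1].copy()
    for v in (a_axis, b_axis):
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v *= -1.0
    c_axis = np.cross(a_axis, b_axis)
    return np.column_stack([a_axis, b_axis, c_axis])


def equivalent_ellipsoid(
    tensor: np.ndarray,
    volume_m: float,
    centroid: np.ndarray | None = None,
) -> EquivalentEllipsoid:
    """Solve the inertia tensor for the equivalent ellipsoid's semi-axes."""
    if volume_m <= 0:
        raise ValueError("steric volume must be positive")
    tensor = np.asarray(tensor, float)
    if np.linalg.norm(tensor - tensor.T) > 1e-8 * max(1.0, np.abs(tensor).max()):
        raise ValueError("inertia tensor must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(tensor)      # ascending
    lam = eigvals[::-1]                            # λ1 >= λ2 >= λ3
    vecs = eigvecs[:, ::-1]
    if lam[1] + lam[2] - lam[0] <= 0:
        raise ValueError("non-ellipsoidal inertia (degenerate planar body)")
    scale = 5.0 / (2.0 * volume_m)
    a = math.sqrt(scale * (lam[0] + lam[1] - lam[2]))
    b = math.sqrt(scale * (lam[0] + lam[2] - lam[1]))
    c = math.sqrt(scale * (lam[1] + lam[2] - lam[0]))
    rotation = _canonical_axes(vecs)
    if centroid is None:
        centroid = np.zeros(3)
    return EquivalentEllipsoid(a, b, c, rotation, np.asarray(centroid, float), volume_m)


def ellipsoid_of_cloud(cloud: AtomCloud) -> EquivalentEllipsoid:
    """Equivalent steric ellipsoid of an atom cloud (tensor + volume in one)."""
    w = _weights(cloud)
    centroid = w @ cloud.coords / w.sum()
    return equivalent_ellipsoid(inertia_tensor(cloud), steric_volume(cloud), centroid)


def beta_boundary(alpha: float) -> float:
    """β separating generally prolate (below) from oblate (above) ellipsoids.

    β_boundary = (ln(α+1) - ln 2) / ln α, the locus where b is the arithmetic
    midpoint of a and c.  The curve rises from its α→1 limit of 1/2 toward 1
    for elongated shapes.
    """
    if alpha <= 1.0:
        return 0.5
    return (math.log(alpha + 1.0) - math.log(2.0)) / math.log(alpha)


def shape_ab(ell: EquivalentEllipsoid, sphere_tol: float = 1e-9) -> ShapeAB:
    """(α, β) of an ellipsoid with prolate/oblate/sphere classification."""
    alpha = ell.a / ell.c
    if alpha <= 1.0 + sphere_tol:
        return ShapeAB(alpha, float("nan"), "sphere")
    beta = math.log(ell.b / ell.c) / math.log(alpha)
    cls = "prolate" if beta < beta_boundary(alpha) else "oblate"
    return ShapeAB(alpha, beta, cls)


def calliper(cloud: AtomCloud, step_deg: float = 1.0) -> CalliperResult:
    """Feret diameters over rotations about x then y in 1° steps on [0, π/2).

    For each orientation the axis-aligned extents (max-min per coordinate,
    padded by the per-atom vdW radius) are recorded; the global largest and
    smallest extents are returned.  The relative discretization error of the
    1° grid is bounded by 1 - cos(π/180) ≈ 0.02%.
    """
    if len(cloud) == 0:
        raise ValueError("empty AtomCloud")
    angles = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    coords = cloud.coords
    r = cloud.radii
    best_max, best_min = -np.inf, np.inf
    cos_y, sin_y = np.cos(angles), np.sin(angles)
    for tx in angles:
        ct, st = math.cos(tx), math.sin(tx)
        # rotate about x: y' = c y - s z ; z' = s y + c z
        X = coords[:, 0]
        Y = ct * coords[:, 1] - st * coords[:, 2]
        Z = st * coords[:, 1] + ct * coords[:, 2]
        ey = (Y + r).max() - (Y - r).min()
        # rotation about y mixes x and z; all angles at once
        XZc = np.outer(cos_y, X) + np.outer(sin_y, Z)      # new x
        ZXc = np.outer(-sin_y, X) + np.outer(cos_y, Z)     # new z
        ex = (XZc + r).max(axis=1) - (XZc - r).min(axis=1)
        ez = (ZXc + r).max(axis=1) - (ZXc - r).min(axis=1)
        ext = np.concatenate([ex, ez, [ey]])
        best_max = max(best_max, ext.max())
        best_min = min(best_min, ext.min())
    return CalliperResult(float(best_max), float(best_min))


def surface_area_model(alpha: float, beta: float, volume: float, p: float = 1.6075) -> float:
    """Knud Thomsen surface-area approximation in (α, β, V) form.

    A ≈ (6√π V / α^{1+β})^{2/3} ((α^{(1+β)p} + α^p + α^{βp})/3)^{1/p},
    exact for the sphere and within ~1.1% of the true ellipsoid area.
    """
    if alpha < 1.0 or volume <= 0:
        raise ValueError("require alpha >= 1 and volume > 0")
    pre = (6.0 * math.sqrt(math.pi) * volume / alpha ** (1.0 + beta)) ** (2.0 / 3.0)
    mean = (alpha ** ((1.0 + beta) * p) + alpha ** p + alpha ** (beta * p)) / 3.0
    return pre * mean ** (1.0 / p)


def isoperimetric_quotient(alpha: float, beta: float) -> float:
    """36πV²/A³ for the shape (α, β); 1 for a sphere, < 1 otherwise."""
    area = surface_area_model(alpha, beta, 1.0)
    return 36.0 * math.pi / area ** 3


def order_parameter(segment_vectors: np.ndarray, a_axis: np.ndarray) -> float:
    """Nematic order S = <1.5 cos²θ - 0.5> of segments against the a-axis.

    Segments are start-to-end vectors of annotated secondary-structure units;
    zero-length vectors are skipped.  S ranges from -0.5 (all perpendicular)
    to 1 (all parallel).
    """
    vecs = np.atleast_2d(np.asarray(segment_vectors, float))
    a_hat = np.asarray(a_axis, float)
    a_hat = a_hat / np.linalg.norm(a_hat)
    norms = np.linalg.norm(vecs, axis=1)
    keep = norms > 0
    if not keep.any():
        raise ValueError("no nonzero segment vectors")
    cos_t = (vecs[keep] @ a_hat) / norms[keep]
    return float(np.mean(1.5 * cos_t ** 2 - 0.5))


def fractional_radial_extent(cloud: AtomCloud, ell: EquivalentEllipsoid) -> ResidueScalarTable:
    """Fractional radial distance m of each residue's Cα from core to surface.

    m = sqrt((x/a)² + (y/b)² + (z/c)²) in the ellipsoid body frame; m = 0 at
    the centroid and m = 1 on the surface.  Residues without a Cα are omitted.
    """
    ca = cloud.ca_cloud()
    if len(ca) == 0:
        raise ValueError("no alpha carbons in cloud")
    body = ell.to_body_frame(ca.coords)
    scaled = body / ell.semi_axes
    m = np.sqrt(np.einsum("ij,ij->i", scaled, scaled))
    values = {}
    types = {}
    for idx, name, mi in zip(ca.res_index, ca.res_name, m):
        values[int(idx)] = float(mi)
        types[int(idx)] = str(name)
    return ResidueScalarTable(pd.Series(values), res_types=types)


def shape_distribution(
    shapes: list[ShapeAB],
    bandwidth: tuple[float, float] = (0.05, 0.05),
    alpha_range: tuple[float, float] = (1.0, 4.0),
    n_alpha: int = 301,
    n_beta: int = 101,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    """Gaussian-smoothed 2D histogram of (α, β) shapes with its modal point.

    Spheres (β undefined) enter at β = 0.5 with α = 1.  Returns
    (alpha_grid, beta_grid, density, (alpha_mode, beta_mode)).
    """
    if not shapes:
        raise ValueError("no shapes")
    alphas = np.array([s.alpha for s in shapes])
    betas = np.array([0.5 if math.isnan(s.beta) else s.beta for s in shapes])
    a_grid = np.linspace(*alpha_range, n_alpha)
    b_grid = np.linspace(0.0, 1.0, n_beta)
    da = a_grid[1] - a_grid[0]
    db = b_grid[1] - b_grid[0]
    hist, _, _ = np.histogram2d(
        alphas, betas,
        bins=[np.append(a_grid - da / 2, a_grid[-1] + da / 2),
              np.append(b_grid - db / 2, b_grid[-1] + db / 2)],
    )
    density = ndimage.gaussian_filter(hist, sigma=(bandwidth[0] / da, bandwidth[1] / db))
    i, j = np.unravel_index(np.argmax(density), density.shape)
    return a_grid, b_grid, density, (float(a_grid[i]), float(b_grid[j]))
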