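"""θφ cartography of ellipsoid surfaces.

A body-frame surface point is parameterized by the polar angle θ from the
a-axis and azimuth φ_s from the b-axis toward c:

    x = t cosθ,  y = t sinθ cosφ_s,  z = t sinθ sinφ_s,
    t = abc / sqrt(b²c² cos²θ + a²c² sin²θ cos²φ_s + a²b² sin²θ sin²φ_s),

so t is the radial distance to the surface along the (θ, φ_s) direction.
Maps are 180×360 images with pixel centres at half-degrees (row i: θ=i+0.5;
column j: φ_s=j+0.5).  Geodesic distances between pixels are approximated by
a shortest-path walk on the pixel lattice (8-connected, wrapped in φ_s) with
step costs equal to the Cartesian distances between neighbouring pixel-centre
surface points.  Contact or residue events are deposited as Gaussian spots of
the geodesic arc distance (default σ = 10° of arc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .shape_core import EquivalentEllipsoid

__all__ = [
    "SurfaceMap", "surface_point", "surface_radius", "invert_surface_point",
    "geodesic_distance_grid", "deposit_gaussian", "pw_contact_function",
    "ellipsoids_overlap", "dimer_contact_centre", "map_residue_values",
    "N_THETA", "N_PHI",
]

N_THETA, N_PHI = 180, 360


def surface_radius(ell: EquivalentEllipsoid, theta_deg, phi_deg):
    """Radial distance t(θ, φ_s) from centre to surface (same units as axes)."""
    a, b, c = ell.a, ell.b, ell.c
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    st, ct = np.sin(th), np.cos(th)
    return a * b * c / np.sqrt(
        b * b * c * c * ct * ct
        + a * a * c * c * (st * np.cos(ph)) ** 2
        + a * a * b * b * (st * np.sin(ph)) ** 2
    )


def surface_point(ell: EquivalentEllipsoid, theta_deg, phi_deg) -> np.ndarray:
    """Body-frame surface point(s) at angles (θ, φ_s) in degrees."""
    t = surface_radius(ell, theta_deg, phi_deg)
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.stack([t * np.cos(th),
                     t * np.sin(th) * np.cos(ph),
                     t * np.sin(th) * np.sin(ph)], axis=-1)


def invert_surface_point(ell: EquivalentEllipsoid, point, tol: float = 1e-6):
    """Angles (θ, φ_s) in degrees of a body-frame surface point.

    Off-surface points are projected radially (with a warning outside
    ``tol``); the angles depend only on the direction, so the projection is
    exact for radial displacement.
    """
    p = np.asarray(point, float)
    scaled = p / ell.semi_axes
    m = math.sqrt(float(scaled @ scaled))
    if abs(m - 1.0) > tol:
        import logging
        logging.getLogger(__name__).warning(
            "point off surface (m=%.6f); projecting radially", m)
    r = math.sqrt(float(p @ p))
    if r == 0.0:
        raise ValueError("cannot invert the centre point")
    theta = math.degrees(math.acos(max(-1.0, min(1.0, p[0] / r))))
    phi = math.degrees(math.atan2(p[2], p[1])) % 360.0
    return theta, phi


def _pixel_centres(ell: EquivalentEllipsoid) -> np.ndarray:
    th = np.arange(N_THETA) + 0.5
    ph = np.arange(N_PHI) + 0.5
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    return surface_point(ell, TH.ravel(), PH.ravel())


_GRAPH_CACHE: dict[tuple, tuple] = {}


def _pixel_graph(ell: EquivalentEllipsoid):
    """Sparse 8-connected pixel graph with Cartesian step costs (cached)."""
    key = (round(ell.a, 9), round(ell.b, 9), round(ell.c, 9))
    hit = _GRAPH_CACHE.get(key)
    if hit is not None:
        return hit
    pts = _pixel_centres(ell)
    n = N_THETA * N_PHI
    idx = np.arange(n).reshape(N_THETA, N_PHI)
    rows, cols = [], []
    for di, dj in ((0, 1), (1, -1), (1, 0), (1, 1)):
        src = idx[:N_THETA - di, :]
        dst = np.roll(idx, -dj, axis=1)[di:, :]
        rows.append(src.ravel())
        cols.append(dst.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.linalg.norm(pts[rows] - pts[cols], axis=1)
    graph = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    out = (graph, pts)
    _GRAPH_CACHE[key] = out
    if len(_GRAPH_CACHE) > 8:
        _GRAPH_CACHE.pop(next(iter(_GRAPH_CACHE)))
    return out


def pixel_of(theta_deg: float, phi_deg: float) -> tuple[int, int]:
    """Pixel (row, col) containing the angles."""
    i = min(N_THETA - 1, max(0, int(theta_deg)))
    j = int(phi_deg) % N_PHI
    return i, j


def geodesic_distance_grid(
    ell: EquivalentEllipsoid,
    source_pixel: tuple[int, int],
    limit: float = np.inf,
) -> np.ndarray:
    """Geodesic distance from a source pixel to every pixel (180×360).

    Shortest-path distance on the 8-connected pixel lattice; an upper-bound
    approximation to the true surface geodesic (within a few percent for
    moderate aspect ratios).  ``limit`` truncates the search; unreached
    pixels hold +inf.
    """
    i, j = source_pixel
    if not (0 <= i < N_THETA and 0 <= j < N_PHI):
        raise ValueError("source pixel out of range")
    graph, _ = _pixel_graph(ell)
    dist = dijkstra(graph, directed=False, indices=i * N_PHI + j, limit=limit)
    return dist.reshape(N_THETA, N_PHI)


@dataclass
class SurfaceMap:
    """A 180×360 accumulation map over (θ, φ_s)."""

    data: np.ndarray = field(default_factory=lambda: np.zeros((N_THETA, N_PHI)))
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.shape != (N_THETA, N_PHI):
            raise ValueError(f"map must be {N_THETA}x{N_PHI}")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("map values must be finite and nonnegative")

    @property
    def total_mass(self) -> float:
        """Raw pixel sum (no area weighting, matching map presentation)."""
        return float(self.data.sum())

    @property
    def area_weighted_mass(self) -> float:
        """sinθ-weighted sum: proportional to integrated surface density."""
        sin_t = np.sin(np.deg2rad(np.arange(N_THETA) + 0.5))
        return float((self.data * sin_t[:, None]).sum())

    def normalize_max(self) -> "SurfaceMap":
        peak = self.data.max()
        return SurfaceMap(self.data / peak if peak > 0 else self.data, normalized=True)

    def region_mean(self, theta_range: tuple[float, float],
                    phi_range: tuple[float, float] | None = None) -> float:
        """Mean pixel value over a θ (and optional φ_s) band."""
        th = np.arange(N_THETA) + 0.5
        ph = np.arange(N_PHI) + 0.5
        rows = (th >= theta_range[0]) & (th <= theta_range[1])
        sub = self.data[rows]
        if phi_range is not None:
            cols = (ph >= phi_range[0]) & (ph <= phi_range[1])
            sub = sub[:, cols]
        return float(sub.mean())

    def to_text(self, path) -> None:
        np.savetxt(path, self.data, fmt="%.6g")

    @classmethod
    def from_text(cls, path) -> "SurfaceMap":
        return cls(np.loadtxt(path))

    def to_image(self, path) -> None:
        """8-bit grayscale image, dark = high."""
        from PIL import Image
        peak = self.data.max() or 1.0
        img = (255 * (1.0 - self.data / peak)).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)


def deposit_gaussian(
    smap: SurfaceMap,
    ell: EquivalentEllipsoid,
    theta_deg: float,
    phi_deg: float,
    sigma_deg: float = 10.0,
    weight: float = 1.0,
    arc_metric: bool = True,
) -> SurfaceMap:
    """Add a Gaussian spot of geodesic arc width σ at (θ, φ_s) to the map.

    With ``arc_metric`` the geodesic distance (in the ellipsoid's length
    units) is converted to degrees of arc through the local surface radius at
    the deposited point; otherwise flat pixel (θ, φ_s) degrees are used.
    Deposition is additive: total mass accumulates exactly.
    """
    i, j = pixel_of(theta_deg, phi_deg)
    if arc_metric:
        t_local = float(surface_radius(ell, theta_deg, phi_deg))
        sigma_len = math.radians(sigma_deg) * t_local
        dist = geodesic_distance_grid(ell, (i, j), limit=5.0 * sigma_len)
        g_deg = np.degrees(dist / t_local)
    else:
        th = np.arange(N_THETA) + 0.5
        ph = np.arange(N_PHI) + 0.5
        dth = th[:, None] - (i + 0.5)
        dph = np.abs(ph[None, :] - (j + 0.5))
        dph = np.minimum(dph, 360.0 - dph)
        g_deg = np.sqrt(dth ** 2 + dph ** 2)
    with np.errstate(over="ignore"):
        spot = np.where(np.isfinite(g_deg),
                        np.exp(-np.square(g_deg) / (2.0 * sigma_deg ** 2)), 0.0)
    smap.data += weight * spot
    return smap


def _shape_matrices(ell: EquivalentEllipsoid):
    """World-frame quadric X = R diag(a²,b²,c²) Rᵀ and its inverse A."""
    R = ell.rotation
    X = R @ np.diag(ell.semi_axes ** 2) @ R.T
    A = R @ np.diag(ell.semi_axes ** -2.0) @ R.T
    return X, A


def pw_contact_function(ellA: EquivalentEllipsoid, ellB: EquivalentEllipsoid) -> tuple[float, np.ndarray]:
    """Perram-Wertheim contact function F and the contact point.

    F = max_λ λ(1-λ) dᵀ(λX_B + (1-λ)X_A)⁻¹ d with d the centre separation and
    X the world-frame shape quadrics.  The ellipsoids overlap iff F < 1; both
    scaled by s are externally tangent at s = √F.  The returned point is the
    common point minimizing the joint quadric (the tangency point of the
    scaled pair).
    """
    XA, AA = _shape_matrices(ellA)
    XB, AB = _shape_matrices(ellB)
    d = ellB.centroid - ellA.centroid
    if np.linalg.norm(d) < 1e-12:
        raise ValueError("concentric ellipsoids have no contact centre")

    def s_of(lam: float) -> float:
        Y = lam * XB + (1.0 - lam) * XA
        return lam * (1.0 - lam) * float(d @ np.linalg.solve(Y, d))

    from scipy.optimize import minimize_scalar
    sol = minimize_scalar(lambda l: -s_of(l), bounds=(1e-12, 1.0 - 1e-12),
                          method="bounded", options={"xatol": 1e-13})
    lam = float(sol.x)
    F = s_of(lam)
    M = lam * AA + (1.0 - lam) * AB
    x_c = np.linalg.solve(M, lam * AA @ ellA.centroid + (1.0 - lam) * AB @ ellB.centroid)
    return F, x_c


def ellipsoids_overlap(ellA: EquivalentEllipsoid, ellB: EquivalentEllipsoid,
                       scale: float = 1.0) -> bool:
    """True if the two ellipsoids, both scaled by ``scale``, interpenetrate."""
    F, _ = pw_contact_function(ellA, ellB)
    return math.sqrt(F) < scale


def dimer_contact_centre(
    ellA: EquivalentEllipsoid,
    ellB: EquivalentEllipsoid,
    tol: float = 1e-9,
) -> dict:
    """Contact centre of a dimer by shrinking both partners to tangency.

    Both ellipsoids are scaled by a common factor s about their own centres
    until their surfaces just touch; s is located by bisection on the overlap
    predicate (bracket grown geometrically first).  The tangency point is
    mapped into each body frame and returned as (θ, φ_s) on each partner.
    """
    lo, hi = 1e-6, 1.0
    while ellipsoids_overlap(ellA, ellB, lo):
        lo *= 0.5
        if lo < 1e-12:
            raise ValueError("degenerate pose: overlap at vanishing scale")
    while not ellipsoids_overlap(ellA, ellB, hi):
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("no contact found at any scale")
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if ellipsoids_overlap(ellA, ellB, mid):
            hi = mid
        else:
            lo = mid
    s = 0.5 * (lo + hi)
    _, x_c = pw_contact_function(ellA, ellB)
    angles = {}
    for tag, ell in (("A", ellA), ("B", ellB)):
        body = ell.to_body_frame(x_c)[0]
        angles[tag] = invert_surface_point(ell, body, tol=np.inf)
    return {"scale": s, "contact_point": x_c,
            "theta_phi_A": angles["A"], "theta_phi_B": angles["B"]}


def map_residue_values(
    cloud,
    ell: EquivalentEllipsoid,
    table,
    surface_m: float = 0.75,
    sigma_deg: float = 10.0,
    canonicalize: bool = True,
) -> SurfaceMap:
    """Average-value θφ map of surface residues.

    Residues whose Cα fractional radial extent m ≥ ``surface_m`` are
    projected radially to the surface, their scalar deposited as a Gaussian
    spot; the map is the value-weighted deposit divided by the unweighted
    deposit (a smoothed surface average).  With ``canonicalize`` the body is
    rotated by 180° about the a-axis when needed so the hemisphere
    0 < φ_s < 180 carries the lower mean value; the operation is idempotent.
    """
    from .shape_core import fractional_radial_extent
    extent = fractional_radial_extent(cloud, ell)
    ca = cloud.ca_cloud()
    body = ell.to_body_frame(ca.coords)
    weighted = SurfaceMap()
    weight = SurfaceMap()
    n_surface = 0
    for k, idx in enumerate(ca.res_index):
        idx = int(idx)
        m = extent.values.get(idx)
        if m is None or m < surface_m or idx not in table.values.index:
            continue
        p = body[k] / m          # radial projection to the surface
        theta, phi = invert_surface_point(ell, p, tol=np.inf)
        value = float(table.values[idx])
        deposit_gaussian(weighted, ell, theta, phi, sigma_deg, weight=value)
        deposit_gaussian(weight, ell, theta, phi, sigma_deg, weight=1.0)
        n_surface += 1
    if n_surface == 0:
        raise ValueError("no surface residues under the given criterion")
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(weight.data > 1e-12, weighted.data / weight.data, 0.0)
    if canonicalize:
        half = N_PHI // 2
        if avg[:, :half].mean() > avg[:, half:].mean():
            avg = np.roll(avg, half, axis=1)
    return SurfaceMap(avg)
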