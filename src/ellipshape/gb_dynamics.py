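"""Brownian/Langevin dynamics of soft spheroids and collision cartography.

Particles interact through the uniaxial Gay-Berne pair potential

    V = 4ε(ζ⁻¹² - ζ⁻⁶)  for ζ < ζ_cut,  else 0,
    ζ = (r - σ + σ_min)/σ_min,   σ⁻² = ½ r̂·H⁻¹·r̂,
    H = 2ℓ⊥² 1 + (ℓ∥² - ℓ⊥²)(e_i⊗e_i + e_j⊗e_j),   σ_min = min(ℓ⊥, ℓ∥),

with (ℓ∥, ℓ⊥) calibrated so that two parallel unit-volume spheroids have
V = 1 kT at end-to-end separation 2a and side-by-side separation 2c.  The
cutoff defaults to ζ_cut = 2^{1/6}, keeping only the repulsive branch (soft
quasi-hard particles); the force is continuous (zero) at the cutoff.

Dynamics are run in reduced units (kT = 1, friction γ = 1, δt = 1e-4) in a
periodic box: first-order Brownian (overdamped) or unit-mass Langevin
integration, with the box ramped to the target volume fraction, an
equilibration phase, then production sampling of wrapped and unwrapped
positions.  Translational diffusion follows from the mean-squared
displacement, D_t = <d²>/6t, and D_t(φ)/D⁰ curves are fitted for the
critical volume fraction φ_c with the cage model in :mod:`crowding`.

Collision locations: for Gay-Berne runs a collision is the onset of a
contiguous ζ < 1 interval for a pair; for triaxial ellipsoids an interaction-
free anisotropic Brownian "ghost" run records overlap onsets detected with
the Perram-Wertheim contact function.  Contact points are mapped to
body-frame (θ, φ_s) along the inter-centre direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .crowding import PhiCFit, fit_phi_c
from .shape_core import EquivalentEllipsoid

__all__ = [
    "SimConfig", "Trajectory", "ContactEvent", "zeta_star",
    "calibrate_lengths", "gay_berne", "initial_state", "run_dynamics",
    "msd_diffusion", "phi_c_pipeline", "record_collisions",
    "brownian_collision_atlas", "collision_map", "unit_volume_semi_axes",
    "ZETA_CUT_DEFAULT",
]

ZETA_CUT_DEFAULT = 2.0 ** (1.0 / 6.0)
_ZETA_FLOOR = 0.15   # deep-overlap force cap (integration safety)


def unit_volume_semi_axes(alpha: float, beta: float = 0.0) -> np.ndarray:
    """Semi-axes (a, b, c) of the unit-volume ellipsoid with shape (α, β)."""
    k = (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    c = k * alpha ** (-(1.0 + beta) / 3.0)
    return np.array([alpha * c, alpha ** beta * c, c])


def zeta_star(eps: float = 1.0) -> float:
    """ζ at which V(ζ) = 1 on the repulsive branch (4ε(ζ⁻¹²-ζ⁻⁶) = 1)."""
    u = 0.5 * (1.0 + math.sqrt(1.0 + 1.0 / eps))
    return u ** (-1.0 / 6.0)


def calibrate_lengths(alpha: float, eps: float = 1.0) -> tuple[float, float]:
    """(ℓ∥, ℓ⊥) such that V(2a) = V(2c) = 1 for a unit-volume spheroid.

    For parallel spheroids the range parameter is exactly 2ℓ∥ end-to-end and
    2ℓ⊥ side-by-side, so the two conditions decouple in closed form.
    """
    if alpha < 1.0:
        raise ValueError("spheroid aspect ratio must be >= 1 (prolate/sphere)")
    a, _, c = unit_volume_semi_axes(alpha, 0.0)
    zs = zeta_star(eps)
    lperp = 2.0 * c / (1.0 + zs)
    lpar = a + lperp * (1.0 - zs) / 2.0
    return lpar, lperp


@dataclass(frozen=True)
class SimConfig:
    """Reduced-unit simulation parameters for soft-spheroid dynamics."""

    n_particles: int = 256
    alpha: float = 1.0          # spheroid aspect ratio (unit steric volume)
    phi: float = 0.3            # target volume fraction
    eps: float = 1.0            # Gay-Berne well depth (kT units)
    kt: float = 1.0
    gamma_t: float = 1.0
    gamma_r: float = 1.0
    dt: float = 1e-4
    n_ramp: int = 10_000
    n_equil: int = 10_000
    n_production: int = 100_000
    sample_every: int = 50
    zeta_cut: float = ZETA_CUT_DEFAULT
    integrator: str = "brownian"   # or "langevin"
    seed: int = 0
    track_collisions: bool = False
    max_events: int = 200_000

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 0.74):
            raise ValueError("volume fraction must be in (0, 0.74)")
        if self.dt > 1e-3:
            raise ValueError("timestep too large for the soft potential (dt <= 1e-3)")
        if self.integrator not in ("brownian", "langevin"):
            raise ValueError("integrator must be 'brownian' or 'langevin'")
        if min(self.n_particles, self.n_ramp, self.n_equil, self.n_production,
               self.sample_every) <= 0 or min(self.eps, self.kt, self.gamma_t,
                                              self.gamma_r, self.dt) <= 0:
            raise ValueError("all counts and physical parameters must be positive")

    @property
    def lengths(self) -> tuple[float, float]:
        return calibrate_lengths(self.alpha, self.eps)

    @property
    def box_length(self) -> float:
        return (self.n_particles / self.phi) ** (1.0 / 3.0)


@dataclass
class Trajectory:
    """Production-phase frames of a soft-spheroid run."""

    times: np.ndarray         # (nf,)
    positions: np.ndarray     # (nf, N, 3) wrapped into the box
    unwrapped: np.ndarray     # (nf, N, 3) displacement-accumulated
    orientations: np.ndarray  # (nf, N, 3) unit symmetry-axis vectors
    box_length: float
    energies: np.ndarray      # (nf,) mean pair potential energy per particle
    config: SimConfig
    events: np.ndarray | None = None   # raw collision records (see kernel)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.orientations, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("orientations must be unit vectors")


@dataclass(frozen=True)
class ContactEvent:
    """A recorded collision between particles i and j."""

    i: int
    j: int
    time: float
    theta_phi_i: tuple[float, float]
    theta_phi_j: tuple[float, float]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _gb_pair(dx, dy, dz, r, eix, eiy, eiz, ejx, ejy, ejz,
             eps, lpar, lperp, zcut, zfloor):
    """Energy, force on i, orientation gradients g_i/g_j, and ζ for one pair.

    The separation (dx,dy,dz) points from j to i.  Returns a 12-tuple
    (V, fx, fy, fz, gix, giy, giz, gjx, gjy, gjz, zeta, sigma).
    """
    lp2 = lperp * lperp
    q = lpar * lpar - lp2
    smin = min(lpar, lperp)
    # H = 2 lperp^2 I + q (ei ei^T + ej ej^T)
    h00 = 2.0 * lp2 + q * (eix * eix + ejx * ejx)
    h11 = 2.0 * lp2 + q * (eiy * eiy + ejy * ejy)
    h22 = 2.0 * lp2 + q * (eiz * eiz + ejz * ejz)
    h01 = q * (eix * eiy + ejx * ejy)
    h02 = q * (eix * eiz + ejx * ejz)
    h12 = q * (eiy * eiz + ejy * ejz)
    c00 = h11 * h22 - h12 * h12
    c01 = h02 * h12 - h01 * h22
    c02 = h01 * h12 - h02 * h11
    c11 = h00 * h22 - h02 * h02
    c12 = h01 * h02 - h00 * h12
    c22 = h00 * h11 - h01 * h01
    det = h00 * c00 + h01 * c01 + h02 * c02
    rx, ry, rz = dx / r, dy / r, dz / r
    ux = (c00 * rx + c01 * ry + c02 * rz) / det
    uy = (c01 * rx + c11 * ry + c12 * rz) / det
    uz = (c02 * rx + c12 * ry + c22 * rz) / det
    ph = rx * ux + ry * uy + rz * uz          # r̂·H⁻¹·r̂
    sigma = math.sqrt(2.0 / ph)
    zeta = (r - sigma + smin) / smin
    if zeta >= zcut:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, zeta, sigma
    zeff = zeta if zeta > zfloor else zfloor
    z6 = zeff ** (-6.0)
    v = 4.0 * eps * (z6 * z6 - z6)
    dvdz = 24.0 * eps * (z6 - 2.0 * z6 * z6) / zeff
    # dzeta/dr_vec = (1/smin)(r̂ + (σ³/2r)(u - φ r̂))
    s3 = sigma * sigma * sigma
    kr = s3 / (2.0 * r)
    tx = (rx + kr * (ux - ph * rx)) / smin
    ty = (ry + kr * (uy - ph * ry)) / smin
    tz = (rz + kr * (uz - ph * rz)) / smin
    fx = -dvdz * tx
    fy = -dvdz * ty
    fz = -dvdz * tz
    # dzeta/de_i = -(σ³ q / (2 σ_min)) (u·e_i) u  (and same for j)
    ke = -s3 * q / (2.0 * smin)
    uei = ux * eix + uy * eiy + uz * eiz
    uej = ux * ejx + uy * ejy + uz * ejz
    gix = dvdz * ke * uei * ux
    giy = dvdz * ke * uei * uy
    giz = dvdz * ke * uei * uz
    gjx = dvdz * ke * uej * ux
    gjy = dvdz * ke * uej * uy
    gjz = dvdz * ke * uej * uz
    return v, fx, fy, fz, gix, giy, giz, gjx, gjy, gjz, zeta, sigma


@njit(cache=True)
def _build_pairs(pos, L, rlist2, pairs):
    n = pos.shape[0]
    m = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            if dx * dx + dy * dy + dz * dz < rlist2:
                if m < pairs.shape[0]:
                    pairs[m, 0] = i
                    pairs[m, 1] = j
                m += 1
    return m


@njit(cache=True)
def _forces(pos, e, L, pairs, npairs, eps, lpar, lperp, zcut, zfloor,
            F, G, zetas):
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0; F[i, 1] = 0.0; F[i, 2] = 0.0
        G[i, 0] = 0.0; G[i, 1] = 0.0; G[i, 2] = 0.0
    energy = 0.0
    rcut = 2.0 * max(lpar, lperp) + (zcut - 1.0) * min(lpar, lperp)
    rcut2 = rcut * rcut
    for k in range(npairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        zetas[k] = 1e9
        if r2 > rcut2:
            continue
        r = math.sqrt(r2)
        (v, fx, fy, fz, gix, giy, giz, gjx, gjy, gjz,
         zeta, _sig) = _gb_pair(dx, dy, dz, r,
                                e[i, 0], e[i, 1], e[i, 2],
                                e[j, 0], e[j, 1], e[j, 2],
                                eps, lpar, lperp, zcut, zfloor)
        zetas[k] = zeta
        energy += v
        F[i, 0] += fx; F[i, 1] += fy; F[i, 2] += fz
        F[j, 0] -= fx; F[j, 1] -= fy; F[j, 2] -= fz
        G[i, 0] += gix; G[i, 1] += giy; G[i, 2] += giz
        G[j, 0] += gjx; G[j, 1] += gjy; G[j, 2] += gjz
    return energy


@njit(cache=True)
def _run_gb(pos, e, vel, omg, L0, L1, n_ramp, n_equil, n_prod, sample_every,
            dt, kt, gt, gr, eps, lpar, lperp, zcut, zfloor, langevin, seed,
            track_collisions, max_events):
    np.random.seed(seed)
    n = pos.shape[0]
    rcut = 2.0 * max(lpar, lperp) + (zcut - 1.0) * min(lpar, lperp)
    skin = 0.4
    rlist2 = (rcut + skin) ** 2
    maxpairs = n * 96
    pairs = np.empty((maxpairs, 2), np.int64)
    zetas = np.empty(maxpairs, np.float64)
    F = np.empty((n, 3))
    G = np.empty((n, 3))
    ref = pos.copy()
    upos = pos.copy()
    L = L0
    npairs = _build_pairs(pos, L, rlist2, pairs)

    nf = n_prod // sample_every + 1
    frames_pos = np.empty((nf, n, 3))
    frames_upos = np.empty((nf, n, 3))
    frames_e = np.empty((nf, n, 3))
    frames_t = np.empty(nf)
    frames_en = np.empty(nf)

    contact = np.zeros((n, n), np.uint8)
    events = np.empty((max_events, 12))
    n_events = 0

    st2_t = math.sqrt(2.0 * kt * dt / gt)
    st2_r = math.sqrt(2.0 * kt * dt / gr)
    sl_t = math.sqrt(2.0 * gt * kt * dt)
    sl_r = math.sqrt(2.0 * gr * kt * dt)
    # force/gradient caps limiting the deterministic move to ~0.05 sigma_min
    # per step (engages only in deep overlaps during compression)
    fmax = 0.05 * min(lpar, lperp) * gt / dt
    gmax = 0.1 * gr / dt

    total = n_ramp + n_equil + n_prod
    frame = 0
    energy = 0.0
    for step in range(total + 1):
        in_prod = step >= n_ramp + n_equil
        # box ramp with affine position rescale
        if step < n_ramp and n_ramp > 0:
            L_new = L0 + (L1 - L0) * (step + 1) / n_ramp
            f = L_new / L
            for i in range(n):
                for d in range(3):
                    pos[i, d] *= f
                    ref[i, d] *= f
            L = L_new
        # neighbour-list rebuild on displacement (box scaling folded into ref)
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > (0.5 * skin) ** 2 or step == 0:
            npairs = _build_pairs(pos, L, rlist2, pairs)
            if npairs > maxpairs:
                return (frames_t[:0], frames_pos[:0], frames_upos[:0],
                        frames_e[:0], frames_en[:0], events[:0], -1, L)
            for i in range(n):
                for d in range(3):
                    ref[i, d] = pos[i, d]
        energy = _forces(pos, e, L, pairs, npairs, eps, lpar, lperp,
                         zcut, zfloor, F, G, zetas)
        if not math.isfinite(energy):
            return (frames_t[:0], frames_pos[:0], frames_upos[:0],
                    frames_e[:0], frames_en[:0], events[:0], -2, L)

        if in_prod:
            k = step - (n_ramp + n_equil)
            if k % sample_every == 0:
                t = k * dt
                for i in range(n):
                    for d in range(3):
                        frames_pos[frame, i, d] = pos[i, d]
                        frames_upos[frame, i, d] = upos[i, d]
                        frames_e[frame, i, d] = e[i, d]
                frames_t[frame] = t
                frames_en[frame] = energy / n
                frame += 1
            if track_collisions and n_events < max_events:
                t = k * dt
                for kk in range(npairs):
                    i = pairs[kk, 0]
                    j = pairs[kk, 1]
                    # hysteresis: a contact ends only after clear separation,
                    # so boundary flicker cannot spawn duplicate events
                    was = contact[i, j] == 1
                    now = zetas[kk] < 1.0 or (was and zetas[kk] < 1.05)
                    if now and not was and n_events < max_events:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        dx -= L * round(dx / L)
                        dy -= L * round(dy / L)
                        dz -= L * round(dz / L)
                        rr = math.sqrt(dx * dx + dy * dy + dz * dz)
                        events[n_events, 0] = t
                        events[n_events, 1] = i
                        events[n_events, 2] = j
                        events[n_events, 3] = dx / rr
                        events[n_events, 4] = dy / rr
                        events[n_events, 5] = dz / rr
                        events[n_events, 6] = e[i, 0]
                        events[n_events, 7] = e[i, 1]
                        events[n_events, 8] = e[i, 2]
                        events[n_events, 9] = e[j, 0]
                        events[n_events, 10] = e[j, 1]
                        events[n_events, 11] = e[j, 2]
                        n_events += 1
                    contact[i, j] = 1 if now else 0
        if step == total:
            break

        # integrate
        for i in range(n):
            fn = math.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2 + F[i, 2] ** 2)
            if fn > fmax:
                s = fmax / fn
                F[i, 0] *= s; F[i, 1] *= s; F[i, 2] *= s
            gn = math.sqrt(G[i, 0] ** 2 + G[i, 1] ** 2 + G[i, 2] ** 2)
            if gn > gmax:
                s = gmax / gn
                G[i, 0] *= s; G[i, 1] *= s; G[i, 2] *= s
            if langevin:
                dxv = np.empty(3)
                for d in range(3):
                    vel[i, d] += dt * (F[i, d] - gt * vel[i, d]) + sl_t * np.random.normal()
                    dxv[d] = vel[i, d] * dt
            else:
                dxv = np.empty(3)
                for d in range(3):
                    dxv[d] = F[i, d] * dt / gt + st2_t * np.random.normal()
            for d in range(3):
                pos[i, d] += dxv[d]
                if in_prod:
                    upos[i, d] += dxv[d]
                pos[i, d] -= L * math.floor(pos[i, d] / L)
            # orientation update
            ex, ey, ez = e[i, 0], e[i, 1], e[i, 2]
            gx, gy, gz = G[i, 0], G[i, 1], G[i, 2]
            gd = gx * ex + gy * ey + gz * ez
            gpx, gpy, gpz = gx - gd * ex, gy - gd * ey, gz - gd * ez
            if langevin:
                # torque tau = -e x g ; domega = (tau - gr*omega) dt + noise
                tx = -(ey * gz - ez * gy)
                ty = -(ez * gx - ex * gz)
                tz = -(ex * gy - ey * gx)
                omg[i, 0] += dt * (tx - gr * omg[i, 0]) + sl_r * np.random.normal()
                omg[i, 1] += dt * (ty - gr * omg[i, 1]) + sl_r * np.random.normal()
                omg[i, 2] += dt * (tz - gr * omg[i, 2]) + sl_r * np.random.normal()
                od = omg[i, 0] * ex + omg[i, 1] * ey + omg[i, 2] * ez
                omg[i, 0] -= od * ex
                omg[i, 1] -= od * ey
                omg[i, 2] -= od * ez
                nex = ex + (omg[i, 1] * ez - omg[i, 2] * ey) * dt
                ney = ey + (omg[i, 2] * ex - omg[i, 0] * ez) * dt
                nez = ez + (omg[i, 0] * ey - omg[i, 1] * ex) * dt
            else:
                x1 = np.random.normal()
                x2 = np.random.normal()
                x3 = np.random.normal()
                xd = x1 * ex + x2 * ey + x3 * ez
                nex = ex - gpx * dt / gr + st2_r * (x1 - xd * ex)
                ney = ey - gpy * dt / gr + st2_r * (x2 - xd * ey)
                nez = ez - gpz * dt / gr + st2_r * (x3 - xd * ez)
            nn = math.sqrt(nex * nex + ney * ney + nez * nez)
            e[i, 0] = nex / nn
            e[i, 1] = ney / nn
            e[i, 2] = nez / nn

    return (frames_t[:frame], frames_pos[:frame], frames_upos[:frame],
            frames_e[:frame], frames_en[:frame], events[:n_events], 0, L)


def gay_berne(r_vec, e_i, e_j, alpha: float = 1.0, eps: float = 1.0,
              zeta_cut: float = ZETA_CUT_DEFAULT,
              lengths: tuple[float, float] | None = None) -> dict:
    """Gay-Berne energy, force on i, and torques for one pair (library API).

    ``r_vec`` points from particle j to particle i; ``e_i``/``e_j`` are unit
    symmetry axes.  Lengths default to the unit-volume calibration for the
    given aspect ratio.  Deeply overlapping pairs (ζ below the cap) get the
    capped repulsive force with a warning.
    """
    lpar, lperp = lengths if lengths is not None else calibrate_lengths(alpha, eps)
    r_vec = np.asarray(r_vec, float)
    e_i = np.asarray(e_i, float)
    e_j = np.asarray(e_j, float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError("coincident particle centres")
    out = _gb_pair(r_vec[0], r_vec[1], r_vec[2], r,
                   e_i[0], e_i[1], e_i[2], e_j[0], e_j[1], e_j[2],
                   eps, lpar, lperp, zeta_cut, _ZETA_FLOOR)
    v, fx, fy, fz, gix, giy, giz, gjx, gjy, gjz, zeta, sigma = out
    if zeta <= _ZETA_FLOOR:
        import logging
        logging.getLogger(__name__).warning(
            "deep overlap (zeta=%.3f <= %.2f): repulsion capped", zeta, _ZETA_FLOOR)
    g_i = np.array([gix, giy, giz])
    g_j = np.array([gjx, gjy, gjz])
    return {
        "energy": float(v),
        "force_i": np.array([fx, fy, fz]),
        "torque_i": -np.cross(e_i, g_i),
        "torque_j": -np.cross(e_j, g_j),
        "grad_ei": g_i,
        "grad_ej": g_j,
        "zeta": float(zeta),
        "sigma": float(sigma),
    }


def initial_state(config: SimConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Random-sequential-insertion start (positions, orientations, box L).

    Particles are inserted at a dilute volume fraction (the box is then
    compressed to target during the ramp) with a minimum centre-centre
    spacing to avoid deep overlaps; orientations are uniform on the sphere.
    """
    rng = np.random.default_rng(config.seed)
    phi0 = min(0.15, config.phi)
    L0 = (config.n_particles / phi0) ** (1.0 / 3.0)
    lpar, lperp = config.lengths
    min_d = 1.8 * lperp
    pos = np.empty((config.n_particles, 3))
    placed = 0
    attempts = 0
    while placed < config.n_particles:
        cand = rng.uniform(0.0, L0, size=3)
        d = pos[:placed] - cand
        d -= L0 * np.round(d / L0)
        if placed == 0 or np.min(np.einsum("ij,ij->i", d, d)) > min_d ** 2:
            pos[placed] = cand
            placed += 1
        attempts += 1
        if attempts > 1000 * config.n_particles:
            raise RuntimeError("random sequential insertion failed; lower phi")
    e = rng.normal(size=(config.n_particles, 3))
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    return pos, e, L0


def run_dynamics(config: SimConfig,
                 state: tuple[np.ndarray, np.ndarray, float] | None = None) -> Trajectory:
    """Ramp-equilibrate-produce protocol for one (α, φ) state point."""
    if state is None:
        state = initial_state(config)
    pos, e, L0 = state
    pos = np.array(pos, float)
    e = np.array(e, float)
    lpar, lperp = config.lengths
    vel = np.zeros_like(pos)
    omg = np.zeros_like(pos)
    out = _run_gb(pos, e, vel, omg, float(L0), config.box_length,
                  config.n_ramp, config.n_equil, config.n_production,
                  config.sample_every, config.dt, config.kt, config.gamma_t,
                  config.gamma_r, config.eps, lpar, lperp, config.zeta_cut,
                  _ZETA_FLOOR, config.integrator == "langevin",
                  config.seed, config.track_collisions, config.max_events)
    times, fpos, fupos, fe, fen, events, status, L = out
    if status == -1:
        raise RuntimeError("neighbour list overflow; density too high")
    if status == -2:
        raise RuntimeError("energy blow-up: simulation unstable (reduce dt or phi)")
    return Trajectory(times, fpos, fupos, fe, L, fen, config,
                      events if config.track_collisions else None)


def msd_diffusion(traj_or_upos, times: np.ndarray | None = None,
                  window: tuple[float, float] = (0.1, 0.5),
                  n_blocks: int = 4) -> dict:
    """Translational diffusion from the mean-squared displacement.

    Time-origin-averaged MSD is fitted as 6 D t + b over lag times in
    ``window`` (fractions of the maximum lag; the linear late-time regime by
    default).  The uncertainty is the standard error over particle blocks,
    and a log-log slope far from 1 flags non-diffusive (caged or ballistic)
    motion.
    """
    if isinstance(traj_or_upos, Trajectory):
        upos = traj_or_upos.unwrapped
        times = traj_or_upos.times
    else:
        upos = np.asarray(traj_or_upos, float)
        if times is None:
            raise ValueError("times required when passing a raw array")
    nf = upos.shape[0]
    if nf < 100:
        raise ValueError("need at least 100 frames for an MSD estimate")
    dtf = times[1] - times[0]
    max_lag = nf - 1
    lags = np.unique(np.clip(np.round(
        np.linspace(max(1, int(window[0] * max_lag)),
                    max(2, int(window[1] * max_lag)), 24)).astype(int), 1, max_lag))

    def msd_of(u):
        out = np.empty(lags.size)
        for k, lag in enumerate(lags):
            d = u[lag:] - u[:-lag]
            out[k] = np.mean(np.einsum("fij,fij->fi", d, d))
        return out

    msd = msd_of(upos)
    tl = lags * dtf
    slope, intercept = np.polyfit(tl, msd, 1)
    d_est = slope / 6.0
    loglog = np.polyfit(np.log(tl), np.log(np.maximum(msd, 1e-300)), 1)[0]
    n_part = upos.shape[1]
    d_blocks = []
    if n_part >= n_blocks:
        for b in range(n_blocks):
            sel = slice(b * n_part // n_blocks, (b + 1) * n_part // n_blocks)
            sl = np.polyfit(tl, msd_of(upos[:, sel]), 1)[0]
            d_blocks.append(sl / 6.0)
    err = float(np.std(d_blocks) / math.sqrt(len(d_blocks))) if d_blocks else float("nan")
    return {
        "D": float(d_est),
        "D_err": err,
        "exponent": float(loglog),
        "nonlinear": bool(abs(loglog - 1.0) > 0.35),
        "lags": tl,
        "msd": msd,
        "intercept": float(intercept),
    }


def phi_c_pipeline(alpha: float, phis, config: SimConfig | None = None,
                   kappa: float | None = None,
                   msd_window: tuple[float, float] = (0.1, 0.5)) -> dict:
    """D_t(φ)/D⁰ table for one aspect ratio and the fitted (φ_c, κ).

    D⁰ is the free-draining single-particle value kT/γ (the exact dilute
    limit of both integrators).  The cage model is fitted with
    :func:`crowding.fit_phi_c` (κ free by default, as in fits to protein
    data).
    """
    phis = np.asarray(phis, float)
    if phis.size < 4:
        raise ValueError("need at least 4 volume fractions")
    if config is None:
        config = SimConfig()
    d0 = config.kt / config.gamma_t
    ratios = np.empty(phis.size)
    errs = np.empty(phis.size)
    for k, phi in enumerate(phis):
        cfg = replace(config, alpha=alpha, phi=float(phi))
        res = msd_diffusion(run_dynamics(cfg), window=msd_window)
        ratios[k] = res["D"] / d0
        errs[k] = res["D_err"] / d0
    fit: PhiCFit = fit_phi_c(phis, ratios, kappa=kappa)
    return {"phi": phis, "ratio": ratios, "ratio_err": errs,
            "phi_c": fit.phi_c, "kappa": fit.kappa, "fit": fit}


# ---------------------------------------------------------------------------
# collision recording
# ---------------------------------------------------------------------------

def _body_angles_uniaxial(direction: np.ndarray, e: np.ndarray,
                          rng: np.random.Generator) -> tuple[float, float]:
    """(θ, φ_s) of a world direction in a uniaxial body frame.

    The azimuth reference (b-axis) of a spheroid is degenerate; a random
    but seed-deterministic perpendicular frame is completed.
    """
    ct = float(np.clip(direction @ e, -1.0, 1.0))
    theta = math.degrees(math.acos(ct))
    ref = rng.normal(size=3)
    f1 = ref - (ref @ e) * e
    f1 /= np.linalg.norm(f1)
    f2 = np.cross(e, f1)
    phi = math.degrees(math.atan2(float(direction @ f2), float(direction @ f1))) % 360.0
    return theta, phi


def record_collisions(traj: Trajectory) -> list[ContactEvent]:
    """Decode the collision records of a Gay-Berne run into ContactEvents.

    A collision is the onset of a contiguous ζ < 1 interval for a pair; the
    contact location on each particle is the surface point along the
    inter-centre direction, in body-frame (θ, φ_s) angles.
    """
    if traj.events is None:
        raise ValueError("run was not configured with track_collisions=True")
    rng = np.random.default_rng(traj.config.seed + 7)
    out = []
    for row in traj.events:
        t, i, j = row[0], int(row[1]), int(row[2])
        rij = row[3:6]          # unit vector from j to i
        e_i = row[6:9]
        e_j = row[9:12]
        th_i, ph_i = _body_angles_uniaxial(-rij, e_i, rng)
        th_j, ph_j = _body_angles_uniaxial(rij, e_j, rng)
        out.append(ContactEvent(i, j, float(t), (th_i, ph_i), (th_j, ph_j)))
    return out


@njit(cache=True)
def _pw_overlap(d0, d1, d2, Xa, Xb):
    """Perram-Wertheim max_λ S(λ) by golden-section (world-frame quadrics)."""
    gr = 0.6180339887498949
    lo, hi = 1e-9, 1.0 - 1e-9
    x1 = hi - gr * (hi - lo)
    x2 = lo + gr * (hi - lo)

    def s_of(lam):
        y00 = lam * Xb[0, 0] + (1.0 - lam) * Xa[0, 0]
        y01 = lam * Xb[0, 1] + (1.0 - lam) * Xa[0, 1]
        y02 = lam * Xb[0, 2] + (1.0 - lam) * Xa[0, 2]
        y11 = lam * Xb[1, 1] + (1.0 - lam) * Xa[1, 1]
        y12 = lam * Xb[1, 2] + (1.0 - lam) * Xa[1, 2]
        y22 = lam * Xb[2, 2] + (1.0 - lam) * Xa[2, 2]
        c00 = y11 * y22 - y12 * y12
        c01 = y02 * y12 - y01 * y22
        c02 = y01 * y12 - y02 * y11
        c11 = y00 * y22 - y02 * y02
        c12 = y01 * y02 - y00 * y12
        c22 = y00 * y11 - y01 * y01
        det = y00 * c00 + y01 * c01 + y02 * c02
        q = (d0 * (c00 * d0 + c01 * d1 + c02 * d2)
             + d1 * (c01 * d0 + c11 * d1 + c12 * d2)
             + d2 * (c02 * d0 + c12 * d1 + c22 * d2)) / det
        return lam * (1.0 - lam) * q

    f1 = s_of(x1)
    f2 = s_of(x2)
    for _ in range(40):
        if f1 < f2:
            lo = x1
            x1, f1 = x2, f2
            x2 = lo + gr * (hi - lo)
            f2 = s_of(x2)
        else:
            hi = x2
            x2, f2 = x1, f1
            x1 = hi - gr * (hi - lo)
            f1 = s_of(x1)
    return max(f1, f2)


@njit(cache=True)
def _run_ghost(pos, R, a, b, c, dta, dtb, dtc, dra, drb, drc, L, dt,
               n_steps, seed, max_events, events):
    """Anisotropic free Brownian motion of triaxial ellipsoids with
    overlap-onset collision recording (Perram-Wertheim test)."""
    np.random.seed(seed)
    n = pos.shape[0]
    st = np.empty(3)
    st[0] = math.sqrt(2.0 * dta * dt)
    st[1] = math.sqrt(2.0 * dtb * dt)
    st[2] = math.sqrt(2.0 * dtc * dt)
    sr = np.empty(3)
    sr[0] = math.sqrt(2.0 * dra * dt)
    sr[1] = math.sqrt(2.0 * drb * dt)
    sr[2] = math.sqrt(2.0 * drc * dt)
    ax2 = np.empty(3)
    ax2[0] = a * a
    ax2[1] = b * b
    ax2[2] = c * c
    contact = np.zeros((n, n), np.uint8)
    X = np.empty((n, 3, 3))
    n_events = 0
    sure_out2 = (2.0 * a) ** 2
    sure_in = 2.0 * c
    for step in range(n_steps):
        for i in range(n):
            # body-frame translational noise mapped to world
            b0 = st[0] * np.random.normal()
            b1 = st[1] * np.random.normal()
            b2 = st[2] * np.random.normal()
            for d in range(3):
                pos[i, d] += R[i, d, 0] * b0 + R[i, d, 1] * b1 + R[i, d, 2] * b2
                pos[i, d] -= L * math.floor(pos[i, d] / L)
            # body-frame rotational diffusion (Rodrigues, exact per step)
            w0 = sr[0] * np.random.normal()
            w1 = sr[1] * np.random.normal()
            w2 = sr[2] * np.random.normal()
            ang = math.sqrt(w0 * w0 + w1 * w1 + w2 * w2)
            if ang > 1e-14:
                kx, ky, kz = w0 / ang, w1 / ang, w2 / ang
                ca = math.cos(ang)
                sa = math.sin(ang)
                one_ca = 1.0 - ca
                # K = rotation matrix about body axis k by ang
                k00 = ca + kx * kx * one_ca
                k01 = kx * ky * one_ca - kz * sa
                k02 = kx * kz * one_ca + ky * sa
                k10 = ky * kx * one_ca + kz * sa
                k11 = ca + ky * ky * one_ca
                k12 = ky * kz * one_ca - kx * sa
                k20 = kz * kx * one_ca - ky * sa
                k21 = kz * ky * one_ca + kx * sa
                k22 = ca + kz * kz * one_ca
                for d in range(3):
                    r0 = R[i, d, 0]
                    r1 = R[i, d, 1]
                    r2 = R[i, d, 2]
                    R[i, d, 0] = r0 * k00 + r1 * k10 + r2 * k20
                    R[i, d, 1] = r0 * k01 + r1 * k11 + r2 * k21
                    R[i, d, 2] = r0 * k02 + r1 * k12 + r2 * k22
        if step % 500 == 0:
            # re-orthonormalize (Gram-Schmidt on columns)
            for i in range(n):
                nrm = math.sqrt(R[i, 0, 0] ** 2 + R[i, 1, 0] ** 2 + R[i, 2, 0] ** 2)
                for d in range(3):
                    R[i, d, 0] /= nrm
                dot = (R[i, 0, 0] * R[i, 0, 1] + R[i, 1, 0] * R[i, 1, 1]
                       + R[i, 2, 0] * R[i, 2, 1])
                for d in range(3):
                    R[i, d, 1] -= dot * R[i, d, 0]
                nrm = math.sqrt(R[i, 0, 1] ** 2 + R[i, 1, 1] ** 2 + R[i, 2, 1] ** 2)
                for d in range(3):
                    R[i, d, 1] /= nrm
                R[i, 0, 2] = R[i, 1, 0] * R[i, 2, 1] - R[i, 2, 0] * R[i, 1, 1]
                R[i, 1, 2] = R[i, 2, 0] * R[i, 0, 1] - R[i, 0, 0] * R[i, 2, 1]
                R[i, 2, 2] = R[i, 0, 0] * R[i, 1, 1] - R[i, 1, 0] * R[i, 0, 1]
        # shape quadrics X = R diag(ax2) R^T
        for i in range(n):
            for p in range(3):
                for q in range(3):
                    X[i, p, q] = (R[i, p, 0] * R[i, q, 0] * ax2[0]
                                  + R[i, p, 1] * R[i, q, 1] * ax2[1]
                                  + R[i, p, 2] * R[i, q, 2] * ax2[2])
        t = step * dt
        for i in range(n - 1):
            for j in range(i + 1, n):
                d0 = pos[j, 0] - pos[i, 0]
                d1 = pos[j, 1] - pos[i, 1]
                d2 = pos[j, 2] - pos[i, 2]
                d0 -= L * round(d0 / L)
                d1 -= L * round(d1 / L)
                d2 -= L * round(d2 / L)
                dist2 = d0 * d0 + d1 * d1 + d2 * d2
                if dist2 > sure_out2 * 1.0404:
                    contact[i, j] = 0
                    continue
                dist = math.sqrt(dist2)
                was = contact[i, j] == 1
                # hysteresis: once overlapping, release only after the
                # tangency scale clears 1.02 (suppresses boundary flicker)
                rel = 1.02 if was else 1.0
                if dist < sure_in * rel:
                    over = True
                elif dist2 > sure_out2 * rel * rel:
                    over = False
                else:
                    over = _pw_overlap(d0, d1, d2, X[i], X[j]) < rel * rel
                if over and not was and n_events < max_events:
                    # body-frame contact directions (i: toward j, j: toward i)
                    for tag in range(2):
                        sgn = 1.0 if tag == 0 else -1.0
                        idx = i if tag == 0 else j
                        bx = sgn * (R[idx, 0, 0] * d0 + R[idx, 1, 0] * d1 + R[idx, 2, 0] * d2) / dist
                        by = sgn * (R[idx, 0, 1] * d0 + R[idx, 1, 1] * d1 + R[idx, 2, 1] * d2) / dist
                        bz = sgn * (R[idx, 0, 2] * d0 + R[idx, 1, 2] * d1 + R[idx, 2, 2] * d2) / dist
                        th = math.degrees(math.acos(min(1.0, max(-1.0, bx))))
                        ph = math.degrees(math.atan2(bz, by)) % 360.0
                        events[n_events, 3 + 2 * tag] = th
                        events[n_events, 4 + 2 * tag] = ph
                    events[n_events, 0] = t
                    events[n_events, 1] = i
                    events[n_events, 2] = j
                    n_events += 1
                contact[i, j] = 1 if over else 0
    return n_events


def brownian_collision_atlas(
    alpha: float,
    beta: float = 0.0,
    phi: float = 0.2,
    n_particles: int = 64,
    n_steps: int = 30_000,
    dt: float = 2e-4,
    seed: int = 0,
    max_events: int = 100_000,
) -> list[ContactEvent]:
    """Collision locations of freely diffusing triaxial ellipsoids.

    Unit-volume ellipsoids of shape (α, β) perform interaction-free
    anisotropic Brownian motion (per-axis translational and rotational
    diffusion constants from the dilute triaxial theory, normalized to mean
    D_t = 1) in a periodic box at volume fraction φ.  A collision is the
    onset of a surface-overlap interval (Perram-Wertheim criterion); its
    location on each body is the surface point along the inter-centre
    direction.
    """
    from .hydrodynamics import dilute_diffusion
    a, b, c = unit_volume_semi_axes(alpha, beta)
    ell = EquivalentEllipsoid.from_semi_axes(a, b, c)
    hydro = dilute_diffusion(ell, delta_h=0.0, temperature=293.15, viscosity=1.0)
    dt_axes = hydro.dt_axes / hydro.dt_mean          # reduced: mean D_t = 1
    dr_axes = hydro.dr_axes / hydro.dr_mean
    rng = np.random.default_rng(seed)
    L = (n_particles / phi) ** (1.0 / 3.0)
    pos = rng.uniform(0.0, L, size=(n_particles, 3))
    R = np.empty((n_particles, 3, 3))
    for i in range(n_particles):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R[i] = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
    events = np.empty((max_events, 7))
    n_ev = _run_ghost(pos, R, a, b, c,
                      dt_axes[0], dt_axes[1], dt_axes[2],
                      dr_axes[0], dr_axes[1], dr_axes[2],
                      L, dt, n_steps, seed % (2 ** 31), max_events, events)
    out = []
    for row in events[:n_ev]:
        out.append(ContactEvent(int(row[1]), int(row[2]), float(row[0]),
                                (float(row[3]), float(row[4])),
                                (float(row[5]), float(row[6]))))
    return out


def collision_map(events: list[ContactEvent], ell: EquivalentEllipsoid,
                  sigma_deg: float = 10.0, both_bodies: bool = True):
    """Deposit collision events as Gaussian spots on a θφ SurfaceMap."""
    from .surface_mapping import SurfaceMap, deposit_gaussian
    smap = SurfaceMap()
    for ev in events:
        deposit_gaussian(smap, ell, *ev.theta_phi_i, sigma_deg=sigma_deg)
        if both_bodies:
            deposit_gaussian(smap, ell, *ev.theta_phi_j, sigma_deg=sigma_deg)
    return smap
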