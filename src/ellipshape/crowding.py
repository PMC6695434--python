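"""Self-diffusion in crowded suspensions and reaction-rate optimization.

Short-time self-diffusion of spheres follows Tokuyama-Oppenheim:

    D_S^S(φ)/D⁰ = 1/(1 + L(φ)),
    L(φ) = 2B²/(1-B) - C/(1+2C) - BC(2+C)/((1+C)(1-B+C)),

with B = (9φ/8)^{1/2} and C = 11φ/16.  Long-time self-diffusion adds a cage
term diverging at the critical volume fraction φ_c:

    D_S^L(φ, φ_c)/D⁰ = (D_S^S/D⁰) / (1 + κ (D_S^S/D⁰)(φ/φ_c)(1-φ/φ_c)^{-2}),

with κ = 2 describing protein data well.  A diffusion-limited reaction rate
is proportional to φ·D; this module maximizes that product over φ (and over
particle shape when a φ_c(α, β) surface is supplied) and fits (φ_c, κ) to
measured D(φ)/D⁰ curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "CrowdingCurve", "tokuyama_l", "short_time_ratio", "long_time_ratio",
    "quadratic_ratio", "rate_optimum", "fit_phi_c", "PhiCFit",
]


def tokuyama_l(phi: float | np.ndarray) -> float | np.ndarray:
    """The crowding function L(φ) of the short-time self-diffusion model."""
    phi = np.asarray(phi, float)
    if np.any(phi < 0):
        raise ValueError("volume fraction must be nonnegative")
    b = np.sqrt(9.0 * phi / 8.0)
    c = 11.0 * phi / 16.0
    if np.any(b >= 1.0) or np.any(1.0 - b + c <= 0.0):
        raise ValueError("volume fraction outside the model's domain (B >= 1)")
    out = (2.0 * b * b / (1.0 - b)
           - c / (1.0 + 2.0 * c)
           - b * c * (2.0 + c) / ((1.0 + c) * (1.0 - b + c)))
    return out if out.ndim else float(out)


def short_time_ratio(phi: float | np.ndarray) -> float | np.ndarray:
    """D_S^S(φ)/D⁰ = 1/(1 + L(φ)); 1 at infinite dilution."""
    return 1.0 / (1.0 + tokuyama_l(phi))


def long_time_ratio(
    phi: float | np.ndarray,
    phi_c: float,
    kappa: float = 2.0,
) -> float | np.ndarray:
    """D_S^L(φ, φ_c)/D⁰ with the cage term diverging at φ_c.

    Returns 0 at and beyond φ_c (arrested state).
    """
    if phi_c <= 0:
        raise ValueError("phi_c must be positive")
    phi = np.asarray(phi, float)
    arrested = phi >= phi_c
    safe = np.where(arrested, 0.0, phi)
    ds = short_time_ratio(safe)
    x = safe / phi_c
    with np.errstate(divide="ignore"):
        ratio = ds / (1.0 + kappa * ds * x / (1.0 - x) ** 2)
    ratio = np.where(arrested, 0.0, ratio)
    return ratio if ratio.ndim else float(ratio)


def quadratic_ratio(phi: float | np.ndarray, phi_c: float) -> float | np.ndarray:
    """Hard-sphere quadratic model D_t/D⁰ = (1 - φ/φ_c)², 0 past φ_c."""
    phi = np.asarray(phi, float)
    out = np.where(phi >= phi_c, 0.0, (1.0 - phi / phi_c) ** 2)
    return out if out.ndim else float(out)


def rate_optimum(
    model: str = "quadratic",
    phi_c: float | None = 0.58,
    kappa: float = 2.0,
    phi_c_surface=None,
    alpha_grid: np.ndarray | None = None,
    beta_grid: np.ndarray | None = None,
    shape_factor=None,
    grid_step: float = 1e-5,
) -> dict:
    """Maximize the reaction-rate proxy φ·D(φ)/D⁰ over concentration.

    ``model`` is "quadratic" ((1-φ/φ_c)², argmax exactly φ_c/3) or
    "tokuyama" (the long-time cage model).  If ``phi_c_surface`` is a
    callable φ_c(α, β), the product is jointly maximized over the supplied
    (α, β) grids, optionally weighting D by a shape factor such as the
    dilute triaxial reduction.

    Returns a dict with ``phi_opt``, ``value`` (max of φ·D/D⁰), rounded
    integer percent ``phi_percent``, and for joint optimization
    ``alpha_opt``/``beta_opt``.
    """

    def best_phi(pc: float) -> tuple[float, float]:
        if model == "quadratic":
            return pc / 3.0, pc / 3.0 * (1.0 - 1.0 / 3.0) ** 2
        phis = np.arange(grid_step, pc, grid_step)
        prod = phis * long_time_ratio(phis, pc, kappa)
        k = int(np.argmax(prod))
        return float(phis[k]), float(prod[k])

    if model not in ("quadratic", "tokuyama"):
        raise ValueError("model must be 'quadratic' or 'tokuyama'")

    if phi_c_surface is None:
        phi_opt, value = best_phi(float(phi_c))
        return {"phi_opt": phi_opt, "value": value,
                "phi_percent": int(round(100.0 * phi_opt))}

    if alpha_grid is None:
        alpha_grid = np.linspace(1.0, 3.0, 101)
    if beta_grid is None:
        beta_grid = np.array([0.0])
    best = None
    for alpha in alpha_grid:
        for beta in beta_grid:
            pc = float(phi_c_surface(alpha, beta))
            phi_opt, value = best_phi(pc)
            if shape_factor is not None:
                value *= float(shape_factor(alpha, beta))
            if best is None or value > best["value"]:
                best = {"phi_opt": phi_opt, "value": value,
                        "alpha_opt": float(alpha), "beta_opt": float(beta),
                        "phi_percent": int(round(100.0 * phi_opt))}
    return best


@dataclass
class PhiCFit:
    """Result of fitting (φ_c, κ) to a D(φ)/D⁰ curve."""

    phi_c: float
    kappa: float
    residual_rms: float
    phi_c_stderr: float = float("nan")
    narrow_range: bool = False   # flagged when data do not span φ >= 0.2

    def __iter__(self):
        return iter((self.phi_c, self.kappa))


def fit_phi_c(
    phi: np.ndarray,
    ratio: np.ndarray,
    kappa: float | None = None,
) -> PhiCFit:
    """Nonlinear least squares of the long-time cage model to D(φ)/D⁰ data.

    ``kappa=None`` fits κ jointly (bounded (0, 10]); otherwise κ is fixed.
    Initialization is deterministic: φ_c at 1.05× the largest observed φ,
    κ at 2.  Data not reaching φ = 0.2 are fitted but flagged as poorly
    constraining the extrapolation.
    """
    phi = np.asarray(phi, float)
    ratio = np.asarray(ratio, float)
    if phi.size < 4:
        raise ValueError("need at least 4 (phi, ratio) points")
    order = np.argsort(phi)
    phi, ratio = phi[order], ratio[order]
    narrow = phi.max() < 0.2

    fit_kappa = kappa is None
    phi_c0 = 1.05 * phi.max()

    def resid(params):
        pc = params[0]
        kp = params[1] if fit_kappa else kappa
        return long_time_ratio(phi, pc, kp) - ratio

    lower = [phi.max() + 1e-6] + ([1e-6] if fit_kappa else [])
    upper = [1.0] + ([10.0] if fit_kappa else [])
    x0 = [min(max(phi_c0, lower[0] + 1e-6), 0.999)] + ([2.0] if fit_kappa else [])
    sol = optimize.least_squares(resid, x0, bounds=(lower, upper), xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"phi_c fit did not converge: {sol.message}")
    pc = float(sol.x[0])
    kp = float(sol.x[1]) if fit_kappa else float(kappa)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    # asymptotic stderr of phi_c from the Jacobian (diagnostic only)
    stderr = float("nan")
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * max(rms, 1e-15) ** 2 * phi.size / max(phi.size - len(sol.x), 1)
        stderr = float(math.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        pass
    return PhiCFit(pc, kp, rms, stderr, narrow)


@dataclass
class CrowdingCurve:
    """D/D⁰ ratios tabulated on a φ grid for one (φ_c, κ)."""

    phi: np.ndarray
    phi_c: float
    kappa: float = 2.0
    short_ratio: np.ndarray = field(init=False)
    long_ratio: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, float)
        if np.any(self.phi < 0) or np.any(self.phi >= self.phi_c):
            raise ValueError("phi grid must lie in [0, phi_c)")
        self.short_ratio = np.asarray(short_time_ratio(self.phi))
        self.long_ratio = np.asarray(long_time_ratio(self.phi, self.phi_c, self.kappa))
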