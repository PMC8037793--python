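"""Shear-thinning blood rheology and Ergun-type porous coil resistance.

Blood is modelled as an incompressible shear-thinning fluid with a
plateau-capped power-law viscosity

    eta(gamma) = eta0 * gamma^(n-1)     for gamma_low <= gamma < gamma_high,

clamped to constant plateaus below gamma_low = 1e-3 1/s (0.55471 Pa·s)
and above gamma_high = 327 1/s (0.00345 Pa·s).

The coil mass inside the aneurysm dome is not resolved geometrically;
instead the dome is a homogeneous porous medium whose resistance to flow
follows the Ergun packed-bed correlation.  A coil packing density CPD (%)
sets the porosity kappa = 1 - CPD/100 and hence a quadratic (inertial) and
a linear (viscous) resistance coefficient:

    alpha = 1.75 * rho * (1 - kappa) / (kappa^3 * Dp)
    beta  = 150 * mu * (1 - kappa)^2 / (kappa^3 * Dp^2)

with Dp the coil wire diameter and mu the high-shear viscosity plateau.
The resulting momentum sink, per unit volume, is

    F_i = -(beta + alpha * |U|) * U_i

applied in dome cells only (superficial velocity convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BloodModel:
    """Power-law blood rheology constants (SI units).

    ``eta0`` is the consistency index (kg m^-1 s^(n-2)); with n = 0.6 its
    unit string is kg·m⁻¹·s⁻¹·⁴.  The plateau values are redundant with
    (eta0, n, gamma_low, gamma_high) and are validated for consistency.
    """

    density_rho: float = 1050.0  # kg/m^3
    eta0: float = 0.035
    n_index: float = 0.6
    gamma_low: float = 1e-3  # 1/s
    gamma_high: float = 327.0  # 1/s
    eta_low_plateau: float = 0.55471  # Pa s
    eta_high_plateau: float = 0.00345  # Pa s

    def __post_init__(self) -> None:
        if not (0.0 < self.n_index < 1.0):
            raise ValueError(f"n_index must lie in (0, 1), got {self.n_index!r}")
        lo = self.eta0 * self.gamma_low ** (self.n_index - 1.0)
        hi = self.eta0 * self.gamma_high ** (self.n_index - 1.0)
        if abs(lo - self.eta_low_plateau) / self.eta_low_plateau > 1e-4:
            raise ValueError(
                f"low plateau inconsistent with power law: {lo} vs {self.eta_low_plateau}"
            )
        if abs(hi - self.eta_high_plateau) / self.eta_high_plateau > 1e-3:
            raise ValueError(
                f"high plateau inconsistent with power law: {hi} vs {self.eta_high_plateau}"
            )


@dataclass(frozen=True)
class PorousParams:
    """Ergun resistance of the coiled dome at one coil packing density."""

    cpd_pct: float
    kappa: float
    dp: float  # wire diameter, m
    alpha: float  # kg/m^4
    beta: float  # kg/(m^3 s)
    mu_crit: float  # Pa s


DEFAULT_WIRE_DIAMETER_M = 2.54e-4


def viscosity(gamma_dot, model: BloodModel = BloodModel()):
    """Dynamic viscosity (Pa·s) at shear rate ``gamma_dot`` (1/s).

    Accepts scalars or arrays; negative shear rates are rejected.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    with np.errstate(divide="ignore"):
        power = model.eta0 * np.where(g > 0, g, 1.0) ** (model.n_index - 1.0)
    eta = np.where(
        g <= model.gamma_low,
        model.eta_low_plateau,
        np.where(g >= model.gamma_high, model.eta_high_plateau, power),
    )
    if np.ndim(gamma_dot) == 0:
        return float(eta)
    return eta


def shear_rate_magnitude(velocity_gradient) -> float:
    """Scalar shear rate sqrt(2 D:D) from a velocity-gradient tensor.

    ``D`` is the symmetric part of the gradient.  For simple shear
    du/dy = s this reduces to s.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.ndim != 2 or grad.shape[0] != grad.shape[1] or grad.shape[0] not in (2, 3):
        raise ValueError("velocity_gradient must be a 2x2 or 3x3 tensor")
    if not np.all(np.isfinite(grad)):
        raise ValueError("velocity_gradient must be finite")
    strain = 0.5 * (grad + grad.T)
    return float(np.sqrt(2.0 * np.sum(strain * strain)))


def ergun_coefficients(
    cpd_pct: float,
    model: BloodModel = BloodModel(),
    dp: float = DEFAULT_WIRE_DIAMETER_M,
) -> PorousParams:
    """Porous resistance coefficients for a given coil packing density (%).

    The viscous term uses the high-shear plateau viscosity throughout (the
    dense coil mass keeps local shear rates ill-defined at the wire scale,
    so a single critical value is used), and the wire diameter is the
    packed-bed particle scale.
    """
    if not (0.0 <= cpd_pct < 100.0):
        raise ValueError(f"cpd_pct must lie in [0, 100), got {cpd_pct!r}")
    kappa = 1.0 - cpd_pct / 100.0
    mu = model.eta_high_plateau
    alpha = 1.75 * model.density_rho * (1.0 - kappa) / (kappa**3 * dp)
    beta = 150.0 * mu * (1.0 - kappa) ** 2 / (kappa**3 * dp**2)
    return PorousParams(
        cpd_pct=cpd_pct, kappa=kappa, dp=dp, alpha=alpha, beta=beta, mu_crit=mu
    )


def porous_sink(velocity, params: PorousParams):
    """Darcy–Forchheimer momentum sink -(beta + alpha|U|) U, Pa/m.

    ``velocity`` is the superficial velocity vector (m/s); returns the sink
    vector with the same shape.  Zero resistance (CPD = 0) returns zeros.
    """
    u = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("velocity must be finite")
    speed = np.linalg.norm(u)
    return -(params.beta + params.alpha * speed) * u
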