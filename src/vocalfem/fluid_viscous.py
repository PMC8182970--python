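"""1D viscous collapsible-tube glottal flow, solved quasi-steadily by shooting.

Steady continuity gives a constant flow rate q = w A along the channel, with
the effective area A(z) = alpha(z) A0(z) shrunk by the vena-contracta
correction alpha.  The momentum balance, after folding the separation-loss
shear stress tau_chi = (A/S)(1 - chi) rho_f w dw/dz into the advection term,
reads

    chi(z) rho_f w dw/dz = -dp/dz - 2 mu (S/A)^2 w,

with chi = 1 upstream of the minimum-area station and chi = chi_min beyond it
(pressure recovery), and wall friction modeled as fully developed duct flow.
For known q the pressure integral is exact in the advection part
(chi-weighted dynamic-pressure differences) and a trapezoid quadrature in the
friction part; the flow rate is found by bracketed Brent iteration on the
outlet pressure condition p(z_out) = p_sup.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, ShootingError
from .fluid_bernoulli import CLOSED_GAP_TOL, closed_glottis_pressure
from .geometry import ChannelProfile

_KPA = 1e-3          # kPa -> MPa
_MPA_TO_KPA = 1e3
_KG_M3 = 1e-6        # kg/m³ -> g/mm³
_PA_S = 1e-3         # Pa·s (= kg/(m s)) -> MPa·ms


@dataclass
class ViscousFlowParams:
    """Fluid constants and channel-end locations.

    Defaults model air at body conditions: density 1.14 kg/m³ and dynamic
    viscosity 1.9e-5 kg/(m s).  ``chi_min`` is the pressure-recovery constant
    downstream of the minimum area; the vena-contracta correction is
    alpha(z) = alpha0 + alpha1 (z - z_out)² / (z_in - z_out)².
    """

    rho_f: float = 1.14
    mu_f: float = 1.9e-5
    chi_min: float = 0.2
    z_in: float = -3.6
    z_out: float = 0.0
    alpha0: float = 0.75
    alpha1: float = 0.25

    def __post_init__(self):
        if self.rho_f <= 0 or self.mu_f < 0:
            raise ConfigurationError("rho_f must be positive and mu_f non-negative")
        if not 0.0 <= self.chi_min <= 1.0:
            raise ConfigurationError("chi_min must lie in [0, 1]")
        if not self.z_in < self.z_out:
            raise ConfigurationError("z_in must be below z_out")


@dataclass
class FlowSolution:
    """Steady solution: velocity w (m/s), pressure p (kPa), effective area
    A = alpha A0 (mm²) and flow rate q = w A (mm³/ms, constant along z)."""

    z: np.ndarray
    w: np.ndarray
    p: np.ndarray
    area_eff: np.ndarray
    q: float
    closed: bool = False
    bracket: tuple = field(default=(0.0, 0.0))


def alpha(z, params: ViscousFlowParams) -> np.ndarray | float:
    """Vena-contracta area-correction coefficient, clamped outside the channel."""
    zc = np.clip(z, params.z_in, params.z_out)
    return params.alpha0 + params.alpha1 * (zc - params.z_out) ** 2 / (
        params.z_in - params.z_out) ** 2


def chi_profile(channel: ChannelProfile, chi_min: float = 0.2) -> np.ndarray:
    """chi = 1 at and upstream of the minimum-area station, chi_min beyond."""
    chi = np.ones(channel.n_stations)
    chi[channel.i_min + 1:] = chi_min
    return chi


def effective_chi_min(A: np.ndarray, i_min: int, chi_min: float) -> float:
    """Recovery constant limited to values admitting a steady solution.

    In a strongly divergent instant (minimum area at or near the inlet) full
    chi_min recovery would raise the outlet pressure above p_sub for every
    flow rate, leaving the outlet boundary condition unreachable; physically
    the separated jet simply cannot recover that much.  The recovery constant
    is therefore capped so the net advection coefficient stays non-negative.
    """
    c0 = 1.0 / A[i_min] ** 2 - 1.0 / A[0] ** 2            # >= 0
    c1 = 1.0 / A[-1] ** 2 - 1.0 / A[i_min] ** 2
    if c0 + chi_min * c1 >= 0.0 or c1 >= 0.0:
        return chi_min
    return 0.999 * (c0 / -c1)


def _pressure_profile(q: float, z: np.ndarray, A: np.ndarray, S: np.ndarray,
                      i_min: int, chi_min: float, rho: float, mu: float,
                      p_sub_i: float) -> np.ndarray:
    """Exact-advection / trapezoid-friction pressure integral for flow rate q."""
    w = q / A
    dyn = 0.5 * rho * w * w
    # chi-weighted advection: chi=1 up to the minimum, chi_min after it
    adv = np.empty_like(dyn)
    adv[:i_min + 1] = dyn[:i_min + 1] - dyn[0]
    adv[i_min + 1:] = (dyn[i_min] - dyn[0]) + chi_min * (dyn[i_min + 1:] - dyn[i_min])
    # friction: dp = -2 mu (S/A)^2 w dz, trapezoid in z
    g = 2.0 * mu * (S / A) ** 2 * w
    fric = np.concatenate(([0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(z))))
    return p_sub_i - adv - fric


def solve_viscous_flow(channel: ChannelProfile, p_sub: float, p_sup: float,
                       params: ViscousFlowParams | None = None,
                       tol: float = 1e-8,
                       q_bracket: tuple | None = None) -> FlowSolution:
    """Solve the steady viscous flow through an open channel.

    Boundary pressures are p_sub at the inlet and p_sup at the outlet; the
    returned solution satisfies both within ``tol`` kPa.  A closed glottis
    falls back to the closed-glottis pressure assignment with q = 0, flagged.
    """
    params = params or ViscousFlowParams()
    z = channel.z
    if np.any(channel.gap <= CLOSED_GAP_TOL):
        p = closed_glottis_pressure(channel.gap, p_sub, p_sup)
        return FlowSolution(z=z, w=np.zeros_like(z), p=p,
                            area_eff=alpha(z, params) * channel.area,
                            q=0.0, closed=True)

    A = alpha(z, params) * channel.area            # mm²
    S = np.asarray(channel.perimeter, dtype=float)  # mm
    rho = params.rho_f * _KG_M3
    mu = params.mu_f * _PA_S
    dp = (p_sub - p_sup) * _KPA
    p_sub_i = p_sub * _KPA
    p_sup_i = p_sup * _KPA
    i_min = channel.i_min
    chi_eff = effective_chi_min(A, i_min, params.chi_min)

    if dp == 0.0:
        return FlowSolution(z=z, w=np.zeros_like(z), p=np.full_like(z, p_sub),
                            area_eff=A, q=0.0)

    def resid(q):
        return _pressure_profile(q, z, A, S, i_min, chi_eff, rho, mu,
                                 p_sub_i)[-1] - p_sup_i

    # bracket grown geometrically from the inviscid-orifice estimate
    q0 = float(A[i_min] * np.sqrt(2.0 * dp / rho))
    lo, hi = q_bracket if q_bracket is not None else (0.0, q0)
    f_lo = resid(lo)
    f_hi = resid(hi)
    for _ in range(80):
        if f_lo * f_hi <= 0:
            break
        hi *= 2.0
        f_hi = resid(hi)
    else:
        raise ShootingError(
            f"could not bracket the flow rate: resid({lo})={f_lo:.3e}, "
            f"resid({hi})={f_hi:.3e}")
    q = brentq(resid, lo, hi, xtol=1e-15 * max(q0, 1.0), rtol=8.9e-16)
    p = _pressure_profile(q, z, A, S, i_min, chi_eff, rho, mu, p_sub_i)
    if abs(p[-1] - p_sup_i) > tol * _KPA:
        raise ShootingError(
            f"outlet pressure residual {abs(p[-1] - p_sup_i) * _MPA_TO_KPA:.3e} kPa "
            "above tolerance")
    return FlowSolution(z=z, w=q / A, p=p * _MPA_TO_KPA, area_eff=A, q=q,
                        bracket=(lo, hi))
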