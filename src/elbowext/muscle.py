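"""Modified Hill-type musculotendon model for isometric contraction.

Force along the tendon at equilibrium:

    F_t = F_m cos(alpha) = F_z [f_a(l) a + f_p(l)] cos(alpha)

with the active and passive fiber force-length curves

    f_a(l) = sin(b1 x^2 + b2 x + b3),      x = l_m / l_mo   (radians)
    f_p(l) = A_P (exp(k_pe (l_m - l_mo)/l_mo) - 1)

and a piecewise tendon force-strain law: an exponential toe region up to
the transition strain eps_c followed by a linear region,

    F_t(eps) = F_z A (exp(k1 eps) - 1)                 0 <= eps < eps_c
             = k2 F_z (eps - eps_c) + F_c              eps >= eps_c

where F_c = F_z A (exp(k1 eps_c) - 1) makes the curve continuous. With the
default coefficients F_c/F_z evaluates to 0.5036 (the generic tendon's
nominal 0.5) and the tendon reaches F_z at 3.3% strain.

The study is purely isometric, so the force-velocity factor is identically
1 and activation enters only as the scalar ``a``. Negative normalized
forces are clamped to zero: the sine lobe of f_a and the exponential of
f_p below slack length are non-physical there.

Note on the active curve: with these coefficients f_a(l_mo) = 0.670
and the curve's maximum (exactly 1) sits near l_m/l_mo = 0.68. The curves
are evaluated exactly as parameterized — no re-normalization is applied —
so "optimal fiber length" here is the architectural anchor used for the
passive curve and pennation, not the argmax of f_a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import EquilibriumError, GeometryError, ParameterError


@dataclass(frozen=True)
class CurveCoefficients:
    """Dimensionless coefficients of the fiber and tendon curves."""

    A_P: float = 0.129
    k_pe: float = 4.525
    b1: float = -1.317
    b2: float = -0.403
    b3: float = 2.454
    tendon_A: float = 0.1238
    tendon_k1: float = 81.1438
    tendon_k2: float = 37.5
    eps_c: float = 0.02

    @property
    def Fc_over_Fz(self) -> float:
        """Normalized tendon force at the toe-to-linear transition (continuity value)."""
        return self.tendon_A * (math.exp(self.tendon_k1 * self.eps_c) - 1.0)

    @property
    def strain_at_Fz(self) -> float:
        """Tendon strain at which tendon force equals F_z (on the linear branch)."""
        return self.eps_c + (1.0 - self.Fc_over_Fz) / self.tendon_k2


DEFAULT_COEFFS = CurveCoefficients()


@dataclass(frozen=True)
class MusculotendonParams:
    """Architecture and strength parameters of one musculotendon actuator.

    Lengths in cm, forces in N, stress in N/cm2, pennation in degrees.
    F_z = PCSA * sigma_m when both PCSA and sigma_m are given.
    """

    muscle_id: str
    l_mo: float
    alpha_o: float
    l_to: float
    F_z: float | None = None
    sigma_m: float | None = None
    PCSA: float | None = None
    coeffs: CurveCoefficients = DEFAULT_COEFFS
    pennation_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if not self.l_mo > 0:
            raise ParameterError(f"{self.muscle_id}: l_mo must be > 0")
        if not self.l_to > 0:
            raise ParameterError(
                f"{self.muscle_id}: tendon slack length must be > 0 "
                "(check geometry/architecture consistency)"
            )
        if not (0 <= self.alpha_o < 90):
            raise ParameterError(f"{self.muscle_id}: alpha_o must be in [0, 90) deg")
        if self.F_z is None:
            if self.sigma_m is not None and self.PCSA is not None:
                object.__setattr__(self, "F_z", self.sigma_m * self.PCSA)
            else:
                raise ParameterError(f"{self.muscle_id}: need F_z or (sigma_m, PCSA)")
        elif self.sigma_m is None and self.PCSA is not None:
            object.__setattr__(self, "sigma_m", self.F_z / self.PCSA)
        if not self.F_z > 0:
            raise ParameterError(f"{self.muscle_id}: F_z must be > 0")

    def with_force(self, F_z: float) -> "MusculotendonParams":
        """Copy with a new maximum isometric force (stress re-derived from PCSA)."""
        return MusculotendonParams(
            muscle_id=self.muscle_id,
            l_mo=self.l_mo,
            alpha_o=self.alpha_o,
            l_to=self.l_to,
            F_z=F_z,
            sigma_m=None,
            PCSA=self.PCSA,
            coeffs=self.coeffs,
            pennation_table=self.pennation_table,
        )


@dataclass(frozen=True)
class MuscleState:
    """One isometric equilibrium of a musculotendon actuator."""

    l_m: float  # fiber (fascicle) length, cm
    alpha: float  # pennation, degrees
    l_t: float  # tendon length, cm
    eps_t: float  # tendon strain
    F_m: float  # fiber force, N
    F_t: float  # force along the tendon, N


# ---------------------------------------------------------------------------
# curve primitives (vectorized over l_m / eps_t)


def active_force_length(l_m, l_mo: float, coeffs: CurveCoefficients = DEFAULT_COEFFS):
    """Normalized active force-length curve, clamped below at zero."""
    if not l_mo > 0:
        raise ParameterError("l_mo must be > 0")
    x = np.asarray(l_m, dtype=float) / l_mo
    arg = coeffs.b1 * x**2 + coeffs.b2 * x + coeffs.b3
    f = np.where((arg > 0) & (arg < math.pi), np.sin(arg), 0.0)
    return f if f.ndim else float(f)


def passive_force_length(l_m, l_mo: float, coeffs: CurveCoefficients = DEFAULT_COEFFS):
    """Normalized passive force-length curve, zero at and below l_mo."""
    if not l_mo > 0:
        raise ParameterError("l_mo must be > 0")
    x = np.asarray(l_m, dtype=float) / l_mo
    f = np.maximum(coeffs.A_P * (np.exp(coeffs.k_pe * (x - 1.0)) - 1.0), 0.0)
    return f if f.ndim else float(f)


def tendon_force(eps_t, F_z: float, coeffs: CurveCoefficients = DEFAULT_COEFFS):
    """Tendon force (N) at strain ``eps_t``; zero at or below zero strain."""
    if not F_z > 0:
        raise ParameterError("F_z must be > 0")
    eps = np.asarray(eps_t, dtype=float)
    Fc = F_z * coeffs.Fc_over_Fz
    # clip the toe argument so the exponential is only evaluated on its branch
    toe = F_z * coeffs.tendon_A * (np.exp(coeffs.tendon_k1 * np.minimum(eps, coeffs.eps_c)) - 1.0)
    lin = coeffs.tendon_k2 * F_z * (eps - coeffs.eps_c) + Fc
    f = np.where(eps <= 0, 0.0, np.where(eps < coeffs.eps_c, toe, lin))
    return f if f.ndim else float(f)


def tendon_slack_length(lmt_o: float, l_mo: float, alpha_o: float) -> float:
    """Tendon slack length l_to = l_mt(optimal angle) - l_mo cos(alpha_o), cm."""
    l_to = lmt_o - l_mo * math.cos(math.radians(alpha_o))
    if not l_to > 0:
        raise ParameterError(
            f"derived tendon slack length {l_to:.3f} cm is not positive: "
            "geometry and architecture inputs are inconsistent"
        )
    return l_to


def pennation_at_fiber_length(l_m: float, l_mo: float, alpha_o: float) -> float:
    """Pennation (deg) at fiber length ``l_m`` under the constant-thickness model.

    The muscle's thickness l_m sin(alpha) is conserved as the fiber
    shortens/lengthens, so alpha(l_m) = asin(l_mo sin(alpha_o) / l_m).
    """
    h = l_mo * math.sin(math.radians(alpha_o))
    if l_m < h - 1e-12:
        raise GeometryError(
            f"fiber length {l_m:.3f} cm shorter than muscle thickness {h:.3f} cm"
        )
    return math.degrees(math.asin(min(h / l_m, 1.0)))


def _pennation_rad(l_m: float, params: MusculotendonParams) -> float:
    return math.radians(pennation_at_fiber_length(l_m, params.l_mo, params.alpha_o))


# ---------------------------------------------------------------------------
# equilibrium


def _fiber_force_along_tendon(l_m: float, a: float, params: MusculotendonParams) -> float:
    c = params.coeffs
    f = active_force_length(l_m, params.l_mo, c) * a + passive_force_length(l_m, params.l_mo, c)
    return params.F_z * f * math.cos(_pennation_rad(l_m, params))


def solve_isometric_equilibrium(
    lmt: float, a: float, params: MusculotendonParams, tol_rel: float = 1e-8
) -> MuscleState:
    """Solve the isometric fiber/tendon force balance at path length ``lmt``.

    Finds the fiber length l_m at which the fiber force resolved along the
    tendon equals the tendon force at strain (l_mt - l_m cos alpha - l_to)/l_to,
    by bracketed root finding; the residual at the returned state is below
    ``tol_rel * F_z``. If the tendon is slack at every admissible fiber
    length the zero-force rest state is returned (only possible with a = 0).
    """
    if not (0.0 <= a <= 1.0):
        raise ParameterError("activation must be in [0, 1]")
    coeffs = params.coeffs
    h = params.l_mo * math.sin(math.radians(params.alpha_o))  # constant thickness
    l_lo = h + 1e-9 * params.l_mo if h > 0 else 1e-9 * params.l_mo

    proj = lmt - params.l_to  # fiber projection l_m cos(alpha) at zero tendon strain
    if proj <= l_lo * math.cos(_pennation_rad(l_lo, params)):
        # tendon slack over the whole admissible bracket
        if a > 0:
            raise EquilibriumError(
                f"{params.muscle_id}: tendon slack at all fiber lengths "
                f"(l_mt = {lmt:.3f} cm <= slack length {params.l_to:.3f} cm) "
                "but the fiber is active"
            )
        l_m = params.l_mo if proj >= params.l_mo * math.cos(math.radians(params.alpha_o)) \
            else math.sqrt(max(proj, 0.0) ** 2 + h**2) if proj > 0 else l_lo
        alpha = pennation_at_fiber_length(l_m, params.l_mo, params.alpha_o)
        l_t = lmt - l_m * math.cos(math.radians(alpha))
        return MuscleState(l_m, alpha, l_t, (l_t - params.l_to) / params.l_to, 0.0, 0.0)

    # upper end of the bracket: fiber length at exactly zero tendon strain
    l_hi = math.sqrt(proj**2 + h**2)

    def residual(l_m: float) -> float:
        alpha = _pennation_rad(l_m, params)
        l_t = lmt - l_m * math.cos(alpha)
        eps = (l_t - params.l_to) / params.l_to
        return _fiber_force_along_tendon(l_m, a, params) - tendon_force(eps, params.F_z, coeffs)

    r_lo, r_hi = residual(l_lo), residual(l_hi)
    if r_hi <= 0 and abs(r_hi) <= tol_rel * params.F_z:
        l_m = l_hi  # rest configuration: both forces vanish
    elif r_lo > 0 or r_hi < 0:
        raise EquilibriumError(
            f"{params.muscle_id}: no sign change in the force residual over "
            f"l_m in [{l_lo:.4f}, {l_hi:.4f}] cm (residuals {r_lo:.3e}, {r_hi:.3e} N)"
        )
    else:
        l_m = brentq(residual, l_lo, l_hi, xtol=1e-12, rtol=8.9e-16)

    alpha = pennation_at_fiber_length(l_m, params.l_mo, params.alpha_o)
    l_t = lmt - l_m * math.cos(math.radians(alpha))
    eps = (l_t - params.l_to) / params.l_to
    F_t = tendon_force(eps, params.F_z, coeffs)
    F_m = _fiber_force_along_tendon(l_m, a, params) / math.cos(math.radians(alpha))
    return MuscleState(l_m, alpha, l_t, eps, F_m, F_t)
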