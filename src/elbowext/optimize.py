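"""Two-step inverse estimation of maximum isometric muscle stress/force.

Given a measured maximal isometric extension torque-angle curve on the
10-100 degree grid (2-degree steps, 46 points), the estimator minimizes the
mean-square torque error

    F = sum_i (T_i^m - T_i^p)^2 / 46        [Nm^2]

with a Nelder-Mead simplex, in two steps:

1. a single maximum isometric muscle stress sigma shared by all three
   extensor heads (one-dimensional simplex; F_z,i = sigma * PCSA_i);
2. the three per-muscle maximum isometric forces, initialized at the step-1
   solution and box-bounded to +/-15% (control) or +/-30% (stroke) of it.

Per-muscle stress is the fitted force divided by the muscle's PCSA, itself
scaled from literature cadaver values by the upper-arm-circumference ratio.

Because every force term of the musculotendon model is proportional to F_z,
the equilibrium fiber length does not depend on F_z and the predicted
torque is exactly linear in the per-muscle forces. The estimator therefore
precomputes each muscle's torque per unit F_z on the fit grid once and
evaluates the simplex objective on the exact linear combination; this is an
algebraic identity with the full forward solve (asserted in the tests), not
an approximation.

The simplex honors the step-2 box through a logistic reparameterization
x = lo + (hi - lo) * expit(u), so iterates can approach but never leave the
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ValidationError
from .geometry import moment_arm, musculotendon_length
from .muscle import solve_isometric_equilibrium
from .torque import CM_TO_M, SubjectModel, TorqueAngleCurve, predict_extension_torque


@dataclass(frozen=True)
class OptimizationConfig:
    """Grid and simplex settings for the two-step fit."""

    theta_start: float = 10.0
    theta_stop: float = 100.0
    theta_step: float = 2.0
    bounds_fraction_control: float = 0.15
    bounds_fraction_stroke: float = 0.30
    fatol: float = 1e-6  # Nm^2, absolute on the mean-square objective
    maxiter: int = 2000

    def grid(self) -> np.ndarray:
        n = int(round((self.theta_stop - self.theta_start) / self.theta_step)) + 1
        return self.theta_start + self.theta_step * np.arange(n)

    def bounds_fraction(self, group: str) -> float:
        if group == "control":
            return self.bounds_fraction_control
        if group == "stroke":
            return self.bounds_fraction_stroke
        raise ValidationError(f"unknown group {group!r}")


DEFAULT_CONFIG = OptimizationConfig()


def optimization_grid(config: OptimizationConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The torque-matching joint-angle grid (degrees); 46 points by default."""
    return config.grid()


def objective(measured: TorqueAngleCurve, predicted: TorqueAngleCurve) -> float:
    """Mean-square torque difference (Nm^2) over the shared grid."""
    if measured.theta.shape != predicted.theta.shape or not np.allclose(
        measured.theta, predicted.theta
    ):
        raise ValidationError("measured and predicted curves must share the same grid")
    d = measured.torque - predicted.torque
    return float(d @ d / d.size)


def scale_pcsa(
    pcsa_lit: dict[str, float], cadaver_circumference: float, subject_circumference: float
) -> dict[str, float]:
    """Scale literature PCSA (cm2) by the upper-arm circumference ratio."""
    if not (cadaver_circumference > 0 and subject_circumference > 0):
        raise ValidationError("circumferences must be > 0")
    if any(v <= 0 for v in pcsa_lit.values()):
        raise ValidationError("literature PCSA values must be > 0")
    ratio = subject_circumference / cadaver_circumference
    return {mid: v * ratio for mid, v in pcsa_lit.items()}


def torque_basis(model: SubjectModel, theta_grid) -> np.ndarray:
    """Per-muscle torque (Nm) per unit F_z on ``theta_grid``: shape (n, k).

    Column order follows ``model.muscles``. Exact because the equilibrium
    fiber length is invariant to F_z.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    cols = []
    for mid in model.muscles:
        path = model.paths[mid]
        p = model.params[mid].with_force(1.0)
        col = np.empty(theta_grid.size)
        for j, th in enumerate(theta_grid):
            lmt = musculotendon_length(path, th)
            state = solve_isometric_equilibrium(lmt, model.activation, p)
            col[j] = state.F_t * moment_arm(path, th) * CM_TO_M
        cols.append(col)
    return np.stack(cols, axis=1)


class MaxStressEstimator(BaseEstimator, RegressorMixin):
    """Two-step Nelder-Mead estimator of maximum isometric muscle stress.

    Parameters
    ----------
    model : SubjectModel
        Scaled geometry plus architecture parameters for the three heads;
        each muscle's PCSA must be set (the F_z values are fit targets and
        any initial values are ignored).
    group : {"control", "stroke"}
        Selects the step-2 search-box half-width (15% vs 30%).
    config : OptimizationConfig
        Grid and simplex settings.

    Attributes
    ----------
    sigma_common_ : float
        Step-1 shared maximum isometric muscle stress, N/cm2.
    forces_ : dict[str, float]
        Step-2 per-muscle maximum isometric forces F_z, N.
    sigma_m_ : dict[str, float]
        Per-muscle stress F_z / PCSA, N/cm2.
    objective_, rms_ : float
        Final mean-square error (Nm^2) and its square root (Nm).
    objective_step1_ : float
        Step-1 mean-square error (Nm^2).
    bounds_ : dict[str, tuple[float, float]]
        Step-2 per-muscle force box, N.
    converged_ : bool
        True when both simplex calls reported success.
    n_iter_ : int
        Total simplex iterations across both steps.
    """

    def __init__(
        self,
        model: SubjectModel,
        group: str = "control",
        config: OptimizationConfig = DEFAULT_CONFIG,
    ):
        self.model = model
        self.group = group
        self.config = config

    # -- internals ----------------------------------------------------------

    def _initial_stress(self, torque: np.ndarray, basis_grid: np.ndarray) -> float:
        """Peak measured torque over sum(PCSA_i * MA_i) at 90 degrees (N/cm2)."""
        denom = sum(
            self.model.params[mid].PCSA * moment_arm(self.model.paths[mid], 90.0) * CM_TO_M
            for mid in self.model.muscles
        )
        return float(np.max(torque) / denom)

    def fit(self, X, y):
        """Fit to a measured torque-angle curve.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Joint angles, degrees, strictly increasing.
        y : array-like, shape (n,)
            Measured maximal isometric extension torque, Nm.
        """
        theta = np.asarray(X, dtype=float)
        if theta.ndim == 2 and theta.shape[1] == 1:
            theta = theta[:, 0]
        torque = np.asarray(y, dtype=float)
        measured = TorqueAngleCurve(theta, torque, provenance="measured")

        muscles = self.model.muscles
        pcsa = np.array([self.model.params[m].PCSA for m in muscles], dtype=float)
        if np.any(~np.isfinite(pcsa)) or np.any(pcsa <= 0):
            raise ValidationError("every muscle needs a positive PCSA to fit stress")
        G = torque_basis(self.model, theta)  # (n, k), Nm per N
        n = torque.size

        def mse(forces: np.ndarray) -> float:
            r = torque - G @ forces
            return float(r @ r / n)

        # step 1: one shared stress
        sigma0 = self._initial_stress(torque, theta)
        res1 = minimize(
            lambda s: mse(s[0] * pcsa),
            x0=[sigma0],
            method="Nelder-Mead",
            options={"fatol": self.config.fatol, "xatol": 1e-8, "maxiter": self.config.maxiter},
        )
        sigma1 = float(res1.x[0])
        f1 = sigma1 * pcsa
        self.sigma_common_ = sigma1
        self.objective_step1_ = float(res1.fun)

        # step 2: per-muscle forces inside the logistic-mapped box
        frac = self.config.bounds_fraction(self.group)
        lo, hi = f1 * (1.0 - frac), f1 * (1.0 + frac)

        def to_forces(u: np.ndarray) -> np.ndarray:
            return lo + (hi - lo) * expit(u)

        res2 = minimize(
            lambda u: mse(to_forces(u)),
            x0=np.zeros(len(muscles)),  # expit(0) = 0.5: the step-1 solution
            method="Nelder-Mead",
            options={"fatol": self.config.fatol, "xatol": 1e-10, "maxiter": self.config.maxiter},
        )
        forces = to_forces(res2.x)
        # the step-1 point is inside the box, so step 2 can never be worse
        if res2.fun > self.objective_step1_:
            forces, res2fun = f1, self.objective_step1_
        else:
            res2fun = float(res2.fun)

        self.bounds_ = {m: (float(l), float(h)) for m, l, h in zip(muscles, lo, hi)}
        self.forces_ = {m: float(f) for m, f in zip(muscles, forces)}
        self.sigma_m_ = {m: float(f / p) for m, f, p in zip(muscles, forces, pcsa)}
        self.objective_ = res2fun
        self.rms_ = float(np.sqrt(res2fun))
        self.converged_ = bool(res1.success and res2.success)
        self.n_iter_ = int(res1.nit + res2.nit)
        self.basis_ = G
        self.theta_ = theta
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted torque (Nm) at angles ``X`` from the fitted forces."""
        theta = np.asarray(X, dtype=float)
        if theta.ndim == 2 and theta.shape[1] == 1:
            theta = theta[:, 0]
        fitted = self.model.with_forces(self.forces_)
        return predict_extension_torque(fitted, theta).torque


@dataclass(frozen=True)
class OptimizationResult:
    """Plain record of a finished two-step fit."""

    sigma_common: float
    forces: dict[str, float]
    sigma_m: dict[str, float]
    objective: float
    rms: float
    objective_step1: float
    bounds: dict[str, tuple[float, float]]
    converged: bool
    n_iter: int

    @classmethod
    def from_estimator(cls, est: MaxStressEstimator) -> "OptimizationResult":
        return cls(
            sigma_common=est.sigma_common_,
            forces=est.forces_,
            sigma_m=est.sigma_m_,
            objective=est.objective_,
            rms=est.rms_,
            objective_step1=est.objective_step1_,
            bounds=est.bounds_,
            converged=est.converged_,
            n_iter=est.n_iter_,
        )


def fit_step1_common_stress(
    model: SubjectModel,
    measured: TorqueAngleCurve,
    config: OptimizationConfig = DEFAULT_CONFIG,
    group: str = "control",
) -> float:
    """Step 1 only: the shared maximum isometric muscle stress (N/cm2)."""
    est = MaxStressEstimator(model, group=group, config=config)
    est.fit(measured.theta, measured.torque)
    return est.sigma_common_


def fit_two_step(
    model: SubjectModel,
    measured: TorqueAngleCurve,
    config: OptimizationConfig = DEFAULT_CONFIG,
    group: str = "control",
) -> OptimizationResult:
    """Run both steps and return a plain result record."""
    est = MaxStressEstimator(model, group=group, config=config)
    est.fit(measured.theta, measured.torque)
    return OptimizationResult.from_estimator(est)


def fit_step2_per_muscle_force(
    model: SubjectModel,
    measured: TorqueAngleCurve,
    config: OptimizationConfig = DEFAULT_CONFIG,
    group: str = "control",
) -> OptimizationResult:
    """The full two-step fit (step 2 requires step 1's solution as its anchor)."""
    return fit_two_step(model, measured, config=config, group=group)
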