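"""Forward prediction of maximal isometric elbow-extension torque.

The joint torque at flexion angle theta is the sum of the three extensor
heads' contributions, each the tendon force from the isometric equilibrium
solve times the muscle's moment arm:

    T(theta) = sum_i F_t,i(theta) * MA_i(theta)

Forces are in N, moment arms in cm and torques in Nm; the single N*cm -> Nm
conversion lives in :data:`CM_TO_M`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EquilibriumError, ValidationError
from .geometry import MusclePath, moment_arm, musculotendon_length
from .muscle import MusculotendonParams, solve_isometric_equilibrium

#: the one place cm-valued moment arms become meters
CM_TO_M = 0.01


@dataclass(frozen=True)
class TorqueAngleCurve:
    """Torque (Nm) sampled on an ordered joint-angle grid (degrees)."""

    theta: np.ndarray
    torque: np.ndarray
    provenance: str = "predicted"  # measured | predicted | fitted
    components: dict | None = None  # per-muscle Nm columns, if available

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        tq = np.asarray(self.torque, dtype=float)
        if th.ndim != 1 or th.shape != tq.shape:
            raise ValidationError("theta and torque must be 1-D arrays of equal length")
        if th.size >= 2 and not np.all(np.diff(th) > 0):
            raise ValidationError("theta grid must be strictly increasing")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "torque", tq)

    def __len__(self):
        return self.theta.size


@dataclass
class SubjectModel:
    """A subject's scaled muscle paths plus per-muscle architecture parameters."""

    paths: dict[str, MusclePath]
    params: dict[str, MusculotendonParams]
    activation: float = 1.0

    def __post_init__(self):
        missing = set(self.params) - set(self.paths)
        if missing:
            raise ValidationError(f"no geometry for muscles {sorted(missing)}")

    @property
    def muscles(self) -> list[str]:
        return list(self.params)

    def with_forces(self, forces: dict[str, float]) -> "SubjectModel":
        params = {
            mid: (p.with_force(forces[mid]) if mid in forces else p)
            for mid, p in self.params.items()
        }
        return SubjectModel(paths=self.paths, params=params, activation=self.activation)


def predict_extension_torque(
    model: SubjectModel, theta_grid, activation: float | None = None
) -> TorqueAngleCurve:
    """Predict the maximal isometric extension torque-angle curve.

    For each grid angle the musculotendon length and moment arm are taken
    from the path geometry, the fiber/tendon equilibrium is solved per
    muscle, and torques are summed across muscles. Per-muscle components
    are returned alongside the total.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    a = model.activation if activation is None else activation
    comps = {mid: np.empty(theta_grid.size) for mid in model.muscles}
    for mid in model.muscles:
        path = model.paths[mid]
        p = model.params[mid]
        for j, th in enumerate(theta_grid):
            lmt = musculotendon_length(path, th)
            ma = moment_arm(path, th)
            try:
                state = solve_isometric_equilibrium(lmt, a, p)
            except EquilibriumError as err:
                raise EquilibriumError(f"{mid} at theta={th:g} deg: {err}") from err
            comps[mid][j] = state.F_t * ma * CM_TO_M
    total = np.sum(list(comps.values()), axis=0)
    return TorqueAngleCurve(theta_grid, total, provenance="predicted", components=comps)
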