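"""Architecture parameters from digitized ultrasound landmarks.

Each B-mode frame is digitized offline into a fascicle segment, a deep
aponeurosis line, and the two extrapolation distances MT1 (fiber proximal
end to the bone) and MT2 (fiber distal end to the superficial aponeurosis).
Pennation is the acute angle between fascicle and deep aponeurosis; the
full fascicle length completes the visualized part planimetrically:

    L = L_f + MT1 / sin(alpha) + MT2 / sin(alpha)

The subject parameter set anchors the optimal fiber length and pennation
at the 90-degree "optimal" elbow angle, takes the musculotendon length
there from the scaled path geometry, and derives the tendon slack length
as l_to = l_mt(90) - l_mo cos(alpha_o).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import ValidationError
from .geometry import MusclePath, musculotendon_length
from .muscle import MusculotendonParams, tendon_slack_length

OPTIMAL_ANGLE = 90.0  # degrees of elbow flexion
MM_TO_CM = 0.1


@dataclass(frozen=True)
class UltrasoundFrame:
    """Digitized landmarks of one frame (image coordinates in px, distances mm)."""

    muscle_id: str
    joint_angle: float  # degrees of flexion
    scale: float  # mm per pixel
    fascicle: tuple[tuple[float, float], tuple[float, float]]  # visualized segment, px
    aponeurosis: tuple[tuple[float, float], tuple[float, float]]  # deep aponeurosis line, px
    mt1: float = 0.0  # mm, proximal extrapolation distance
    mt2: float = 0.0  # mm, distal extrapolation distance

    def __post_init__(self):
        if not self.scale > 0:
            raise ValidationError("pixel scale must be > 0")
        if self.mt1 < 0 or self.mt2 < 0:
            raise ValidationError("MT distances must be >= 0")
        for name in ("fascicle", "aponeurosis"):
            (x0, y0), (x1, y1) = getattr(self, name)
            if math.hypot(x1 - x0, y1 - y0) < 1e-12:
                raise ValidationError(f"degenerate {name} segment")


def _direction(seg) -> np.ndarray:
    (x0, y0), (x1, y1) = seg
    v = np.array([x1 - x0, y1 - y0], dtype=float)
    return v / np.linalg.norm(v)


def pennation_from_frame(frame: UltrasoundFrame) -> float:
    """Acute angle (deg) between the fascicle and the deep aponeurosis."""
    u = _direction(frame.fascicle)
    v = _direction(frame.aponeurosis)
    cosang = abs(float(u @ v))
    return math.degrees(math.acos(min(cosang, 1.0)))


def fascicle_length_visualized(frame: UltrasoundFrame) -> float:
    """Length (cm) of the digitized fascicle segment."""
    (x0, y0), (x1, y1) = frame.fascicle
    return math.hypot(x1 - x0, y1 - y0) * frame.scale * MM_TO_CM


def fascicle_length_extrapolated(frame: UltrasoundFrame) -> float:
    """Full fascicle length (cm): visualized part plus MT1/sin + MT2/sin terms."""
    L = fascicle_length_visualized(frame)
    extra_mm = frame.mt1 + frame.mt2
    if extra_mm > 0:
        alpha = math.radians(pennation_from_frame(frame))
        if math.sin(alpha) < 1e-9:
            raise ValidationError(
                "cannot extrapolate fascicle with zero pennation and nonzero MT distances"
            )
        L += (frame.mt1 / math.sin(alpha) + frame.mt2 / math.sin(alpha)) * MM_TO_CM
    return L


@dataclass(frozen=True)
class PennationRegression:
    """Linear pennation-vs-joint-angle fit: alpha = slope * theta + intercept."""

    slope: float  # deg per deg
    intercept: float  # deg
    r_squared: float
    muscle_id: str = ""
    group: str = ""

    def __call__(self, theta) -> np.ndarray:
        return self.slope * np.asarray(theta, dtype=float) + self.intercept


def pennation_regression(
    theta, alpha, muscle_id: str = "", group: str = ""
) -> PennationRegression:
    """Ordinary least-squares line through (joint angle, pennation) points."""
    th = np.asarray(theta, dtype=float)
    al = np.asarray(alpha, dtype=float)
    if th.ndim != 1 or th.shape != al.shape:
        raise ValidationError("theta and alpha must be 1-D arrays of equal length")
    if np.unique(th).size < 3:
        raise ValidationError("need at least 3 distinct joint angles")
    res = sstats.linregress(th, al)
    r2 = float(res.rvalue**2) if np.std(al) > 0 else 0.0
    return PennationRegression(float(res.slope), float(res.intercept), r2, muscle_id, group)


def assemble_subject_params(
    frames: list[UltrasoundFrame],
    path: MusclePath,
    pcsa: float,
    optimal_angle: float = OPTIMAL_ANGLE,
    extrapolate: bool = True,
    interpolate_missing: bool = False,
) -> MusculotendonParams:
    """Build one muscle's architecture parameters from its frame series.

    l_mo and alpha_o are read from the frame at the optimal joint angle
    (linear interpolation between the bracketing frames when permitted and
    no exact frame exists); l_mt at the optimal angle comes from the scaled
    geometry and the tendon slack length follows from the length identity.
    """
    if not frames:
        raise ValidationError("no frames supplied")
    mids = {f.muscle_id for f in frames}
    if len(mids) != 1:
        raise ValidationError(f"frames mix muscles {sorted(mids)}")
    length_of = fascicle_length_extrapolated if extrapolate else fascicle_length_visualized

    angles = np.array([f.joint_angle for f in frames])
    exact = [f for f in frames if abs(f.joint_angle - optimal_angle) < 1e-9]
    if exact:
        l_mo = length_of(exact[0])
        alpha_o = pennation_from_frame(exact[0])
    elif interpolate_missing:
        below = [f for f in frames if f.joint_angle < optimal_angle]
        above = [f for f in frames if f.joint_angle > optimal_angle]
        if not below or not above:
            raise ValidationError(
                f"cannot interpolate: no frames bracket the optimal angle {optimal_angle}"
            )
        f0 = max(below, key=lambda f: f.joint_angle)
        f1 = min(above, key=lambda f: f.joint_angle)
        w = (optimal_angle - f0.joint_angle) / (f1.joint_angle - f0.joint_angle)
        l_mo = (1 - w) * length_of(f0) + w * length_of(f1)
        alpha_o = (1 - w) * pennation_from_frame(f0) + w * pennation_from_frame(f1)
    else:
        raise ValidationError(
            f"no frame at the optimal angle {optimal_angle} deg "
            f"(measured angles: {sorted(angles.tolist())}); "
            "pass interpolate_missing=True to allow interpolation"
        )

    lmt_o = musculotendon_length(path, optimal_angle)
    l_to = tendon_slack_length(lmt_o, l_mo, alpha_o)
    return MusculotendonParams(
        muscle_id=frames[0].muscle_id,
        l_mo=l_mo,
        alpha_o=alpha_o,
        l_to=l_to,
        sigma_m=1.0,  # placeholder strength; the optimizer fits F_z
        PCSA=pcsa,
    )
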