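"""Seeded generator of synthetic subjects and cohorts.

The generator emulates the study's data products — cohort anthropometry,
pennation-vs-angle series, digitized ultrasound frames, and maximal
isometric torque-angle measurements — with known hidden ground truth, so
the whole inverse pipeline can be exercised and scored without any human
data.

Group-level distributions mirror the study population: maximum isometric
muscle stress N(89.3, 21.8) N/cm2 for controls and N(50.8, 18.6) for the
stroke group (truncated above 10 N/cm2 by redraw); optimal fascicle
lengths are drawn near the study's per-head means; pennation follows the
unimpaired-group regressions (the hemiparetic group measured "similar"
angles, so both groups share them) evaluated per joint angle plus noise.
Measured torque points are the forward model at the truth parameters plus
Gaussian noise scaled to the curve peak.

Per-head stress heterogeneity within a subject is a multiplicative
N(1, 0.05) factor truncated to [0.85, 1.15] by redraw: the study found no
significant stress difference among the three heads, so heads share the
subject's stress up to a small dispersion (which also keeps truths inside
the control-group search box of the two-step fit).

All randomness flows through an explicit ``numpy.random.Generator``; no
global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import load_geometry, load_literature
from .errors import ValidationError
from .geometry import GeometryConfig, musculotendon_length, scale_geometry
from .muscle import MusculotendonParams, tendon_slack_length
from .optimize import scale_pcsa
from .signals import DEFAULT_RATE, TimeSeries
from .torque import SubjectModel, predict_extension_torque
from .ultrasound import OPTIMAL_ANGLE, PennationRegression, UltrasoundFrame

MUSCLES = ("MHT", "LatHT", "LngHT")

#: group stress distributions, N/cm2 (mean, SD)
GROUP_STRESS = {"control": (89.3, 21.8), "stroke": (50.8, 18.6)}
STRESS_FLOOR = 10.0  # N/cm2, redraw below this

#: unimpaired-group pennation-vs-angle regressions (deg = slope*theta + intercept)
PENNATION_REGRESSIONS = {
    "MHT": PennationRegression(-0.05, 11.43, 0.843, "MHT"),
    "LatHT": PennationRegression(0.019, 8.14, 0.648, "LatHT"),
    "LngHT": PennationRegression(-0.051, 12.99, 0.913, "LngHT"),
}

#: optimal fascicle length draws, cm (mean, SD) per group
L_MO_DISTRIBUTIONS = {
    "control": {"MHT": (8.8, 2.2), "LatHT": (11.0, 2.8), "LngHT": (9.2, 2.3)},
    "stroke": {"MHT": (10.9, 2.1), "LatHT": (12.8, 1.9), "LngHT": (10.5, 2.4)},
}
L_MO_FLOOR = 4.5  # cm; keeps the fiber operating range physical at full extension

#: anthropometry draws, cm (mean, SD)
ANTHROPOMETRY = {
    "control": {"upper_arm": (30.0, 2.0), "forearm": (25.0, 1.8), "circumference": (29.5, 2.5)},
    "stroke": {"upper_arm": (30.0, 2.0), "forearm": (25.0, 1.8), "circumference": (28.5, 2.5)},
}

#: joint angles of the measurement protocols, degrees
TORQUE_ANGLES = np.arange(0.0, 106.0, 15.0)  # 8 positions, 0-105
ULTRASOUND_ANGLES = np.arange(15.0, 106.0, 15.0)  # 7 positions, 15-105


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the generator."""

    torque_noise_frac: float = 0.05  # SD as a fraction of the peak torque
    pennation_sd_deg: float = 1.0
    landmark_jitter_mm: float = 0.2
    sigma_spread: float = 0.05  # per-head stress dispersion (SD of the factor)

    def __post_init__(self):
        for name in ("torque_noise_frac", "pennation_sd_deg", "landmark_jitter_mm", "sigma_spread"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


DEFAULT_NOISE = NoiseModel()
NO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden generating parameters of one synthetic subject."""

    group: str
    sigma_m: dict[str, float]  # N/cm2 per muscle
    F_z: dict[str, float]  # N per muscle
    l_mo: dict[str, float]  # cm
    alpha_o: dict[str, float]  # deg
    l_to: dict[str, float]  # cm
    PCSA: dict[str, float]  # cm2


@dataclass(frozen=True)
class SubjectRecord:
    """What the pipeline under test is allowed to see."""

    subject_id: str
    group: str
    upper_arm_length: float  # cm
    forearm_length: float  # cm
    arm_circumference: float  # cm
    frames: tuple[UltrasoundFrame, ...]
    torque_theta: np.ndarray  # deg
    torque: np.ndarray  # Nm


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, floor, ceil=math.inf) -> float:
    """Redraw (not clip) until the draw lands inside (floor, ceil)."""
    if sd == 0:
        return float(min(max(mean, floor), ceil))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if floor < x < ceil:
            return float(x)
    raise ValidationError("truncated draw failed after 1000 attempts; check bounds")


def make_frame(
    muscle_id: str,
    joint_angle: float,
    pennation_deg: float,
    fascicle_length_cm: float,
    rng: np.random.Generator | None = None,
    jitter_mm: float = 0.0,
    scale: float = 0.1,
    visible_fraction: float = 0.7,
) -> UltrasoundFrame:
    """Construct landmark coordinates realizing a pennation and fascicle length.

    The deep aponeurosis is drawn horizontal; the fascicle leaves it at the
    requested angle. ``visible_fraction`` of the fascicle is digitized and
    the remainder is split evenly between the MT1 and MT2 extrapolation
    distances (measured perpendicular, i.e. along length * sin(alpha)).
    Optional landmark jitter perturbs every digitized coordinate.
    """
    if not (0 < visible_fraction <= 1):
        raise ValidationError("visible_fraction must be in (0, 1]")
    alpha = math.radians(pennation_deg)
    L_px = fascicle_length_cm * 10.0 / scale  # full length in px
    visible_px = visible_fraction * L_px
    hidden_cm = (1.0 - visible_fraction) * fascicle_length_cm
    mt_each_mm = 0.5 * hidden_cm * math.sin(alpha) * 10.0

    apo = [[50.0, 300.0], [450.0, 300.0]]
    fx0, fy0 = 100.0, 300.0
    fas = [[fx0, fy0], [fx0 + visible_px * math.cos(alpha), fy0 - visible_px * math.sin(alpha)]]
    if jitter_mm > 0 and rng is not None:
        jit = jitter_mm / scale
        fas = (np.asarray(fas) + rng.normal(0.0, jit, size=(2, 2))).tolist()
        apo = (np.asarray(apo) + rng.normal(0.0, jit, size=(2, 2))).tolist()
    return UltrasoundFrame(
        muscle_id=muscle_id,
        joint_angle=float(joint_angle),
        scale=scale,
        fascicle=(tuple(fas[0]), tuple(fas[1])),
        aponeurosis=(tuple(apo[0]), tuple(apo[1])),
        mt1=mt_each_mm,
        mt2=mt_each_mm,
    )


def generate_subject(
    group: str,
    seed,
    noise: NoiseModel = DEFAULT_NOISE,
    geometry: GeometryConfig | None = None,
    subject_id: str = "sub-000",
) -> tuple[SubjectRecord, GroundTruth]:
    """Draw one synthetic subject with its hidden ground truth."""
    if group not in GROUP_STRESS:
        raise ValidationError(f"unknown group {group!r}")
    rng = _rng(seed)
    geometry = geometry or load_geometry()
    lit = load_literature()

    anth = ANTHROPOMETRY[group]
    upper_arm = _truncated_normal(rng, *anth["upper_arm"], floor=20.0)
    forearm = _truncated_normal(rng, *anth["forearm"], floor=16.0)
    circumference = _truncated_normal(rng, *anth["circumference"], floor=18.0)

    paths = scale_geometry(geometry, upper_arm, forearm)
    pcsa = scale_pcsa(lit["pcsa"], lit["cadaver_arm_circumference"], circumference)

    mean_sigma, sd_sigma = GROUP_STRESS[group]
    sigma_base = _truncated_normal(rng, mean_sigma, sd_sigma, floor=STRESS_FLOOR)

    truth_sigma, truth_F, truth_lmo, truth_ao, truth_lto = {}, {}, {}, {}, {}
    params = {}
    for mid in MUSCLES:
        lmt_o = musculotendon_length(paths[mid], OPTIMAL_ANGLE)
        mean_l, sd_l = L_MO_DISTRIBUTIONS[group][mid]
        for _ in range(1000):
            l_mo = _truncated_normal(rng, mean_l, sd_l, floor=L_MO_FLOOR)
            alpha_o = max(
                1.0,
                float(PENNATION_REGRESSIONS[mid](OPTIMAL_ANGLE))
                + rng.normal(0.0, noise.pennation_sd_deg),
            )
            l_to = lmt_o - l_mo * math.cos(math.radians(alpha_o))
            if l_to > 1.0:
                break
        else:
            raise ValidationError(f"{mid}: could not draw a consistent architecture")
        factor = _truncated_normal(rng, 1.0, noise.sigma_spread, floor=0.85, ceil=1.15)
        sigma = sigma_base * factor
        truth_sigma[mid] = sigma
        truth_F[mid] = sigma * pcsa[mid]
        truth_lmo[mid] = l_mo
        truth_ao[mid] = alpha_o
        truth_lto[mid] = tendon_slack_length(lmt_o, l_mo, alpha_o)
        params[mid] = MusculotendonParams(
            muscle_id=mid, l_mo=l_mo, alpha_o=alpha_o, l_to=truth_lto[mid],
            sigma_m=sigma, PCSA=pcsa[mid],
        )
    truth = GroundTruth(
        group=group, sigma_m=truth_sigma, F_z=truth_F,
        l_mo=truth_lmo, alpha_o=truth_ao, l_to=truth_lto, PCSA=pcsa,
    )

    model = SubjectModel(paths=paths, params=params, activation=1.0)
    theta_pts, torque_pts = generate_measured_torque(model, rng, noise)
    frames = generate_ultrasound_frames(truth, rng, noise)

    record = SubjectRecord(
        subject_id=subject_id,
        group=group,
        upper_arm_length=upper_arm,
        forearm_length=forearm,
        arm_circumference=circumference,
        frames=tuple(frames),
        torque_theta=theta_pts,
        torque=torque_pts,
    )
    return record, truth


def generate_measured_torque(
    model: SubjectModel,
    seed,
    noise: NoiseModel = DEFAULT_NOISE,
    angles=TORQUE_ANGLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-model torque at the measurement angles plus Gaussian noise."""
    rng = _rng(seed)
    angles = np.asarray(angles, dtype=float)
    clean = predict_extension_torque(model, angles).torque
    sd = noise.torque_noise_frac * float(np.max(np.abs(clean)))
    noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
    return angles, noisy


def generate_torque_trace(
    target_nm: float,
    seed,
    rate: float = DEFAULT_RATE,
    ramp_s: float = 1.0,
    hold_s: float = 3.0,
    noise_nm: float = 0.1,
) -> TimeSeries:
    """A raw ramp-hold-release MVC contraction trace at the sampling rate."""
    rng = _rng(seed)
    n_ramp = int(ramp_s * rate)
    n_hold = int(hold_s * rate)
    profile = np.concatenate(
        [
            np.linspace(0.0, target_nm, n_ramp, endpoint=False),
            np.full(n_hold, target_nm),
            np.linspace(target_nm, 0.0, n_ramp),
        ]
    )
    if noise_nm > 0:
        profile = profile + rng.normal(0.0, noise_nm, size=profile.shape)
    return TimeSeries(profile, rate, label="torque")


def generate_ultrasound_frames(
    truth: GroundTruth,
    seed,
    noise: NoiseModel = DEFAULT_NOISE,
    angles=ULTRASOUND_ANGLES,
) -> list[UltrasoundFrame]:
    """Frames realizing the regression pennation and the truth architecture.

    The frame at the optimal angle realizes the subject's true (l_mo,
    alpha_o) exactly up to landmark jitter; other angles follow the
    group/muscle regression line plus pennation noise, with fascicle length
    from the constant-thickness relation l(theta) = l_mo sin(alpha_o) /
    sin(alpha(theta)).
    """
    rng = _rng(seed)
    frames = []
    for mid in MUSCLES:
        reg = PENNATION_REGRESSIONS[mid]
        thick = truth.l_mo[mid] * math.sin(math.radians(truth.alpha_o[mid]))
        all_angles = sorted(set(np.asarray(angles, dtype=float)) | {OPTIMAL_ANGLE})
        for th in all_angles:
            if abs(th - OPTIMAL_ANGLE) < 1e-9:
                alpha, length = truth.alpha_o[mid], truth.l_mo[mid]
            else:
                alpha = max(1.0, float(reg(th)) + rng.normal(0.0, noise.pennation_sd_deg))
                length = thick / math.sin(math.radians(alpha))
            frames.append(
                make_frame(
                    mid, th, alpha, length,
                    rng=rng, jitter_mm=noise.landmark_jitter_mm,
                )
            )
    return frames


def generate_cohort(
    n_per_group: int,
    seed: int,
    noise: NoiseModel = DEFAULT_NOISE,
    geometry: GeometryConfig | None = None,
) -> list[tuple[SubjectRecord, GroundTruth]]:
    """Draw a control + stroke cohort; each subject gets an independent
    child seed so cohorts are reproducible and subjects are uncorrelated."""
    if n_per_group < 2:
        raise ValidationError("need at least 2 subjects per group")
    geometry = geometry or load_geometry()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    out = []
    k = 0
    for group in ("control", "stroke"):
        for i in range(n_per_group):
            rec, truth = generate_subject(
                group,
                np.random.default_rng(children[k]),
                noise=noise,
                geometry=geometry,
                subject_id=f"{group}-{i + 1:03d}",
            )
            out.append((rec, truth))
            k += 1
    return out
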