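"""End-to-end subject fits and cohort analysis.

``fit_subject`` chains the full inverse pipeline for one subject: scale the
path geometry by segment ratios, assemble per-muscle architecture from the
ultrasound frames (optimal fiber length and pennation at 90 degrees, tendon
slack length from the length identity), scale literature PCSA by arm
circumference, fit the measured torque-angle points with a third-order
polynomial resampled on the 46-point grid, and run the two-step stress
estimator. ``analyze_cohort`` applies the statistical battery to the
per-subject results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import load_geometry, load_literature
from .errors import ElbowExtError
from .geometry import GeometryConfig, scale_geometry
from .optimize import (DEFAULT_CONFIG, MaxStressEstimator, OptimizationConfig,
                       OptimizationResult, scale_pcsa)
from .signals import fit_torque_angle, resample_torque_angle
from .stats import ExtensorGroupTest, compare_extensor_stress
from .synthetic import MUSCLES, SubjectRecord
from .torque import SubjectModel
from .ultrasound import assemble_subject_params

#: polynomial order used to build the measured 46-point curve
TORQUE_FIT_ORDER = 3


@dataclass(frozen=True)
class SubjectFit:
    """Everything the pipeline derived for one subject."""

    subject_id: str
    group: str
    result: OptimizationResult
    theta_grid: np.ndarray
    measured_torque: np.ndarray  # polynomial-resampled, Nm
    predicted_torque: np.ndarray  # at the fitted forces, Nm
    params: dict  # assembled MusculotendonParams per muscle
    torque_fit_r2: float

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "sigma_common_n_per_cm2": self.result.sigma_common,
            "sigma_m_n_per_cm2": self.result.sigma_m,
            "F_z_n": self.result.forces,
            "rms_nm": self.result.rms,
            "objective_nm2": self.result.objective,
            "converged": self.result.converged,
            "n_iter": self.result.n_iter,
            "torque_fit_r2": self.torque_fit_r2,
            "l_mo_cm": {m: p.l_mo for m, p in self.params.items()},
            "alpha_o_deg": {m: p.alpha_o for m, p in self.params.items()},
            "l_to_cm": {m: p.l_to for m, p in self.params.items()},
            "PCSA_cm2": {m: p.PCSA for m, p in self.params.items()},
        }


def build_subject_model(
    record: SubjectRecord,
    geometry: GeometryConfig | None = None,
    literature: dict | None = None,
) -> SubjectModel:
    """Scaled paths + ultrasound-derived architecture for one subject."""
    geometry = geometry or load_geometry()
    lit = literature or load_literature()
    paths = scale_geometry(geometry, record.upper_arm_length, record.forearm_length)
    pcsa = scale_pcsa(lit["pcsa"], lit["cadaver_arm_circumference"], record.arm_circumference)
    params = {}
    for mid in MUSCLES:
        frames = [f for f in record.frames if f.muscle_id == mid]
        params[mid] = assemble_subject_params(
            frames, paths[mid], pcsa[mid], interpolate_missing=True
        )
    return SubjectModel(paths=paths, params=params, activation=1.0)


def fit_subject(
    record: SubjectRecord,
    geometry: GeometryConfig | None = None,
    config: OptimizationConfig = DEFAULT_CONFIG,
    torque_fit_order: int | None = TORQUE_FIT_ORDER,
) -> SubjectFit:
    """Run the complete inverse pipeline for one subject."""
    model = build_subject_model(record, geometry)
    pf = fit_torque_angle(record.torque_theta, record.torque, order=torque_fit_order)
    grid = config.grid()
    measured = resample_torque_angle(pf, grid)
    est = MaxStressEstimator(model, group=record.group, config=config)
    est.fit(grid, measured)
    predicted = est.basis_ @ np.array([est.forces_[m] for m in model.muscles])
    return SubjectFit(
        subject_id=record.subject_id,
        group=record.group,
        result=OptimizationResult.from_estimator(est),
        theta_grid=grid,
        measured_torque=measured,
        predicted_torque=predicted,
        params=model.params,
        torque_fit_r2=pf.r_squared,
    )


def fit_cohort(
    records,
    geometry: GeometryConfig | None = None,
    config: OptimizationConfig = DEFAULT_CONFIG,
) -> tuple[list[SubjectFit], dict[str, str]]:
    """Fit every subject, isolating per-subject failures.

    Returns the successful fits and a {subject_id: error message} map for
    the failures; one bad subject does not abort the cohort run.
    """
    geometry = geometry or load_geometry()
    fits, failures = [], {}
    for record in records:
        try:
            fits.append(fit_subject(record, geometry, config))
        except (ElbowExtError, ValueError) as err:
            failures[record.subject_id] = str(err)
    return fits, failures


def analyze_cohort(fits: list[SubjectFit], alpha: float = 0.05) -> dict:
    """Apply the statistical battery to per-subject stress estimates."""
    groups = {"control": [f for f in fits if f.group == "control"],
              "stroke": [f for f in fits if f.group == "stroke"]}
    for name, fs in groups.items():
        if len(fs) < 2:
            raise ElbowExtError(f"need >= 2 fitted subjects in group {name!r}, got {len(fs)}")
    tables = {
        name: {m: np.array([f.result.sigma_m[m] for f in fs]) for m in MUSCLES}
        for name, fs in groups.items()
    }
    test = compare_extensor_stress(tables["control"], tables["stroke"], alpha=alpha)
    summary = {
        name: {
            "n": len(fs),
            "sigma_mean_n_per_cm2": float(np.mean([np.mean(list(f.result.sigma_m.values()))
                                                   for f in fs])),
            "sigma_sd_n_per_cm2": float(np.std([np.mean(list(f.result.sigma_m.values()))
                                                for f in fs], ddof=1)),
            "rms_mean_nm": float(np.mean([f.result.rms for f in fs])),
            "rms_sd_nm": float(np.std([f.result.rms for f in fs], ddof=1)),
        }
        for name, fs in groups.items()
    }
    out = {
        "summary": summary,
        "combined": test.combined,
        "decision_log": list(test.log),
        "within_group_anova": {
            name: {"F": r.F, "df": [r.df_between, r.df_error], "p": r.p_value}
            for name, r in test.within_group_anova.items()
        },
    }
    if test.combined:
        t = test.combined_test
        out["group_test"] = {"test": t.test, "t": t.statistic, "df": t.df, "p": t.p_value,
                             "control_mean": t.mean_a, "stroke_mean": t.mean_b}
    else:
        out["group_test"] = {
            m: {"t": t.statistic, "df": t.df, "p": t.p_value}
            for m, t in test.per_muscle_tests.items()
        }
    return out
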