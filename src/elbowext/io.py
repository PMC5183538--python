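"""Subject file schemas and cohort directory layout.

A cohort directory contains one subdirectory per subject plus a
``manifest.csv`` (columns: subject_id, group, path). Each subject
directory holds:

``subject.json``
    subject_id, group, anthropometry (cm).
``frames.csv``
    one digitized ultrasound frame per row: muscle, joint_angle_deg,
    scale_mm_per_px, fascicle/aponeurosis endpoint pixel coordinates,
    mt1_mm, mt2_mm.
``torque_angle.csv``
    theta_deg, torque_nm: per-angle MVC extension torque.
``ground_truth.json``
    generator sidecar (hidden parameters); never read by the fit pipeline.

CSV dialect: UTF-8, comma separated, header row, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import GroundTruth, SubjectRecord
from .ultrasound import UltrasoundFrame

FRAME_COLUMNS = [
    "muscle", "joint_angle_deg", "scale_mm_per_px",
    "fas_x0", "fas_y0", "fas_x1", "fas_y1",
    "apo_x0", "apo_y0", "apo_x1", "apo_y1",
    "mt1_mm", "mt2_mm",
]


def write_subject(record: SubjectRecord, directory: str | Path,
                  truth: GroundTruth | None = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "subject.json").write_text(json.dumps({
        "subject_id": record.subject_id,
        "group": record.group,
        "upper_arm_length_cm": record.upper_arm_length,
        "forearm_length_cm": record.forearm_length,
        "arm_circumference_cm": record.arm_circumference,
    }, indent=2) + "\n")
    rows = []
    for f in record.frames:
        (fx0, fy0), (fx1, fy1) = f.fascicle
        (ax0, ay0), (ax1, ay1) = f.aponeurosis
        rows.append([f.muscle_id, f.joint_angle, f.scale,
                     fx0, fy0, fx1, fy1, ax0, ay0, ax1, ay1, f.mt1, f.mt2])
    pd.DataFrame(rows, columns=FRAME_COLUMNS).to_csv(d / "frames.csv", index=False)
    pd.DataFrame({"theta_deg": record.torque_theta, "torque_nm": record.torque}).to_csv(
        d / "torque_angle.csv", index=False)
    if truth is not None:
        (d / "ground_truth.json").write_text(json.dumps({
            "group": truth.group,
            "sigma_m_n_per_cm2": truth.sigma_m,
            "F_z_n": truth.F_z,
            "l_mo_cm": truth.l_mo,
            "alpha_o_deg": truth.alpha_o,
            "l_to_cm": truth.l_to,
            "PCSA_cm2": truth.PCSA,
        }, indent=2) + "\n")
    return d


def read_subject(directory: str | Path) -> SubjectRecord:
    d = Path(directory)
    try:
        meta = json.loads((d / "subject.json").read_text())
        frames_df = pd.read_csv(d / "frames.csv")
        torque_df = pd.read_csv(d / "torque_angle.csv")
    except FileNotFoundError as err:
        raise ValidationError(f"incomplete subject directory {d}: {err}") from err
    for col in FRAME_COLUMNS:
        if col not in frames_df.columns:
            raise ValidationError(f"{d / 'frames.csv'}: missing column {col!r}")
    for col in ("theta_deg", "torque_nm"):
        if col not in torque_df.columns:
            raise ValidationError(f"{d / 'torque_angle.csv'}: missing column {col!r}")
    frames = tuple(
        UltrasoundFrame(
            muscle_id=str(r.muscle),
            joint_angle=float(r.joint_angle_deg),
            scale=float(r.scale_mm_per_px),
            fascicle=((r.fas_x0, r.fas_y0), (r.fas_x1, r.fas_y1)),
            aponeurosis=((r.apo_x0, r.apo_y0), (r.apo_x1, r.apo_y1)),
            mt1=float(r.mt1_mm),
            mt2=float(r.mt2_mm),
        )
        for r in frames_df.itertuples()
    )
    try:
        return SubjectRecord(
            subject_id=str(meta["subject_id"]),
            group=str(meta["group"]),
            upper_arm_length=float(meta["upper_arm_length_cm"]),
            forearm_length=float(meta["forearm_length_cm"]),
            arm_circumference=float(meta["arm_circumference_cm"]),
            frames=frames,
            torque_theta=torque_df["theta_deg"].to_numpy(float),
            torque=torque_df["torque_nm"].to_numpy(float),
        )
    except KeyError as err:
        raise ValidationError(f"{d / 'subject.json'}: missing field {err}") from err


def read_ground_truth(directory: str | Path) -> GroundTruth:
    doc = json.loads((Path(directory) / "ground_truth.json").read_text())
    return GroundTruth(
        group=doc["group"],
        sigma_m=doc["sigma_m_n_per_cm2"],
        F_z=doc["F_z_n"],
        l_mo=doc["l_mo_cm"],
        alpha_o=doc["alpha_o_deg"],
        l_to=doc["l_to_cm"],
        PCSA=doc["PCSA_cm2"],
    )


def write_cohort(cohort, directory: str | Path) -> Path:
    """Write a generated cohort to disk and return the directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for record, truth in cohort:
        sub = write_subject(record, d / record.subject_id, truth)
        rows.append([record.subject_id, record.group, sub.name])
    pd.DataFrame(rows, columns=["subject_id", "group", "path"]).to_csv(
        d / "manifest.csv", index=False)
    return d


def read_manifest(directory: str | Path) -> pd.DataFrame:
    d = Path(directory)
    m = d / "manifest.csv"
    if not m.exists():
        raise ValidationError(f"no manifest.csv in {d}")
    return pd.read_csv(m)
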