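"""Configuration loading: geometry YAML schema and literature defaults.

Geometry YAML schema (all lengths cm, angles degrees)::

    name: <str>
    reference:
      upper_arm_length: <float>
      forearm_length: <float>
    muscles:
      <muscle_id>:
        origin:    {xyz: [x, y, z], segment: humerus|ulna}
        insertion: {xyz: [x, y, z], segment: humerus|ulna}
        via_points:
          - {xyz: [x, y, z], segment: ..., active_range: [lo, hi]}  # optional
        wraps:
          - kind: cylinder|sphere
            center: [x, y, z]
            axis: [x, y, z]          # cylinders only, unit vector
            radius: <float>
            active_range: [lo, hi]   # optional, default full range

Ulna-fixed coordinates are given at the fully extended pose (0 degrees of
flexion).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError
from .geometry import GeometryConfig, MusclePath, PathPoint, WrapObject


def _point(d: dict, where: str) -> PathPoint:
    try:
        kwargs = {"xyz": d["xyz"], "segment": d.get("segment", "humerus")}
        if "active_range" in d:
            kwargs["active_range"] = tuple(d["active_range"])
        return PathPoint(**kwargs)
    except (KeyError, TypeError) as err:
        raise ValidationError(f"bad path point in {where}: {err}") from err


def _wrap(d: dict, where: str) -> WrapObject:
    try:
        kwargs = {"kind": d["kind"], "center": d["center"], "radius": d["radius"]}
        if "axis" in d:
            kwargs["axis"] = d["axis"]
        if "active_range" in d:
            kwargs["active_range"] = tuple(d["active_range"])
        if "side" in d:
            kwargs["side"] = d["side"]
        return WrapObject(**kwargs)
    except (KeyError, TypeError) as err:
        raise ValidationError(f"bad wrap object in {where}: {err}") from err


def geometry_from_dict(doc: dict) -> GeometryConfig:
    for key in ("reference", "muscles"):
        if key not in doc:
            raise ValidationError(f"geometry config missing required field {key!r}")
    ref = doc["reference"]
    paths = {}
    for mid, m in doc["muscles"].items():
        for key in ("origin", "insertion"):
            if key not in m:
                raise ValidationError(f"muscle {mid!r} missing required field {key!r}")
        paths[mid] = MusclePath(
            muscle_id=mid,
            origin=_point(m["origin"], mid),
            insertion=_point(m["insertion"], mid),
            via_points=tuple(_point(p, mid) for p in m.get("via_points", [])),
            wraps=tuple(_wrap(w, mid) for w in m.get("wraps", [])),
        )
    try:
        return GeometryConfig(
            paths=paths,
            reference_upper_arm=float(ref["upper_arm_length"]),
            reference_forearm=float(ref["forearm_length"]),
            name=str(doc.get("name", "unnamed")),
        )
    except KeyError as err:
        raise ValidationError(f"geometry reference lengths incomplete: {err}") from err


def load_geometry(path: str | Path | None = None) -> GeometryConfig:
    """Load a geometry config; ``None`` loads the packaged default."""
    if path is None:
        text = resources.files("elbowext.data").joinpath("default_geometry.yaml").read_text()
    else:
        text = Path(path).read_text()
    return geometry_from_dict(yaml.safe_load(text))


def load_literature(path: str | Path | None = None) -> dict:
    """Literature PCSA values (cm2) and the cadaver arm circumference (cm)."""
    if path is None:
        text = resources.files("elbowext.data").joinpath("literature.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if "pcsa" not in doc or "cadaver_arm_circumference" not in doc:
        raise ValidationError("literature config needs 'pcsa' and 'cadaver_arm_circumference'")
    return doc
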