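"""Structured run configuration (YAML).

Keys (all optional, defaults mirror the package's standard constants):

geometry:   ArchParameters fields (teeth_per_quadrant, arch_half_width,
            interference: [fdi, extra_height_mm], ...)
material:   {E_gpa, nu, mu, h_mm}
contact:    {cutoff_mm, k_override}
tasks:      {segments: {task_name: n}}
seeds:      {model, recording}
angle_unit: rad | deg
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dentition import MaterialParams
from .errors import SchemaError
from .kinematics import TASK_SEGMENTS
from .synthetic import ArchParameters


def load_config(path=None) -> dict:
    """Parse a config file into parameter objects with defaults."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")

    geo = dict(raw.get("geometry", {}))
    if "interference" in geo and geo["interference"] is not None:
        fdi, extra = geo["interference"]
        geo["interference"] = (int(fdi), float(extra))
    for key in ("tooth_widths", "clearances"):
        if key in geo:
            geo[key] = tuple(geo[key])
    try:
        arch = ArchParameters(**geo)
    except TypeError as exc:
        raise SchemaError(f"invalid geometry key: {exc}") from None

    mat_raw = raw.get("material", {})
    material = MaterialParams(
        elastic_modulus=mat_raw.get("E_gpa", 84.0),
        poisson_ratio=mat_raw.get("nu", 0.3),
        friction_coefficient=mat_raw.get("mu", 0.1),
        foundation_thickness=mat_raw.get("h_mm", 2.0),
    )

    contact = raw.get("contact", {})
    segments = dict(TASK_SEGMENTS)
    segments.update(raw.get("tasks", {}).get("segments", {}))
    seeds = {"model": 0, "recording": 0}
    seeds.update(raw.get("seeds", {}))
    return {
        "geometry": arch,
        "material": material,
        "cutoff_mm": float(contact.get("cutoff_mm", 5.0)),
        "k_override": contact.get("k_override"),
        "segments": segments,
        "seeds": seeds,
        "angle_unit": raw.get("angle_unit", "rad"),
    }
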