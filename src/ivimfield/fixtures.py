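"""Packaged literature relaxation-time fixtures and their YAML schema.

The shipped document ``data/relaxation_times.yaml`` holds one
:class:`~ivimfield.relaxation.RelaxationSet` per named condition (calf at
0.55 T and 7 T, liver at 1.5 T and 3 T) plus the blood R2 points used for
the quadratic field interpolation.  User files following the same schema
can be loaded with :func:`load_relaxation_file`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .errors import UsageError
from .interp import R2Point
from .relaxation import RelaxationSet

__all__ = [
    "available_relaxation_sets",
    "load_relaxation_set",
    "load_r2_points",
    "load_relaxation_file",
]

_RELAX_KEYS = {
    "field_strength",
    "t1_venous", "t1_arterial", "t1_muscle",
    "t2_venous", "t2_arterial", "t2_muscle",
    "oxygen_saturation_venous", "oxygen_saturation_arterial", "hematocrit",
    "citations",
}


def _packaged_document() -> dict[str, Any]:
    text = (resources.files("ivimfield") / "data" / "relaxation_times.yaml").read_text()
    return yaml.safe_load(text)


def _build_set(name: str, entry: dict[str, Any]) -> RelaxationSet:
    unknown = set(entry) - _RELAX_KEYS
    if unknown:
        raise UsageError(f"unknown keys in relaxation set {name!r}: {sorted(unknown)}")
    entry = dict(entry)
    entry["citations"] = tuple(entry.get("citations", ()))
    return RelaxationSet(name=name, **entry)


def available_relaxation_sets() -> tuple[str, ...]:
    """Names of the shipped relaxation-time fixtures."""
    return tuple(_packaged_document()["relaxation_sets"])


def load_relaxation_set(name: str) -> RelaxationSet:
    """Load a shipped relaxation set by name (e.g. ``"calf_0.55T"``)."""
    sets = _packaged_document()["relaxation_sets"]
    if name not in sets:
        raise UsageError(
            f"unknown relaxation set {name!r}; available: {sorted(sets)}"
        )
    return _build_set(name, sets[name])


def load_r2_points(compartment: str) -> list[R2Point]:
    """Shipped blood R2 points for ``"venous_blood"`` or ``"arterial_blood"``."""
    points = _packaged_document()["r2_points"]
    if compartment not in points:
        raise UsageError(
            f"unknown compartment {compartment!r}; available: {sorted(points)}"
        )
    return [
        R2Point(
            field_strength=float(p["field_strength"]),
            t2=float(p["t2"]),
            source=str(p.get("source", "")),
        )
        for p in points[compartment]
    ]


def load_relaxation_file(path: str | Path) -> dict[str, RelaxationSet]:
    """Load user relaxation sets from a YAML file following the packaged schema."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "relaxation_sets" not in doc:
        raise UsageError(f"{path}: expected a mapping with a 'relaxation_sets' key")
    return {
        name: _build_set(name, entry) for name, entry in doc["relaxation_sets"].items()
    }
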