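"""Pharmacophore model container, exclusion volumes, edits and serialization.

A model is a named set of typed features plus exclusion volumes (forbidden
spheres representing protein bulk) and a ``min_required`` match count.
Derivation (structure- and ligand-based) lives in :mod:`cbscreen.modelgen`;
matching lives in :mod:`cbscreen.screening`.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import EditError
from .features import Feature
from .geometry import apply_transform

EDIT_VERBS = ("add_feature", "remove_feature", "set_radius", "add_xvol", "remove_xvol")


@dataclass
class ExclusionVolume:
    """Forbidden sphere: a ligand heavy atom inside it disqualifies a match."""

    center: np.ndarray
    radius: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("exclusion volume radius must be positive")
        self.center = np.asarray(self.center, dtype=float)

    def transformed(self, R, t) -> "ExclusionVolume":
        return replace(self, center=apply_transform(R, t, self.center[None, :])[0])

    def to_dict(self) -> dict:
        return {"center": [float(x) for x in self.center], "radius": float(self.radius)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExclusionVolume":
        return cls(center=np.array(d["center"], dtype=float), radius=float(d.get("radius", 1.0)))


@dataclass
class PharmacophoreModel:
    """A named pharmacophore: features, exclusion volumes, match requirement.

    ``min_required`` is the number of features a hit must map; ``None``
    means all of them (full-match screening, the default).
    """

    name: str
    features: list[Feature]
    xvols: list[ExclusionVolume] = field(default_factory=list)
    min_required: int | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.min_required is not None and self.min_required > len(self.features):
            raise ValueError("min_required exceeds feature count")

    @property
    def required(self) -> int:
        return len(self.features) if self.min_required is None else self.min_required

    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]

    def anchors(self) -> np.ndarray:
        return np.array([f.anchor for f in self.features]).reshape(-1, 3)

    def transformed(self, R, t) -> "PharmacophoreModel":
        return PharmacophoreModel(
            name=self.name,
            features=[f.transformed(R, t) for f in self.features],
            xvols=[x.transformed(R, t) for x in self.xvols],
            min_required=self.min_required,
            provenance=list(self.provenance),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "min_required": self.min_required,
            "features": [f.to_dict() for f in self.features],
            "xvols": [x.to_dict() for x in self.xvols],
            "provenance": list(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        return cls(
            name=d["name"],
            features=[Feature.from_dict(f) for f in d["features"]],
            xvols=[ExclusionVolume.from_dict(x) for x in d.get("xvols", [])],
            min_required=d.get("min_required"),
            provenance=list(d.get("provenance", [])),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "PharmacophoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ModelEdit:
    """One refinement step: verb plus a verb-specific payload.

    Payloads: ``add_feature`` → {"feature": Feature or dict};
    ``remove_feature``/``remove_xvol`` → {"index": int};
    ``set_radius`` → {"index": int, "radius": float};
    ``add_xvol`` → {"xvol": ExclusionVolume or dict}.
    """

    verb: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.verb not in EDIT_VERBS:
            raise EditError(f"unknown edit verb {self.verb!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEdit":
        return cls(verb=d["verb"], payload={k: v for k, v in d.items() if k != "verb"})


def load_edits(path) -> list[ModelEdit]:
    """Read a list of edits from a YAML file (list of {verb, ...} maps)."""
    data = yaml.safe_load(Path(path).read_text()) or []
    return [ModelEdit.from_dict(d) for d in data]


def apply_edits(model: PharmacophoreModel, edits: list[ModelEdit]) -> PharmacophoreModel:
    """Apply edits in order, returning a new model; the input is unchanged.

    Each applied edit is appended to the provenance log. A dangling feature
    or exclusion-volume reference raises :class:`EditError` naming the edit.
    """
    out = copy.deepcopy(model)
    for n, edit in enumerate(edits):
        try:
            _apply_one(out, edit)
        except IndexError:
            raise EditError(f"edit #{n} ({edit.verb}) references a missing index: {edit.payload}")
        out.provenance.append(f"{edit.verb}:{_payload_repr(edit.payload)}")
    if out.min_required is not None:
        out.min_required = min(out.min_required, len(out.features))
    return out


def _payload_repr(payload: dict) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(payload.items(), key=lambda kv: kv[0]))


def _apply_one(model: PharmacophoreModel, edit: ModelEdit) -> None:
    p = edit.payload
    if edit.verb == "add_feature":
        f = p["feature"]
        model.features.append(f if isinstance(f, Feature) else Feature.from_dict(f))
    elif edit.verb == "remove_feature":
        i = int(p["index"])
        if not 0 <= i < len(model.features):
            raise IndexError
        del model.features[i]
    elif edit.verb == "set_radius":
        i = int(p["index"])
        if not 0 <= i < len(model.features):
            raise IndexError
        model.features[i] = replace(model.features[i], radius=float(p["radius"]))
    elif edit.verb == "add_xvol":
        x = p["xvol"]
        model.xvols.append(x if isinstance(x, ExclusionVolume) else ExclusionVolume.from_dict(x))
    elif edit.verb == "remove_xvol":
        i = int(p["index"])
        if not 0 <= i < len(model.xvols):
            raise IndexError
        del model.xvols[i]


def model_equal(a: PharmacophoreModel, b: PharmacophoreModel, tol: float = 1e-9) -> bool:
    """Value equality of two models (provenance ignored)."""
    if len(a.features) != len(b.features) or len(a.xvols) != len(b.xvols):
        return False
    if a.required != b.required:
        return False
    for fa, fb in zip(a.features, b.features):
        if fa.kind != fb.kind or abs(fa.radius - fb.radius) > tol:
            return False
        if np.max(np.abs(fa.anchor - fb.anchor)) > tol:
            return False
        if (fa.direction is None) != (fb.direction is None):
            return False
        if fa.direction is not None and np.max(np.abs(fa.direction - fb.direction)) > tol:
            return False
    for xa, xb in zip(a.xvols, b.xvols):
        if abs(xa.radius - xb.radius) > tol or np.max(np.abs(xa.center - xb.center)) > tol:
            return False
    return True
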