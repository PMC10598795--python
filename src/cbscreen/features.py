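"""Pharmacophore feature perception.

Assigns typed features with 3D anchors to a conformer:

* ``HBD`` — N/O bearing at least one hydrogen, anchored on the donor heavy
  atom, direction along the mean D–H vector;
* ``HBA`` — N/O with an available lone pair (pyrrole-type and amide
  nitrogens excluded), anchored on the acceptor, direction opposite the
  mean bond vector (the lone-pair side);
* ``AI`` — aromatic ring, anchored at the centroid with the ring normal;
* ``HC`` — centroid of each maximal contiguous group of at least two
  low-polarity heavy atoms (C, S, Cl, Br, I with no charged or polar
  neighbor).

Typing is purely topological, so feature kinds and counts are identical
across conformers of the same molecule; only the anchors move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .chemio import ConformerEnsemble
from .errors import ConfigError
from .geometry import apply_transform

FEATURE_KINDS = ("HBD", "HBA", "HC", "AI")

#: default tolerance sphere radius per feature kind (Å)
DEFAULT_RADII = {"HBD": 1.5, "HBA": 1.5, "HC": 1.5, "AI": 1.5}
#: default angular tolerance for directional features (degrees)
DEFAULT_CONE_DEG = 30.0

DONOR_SMARTS = "[#7,#8;!H0]"
# O always accepts; N accepts unless pyrrole-type aromatic (nX3) or amide N.
ACCEPTOR_SMARTS = "[$([#8]),$([#7;!$([nX3]);!$([NX3][CX3]=[OX1])])]"


@dataclass
class Feature:
    """One typed pharmacophore feature with a 3D anchor and tolerance."""

    kind: str
    anchor: np.ndarray
    radius: float = 1.5
    direction: np.ndarray | None = None
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ConfigError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("feature direction must be nonzero")
            self.direction = d / n
        self.source_atoms = tuple(self.source_atoms)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Feature":
        direction = None if self.direction is None else np.asarray(R, float) @ self.direction
        return replace(self, anchor=apply_transform(R, t, self.anchor[None, :])[0], direction=direction)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "anchor": [float(x) for x in self.anchor],
            "radius": float(self.radius),
            "direction": None if self.direction is None else [float(x) for x in self.direction],
            "source_atoms": list(self.source_atoms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Feature":
        return cls(
            kind=d["kind"],
            anchor=np.array(d["anchor"], dtype=float),
            radius=float(d.get("radius", 1.5)),
            direction=None if d.get("direction") is None else np.array(d["direction"], dtype=float),
            source_atoms=tuple(d.get("source_atoms", ())),
        )


@dataclass
class FeatureSet:
    """The features of one conformer (or of an abstract feature cloud).

    ``coords`` holds the heavy-atom coordinates used for exclusion-volume
    clash tests; for abstract clouds the anchors themselves stand in.
    """

    record_id: str
    conformer_index: int
    features: list[Feature]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]

    def anchors(self) -> np.ndarray:
        return np.array([f.anchor for f in self.features]).reshape(-1, 3)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            record_id=self.record_id,
            conformer_index=self.conformer_index,
            features=[f.transformed(R, t) for f in self.features],
            coords=apply_transform(R, t, self.coords) if len(self.coords) else self.coords,
        )

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "conformer_index": self.conformer_index,
            "features": [f.to_dict() for f in self.features],
            "coords": [[float(x) for x in row] for row in self.coords],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            record_id=d["record_id"],
            conformer_index=int(d.get("conformer_index", 0)),
            features=[Feature.from_dict(f) for f in d["features"]],
            coords=np.array(d["coords"], dtype=float).reshape(-1, 3),
        )

    def to_csv(self, path) -> pd.DataFrame:
        rows = [
            {"kind": f.kind, "x": f.anchor[0], "y": f.anchor[1], "z": f.anchor[2], "radius": f.radius}
            for f in self.features
        ]
        df = pd.DataFrame(rows, columns=["kind", "x", "y", "z", "radius"])
        df.to_csv(path, index=False)
        return df

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "FeatureSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PerceptionRules:
    """Configurable feature-typing rule table.

    The SMARTS defaults approximate conventional pharmacophore typing; the
    modeling programs in routine use never publish theirs, so every rule is
    explicit and overridable from a YAML file.
    """

    donor_smarts: str = DONOR_SMARTS
    acceptor_smarts: str = ACCEPTOR_SMARTS
    hydrophobe_elements: tuple[str, ...] = ("C", "S", "Cl", "Br", "I")
    min_hydrophobe_group: int = 2
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    cone_deg: float = DEFAULT_CONE_DEG
    #: treat fluorine as an acceptor surrogate (off by default)
    halogen_acceptors: bool = False

    def __post_init__(self):
        for kind in self.radii:
            if kind not in FEATURE_KINDS:
                raise ConfigError(f"unknown feature kind {kind!r} in rule table")
        for patt_name, patt in (("donor_smarts", self.donor_smarts), ("acceptor_smarts", self.acceptor_smarts)):
            if Chem.MolFromSmarts(patt) is None:
                raise ConfigError(f"unparsable SMARTS in {patt_name}: {patt!r}")

    @classmethod
    def from_yaml(cls, path) -> "PerceptionRules":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown rule-table keys: {sorted(unknown)}")
        if "hydrophobe_elements" in data:
            data["hydrophobe_elements"] = tuple(data["hydrophobe_elements"])
        return cls(**data)


DEFAULT_RULES = PerceptionRules()


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    return None if n < 1e-8 else v / n


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def perceive_features(
    ens: ConformerEnsemble, conformer_index: int = 0, rules: PerceptionRules = DEFAULT_RULES
) -> FeatureSet:
    """Perceive the typed feature set of one conformer of an ensemble."""
    mol = ens.molecule.mol
    conf = mol.GetConformer(ens.conf_ids[conformer_index])
    pos = np.array(conf.GetPositions(), dtype=float)
    features: list[Feature] = []

    donor_idx = {m[0] for m in mol.GetSubstructMatches(Chem.MolFromSmarts(rules.donor_smarts))}
    for i in sorted(donor_idx):
        atom = mol.GetAtomWithIdx(i)
        h_vecs = [pos[nb.GetIdx()] - pos[i] for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
        direction = _unit(np.mean(h_vecs, axis=0)) if h_vecs else None
        features.append(
            Feature("HBD", pos[i], radius=rules.radii["HBD"], direction=direction, source_atoms=(i,))
        )

    acceptor_idx = {m[0] for m in mol.GetSubstructMatches(Chem.MolFromSmarts(rules.acceptor_smarts))}
    if rules.halogen_acceptors:
        acceptor_idx |= {a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "F"}
    for i in sorted(acceptor_idx):
        atom = mol.GetAtomWithIdx(i)
        nb_vecs = [pos[nb.GetIdx()] - pos[i] for nb in atom.GetNeighbors()]
        direction = _unit(-np.mean(nb_vecs, axis=0)) if nb_vecs else None
        features.append(
            Feature("HBA", pos[i], radius=rules.radii["HBA"], direction=direction, source_atoms=(i,))
        )

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            ring_pos = pos[list(ring)]
            features.append(
                Feature(
                    "AI",
                    ring_pos.mean(axis=0),
                    radius=rules.radii["AI"],
                    direction=_ring_normal(ring_pos),
                    source_atoms=tuple(ring),
                )
            )

    features.extend(_hydrophobic_features(mol, pos, rules))

    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    return FeatureSet(
        record_id=ens.record_id, conformer_index=conformer_index, features=features, coords=pos[heavy]
    )


def _hydrophobic_features(mol: Chem.Mol, pos: np.ndarray, rules: PerceptionRules) -> list[Feature]:
    polar = {7, 8}

    def qualifies(atom) -> bool:
        if atom.GetSymbol() not in rules.hydrophobe_elements or atom.GetFormalCharge() != 0:
            return False
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() in polar or nb.GetFormalCharge() != 0:
                return False
        return True

    member = {a.GetIdx() for a in mol.GetAtoms() if qualifies(a)}
    # connected components of the qualifying-atom subgraph
    seen: set[int] = set()
    out = []
    for start in sorted(member):
        if start in seen:
            continue
        group = []
        stack = [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            group.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in member and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(group) >= rules.min_hydrophobe_group:
            group = tuple(sorted(group))
            out.append(
                Feature("HC", pos[list(group)].mean(axis=0), radius=rules.radii["HC"], source_atoms=group)
            )
    return out
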