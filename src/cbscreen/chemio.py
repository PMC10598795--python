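"""Chemical structure IO, conformer embedding and physicochemical properties.

RDKit does the heavy lifting (parsing, ETKDG embedding, descriptor
calculation); this module wraps it in the library-record semantics the rest
of the pipeline expects: stable record ids, canonical structure keys for
deduplication, and the seven-property vector used for decoy matching
(molecular weight, #N, #O, rotatable bonds, HBD, HBA, logP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

from .errors import EmbeddingError, LibraryError

log = logging.getLogger(__name__)

#: heavy-atom RMSD below which two conformers are considered duplicates
PRUNE_RMSD = 0.5

PROPERTY_FIELDS = ("mw", "n_n", "n_o", "n_rot", "n_hbd", "n_hba", "logp")


@dataclass
class PropertyVector:
    """The seven physicochemical descriptors used for decoy matching.

    mw in g/mol; counts are integers on the hydrogen-resolved heavy-atom
    graph; logp is a Crippen atomic-contribution estimate (unitless).
    """

    mw: float
    n_n: int
    n_o: int
    n_rot: int
    n_hbd: int
    n_hba: int
    logp: float

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PROPERTY_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROPERTY_FIELDS], dtype=float)


@dataclass
class Molecule:
    """A library record: an RDKit mol plus its id and provenance tag."""

    mol: Chem.Mol
    record_id: str
    source: str | None = None

    @classmethod
    def from_smiles(cls, smiles: str, record_id: str = "", source: str | None = None) -> "Molecule":
        m = Chem.MolFromSmiles(smiles)
        if m is None:
            raise LibraryError(f"unparsable SMILES for record {record_id!r}: {smiles!r}")
        return cls(mol=m, record_id=record_id or smiles, source=source)

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def canonical_key(self, strip_salts: bool = True) -> str:
        """Canonical isomeric SMILES of the (salt-stripped) parent structure.

        Used everywhere structural identity matters: library round-trips,
        actives exclusion, duplicate collapse. Salt stripping keeps the
        fragment with the most heavy atoms (ties broken by SMILES order).
        """
        m = self.mol
        if strip_salts:
            frags = Chem.GetMolFrags(m, asMols=True, sanitizeFrags=False)
            if len(frags) > 1:
                m = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
        return Chem.MolToSmiles(m)


@dataclass
class ConformerEnsemble:
    """A molecule with up to ``max_n`` embedded 3D conformers.

    ``molecule.mol`` carries explicit hydrogens and the conformers;
    ``conf_ids`` are the surviving RDKit conformer ids after duplicate
    pruning. Energies are optional and in arbitrary units.
    """

    molecule: Molecule
    conf_ids: list[int] = field(default_factory=list)
    energies: list[float] | None = None

    @property
    def record_id(self) -> str:
        return self.molecule.record_id

    @property
    def n_conformers(self) -> int:
        return len(self.conf_ids)

    def coords(self, index: int, heavy_only: bool = True) -> np.ndarray:
        """Coordinates (Å) of conformer ``index`` (position in conf_ids)."""
        conf = self.molecule.mol.GetConformer(self.conf_ids[index])
        pos = np.array(conf.GetPositions(), dtype=float)
        if heavy_only:
            keep = [a.GetIdx() for a in self.molecule.mol.GetAtoms() if a.GetAtomicNum() > 1]
            pos = pos[keep]
        return pos


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        suffix = path.suffix.lower()
        f = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf"}.get(suffix, "")
    if f not in ("smiles", "sdf"):
        raise LibraryError(f"unsupported library format {fmt or path.suffix!r} for {path}")
    return f


def read_library(path: str | Path, fmt: str | None = None, source: str | None = None) -> list[Molecule]:
    """Read a SMILES (one record per line, optional name) or SDF library.

    Unparsable records are skipped with a logged warning; an entirely
    unparsable non-empty file is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    f = _infer_format(path, fmt)
    mols: list[Molecule] = []
    skipped = 0
    n_records = 0
    if f == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_records += 1
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else str(i)
            m = Chem.MolFromSmiles(smiles)
            if m is None:
                skipped += 1
                log.warning("skipping unparsable SMILES record %r (line %d)", name, i + 1)
                continue
            mols.append(Molecule(mol=m, record_id=name, source=source))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, m in enumerate(supplier):
            n_records += 1
            if m is None:
                skipped += 1
                log.warning("skipping unparsable SDF record at index %d", i)
                continue
            name = m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else str(i)
            mols.append(Molecule(mol=m, record_id=name, source=source))
    if n_records == 0:
        log.warning("library %s is empty", path)
        return []
    if not mols:
        raise LibraryError(f"no parsable records in {path} ({skipped} skipped)")
    if skipped:
        log.warning("read %d records from %s, skipped %d unparsable", len(mols), path, skipped)
    return mols


def write_library(mols: list[Molecule], path: str | Path, fmt: str | None = None) -> None:
    """Write records as SMILES lines or an SDF V2000 file."""
    path = Path(path)
    f = _infer_format(path, fmt)
    if f == "smiles":
        lines = [f"{Chem.MolToSmiles(m.mol)} {m.record_id}" for m in mols]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        writer = Chem.SDWriter(str(path))
        for m in mols:
            mm = Chem.Mol(m.mol)
            mm.SetProp("_Name", m.record_id)
            writer.write(mm)
        writer.close()


def write_manifest(mols: list[Molecule], path: str | Path) -> pd.DataFrame:
    """Library manifest CSV: record_id, source, canonical key, 7 properties."""
    rows = []
    for m in mols:
        row = {"record_id": m.record_id, "source": m.source or "", "canonical_key": m.canonical_key()}
        row.update(compute_properties(m).as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def _heavy_rmsd(mol: Chem.Mol, cid_a: int, cid_b: int) -> float:
    """Symmetry-aware heavy-atom best RMSD between two conformers."""
    return AllChem.GetBestRMS(Chem.RemoveHs(mol), Chem.RemoveHs(mol), prbId=cid_a, refId=cid_b)


def embed_conformers(molecule: Molecule, max_n: int = 25, seed: int = 7) -> ConformerEnsemble:
    """Embed up to ``max_n`` ETKDG conformers, pruning duplicates.

    Deterministic for a fixed ``(molecule, max_n, seed)``. Duplicates are
    pruned at 0.5 Å heavy-atom RMSD, so rigid molecules collapse to a
    single distinct geometry.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if molecule.mol.GetNumAtoms() == 0:
        raise EmbeddingError(f"record {molecule.record_id!r} is empty")
    molh = Chem.AddHs(Chem.Mol(molecule.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = PRUNE_RMSD
    ids = list(AllChem.EmbedMultipleConfs(molh, numConfs=int(max_n), params=params))
    if not ids:
        raise EmbeddingError(f"conformer embedding failed for record {molecule.record_id!r}")
    # ETKDG's prune threshold is not symmetry-aware; re-prune explicitly.
    kept: list[int] = []
    for cid in ids:
        if all(_heavy_rmsd(molh, cid, k) >= PRUNE_RMSD for k in kept):
            kept.append(cid)
    kept = kept[: int(max_n)]
    mol_out = Molecule(mol=molh, record_id=molecule.record_id, source=molecule.source)
    return ConformerEnsemble(molecule=mol_out, conf_ids=kept)


def compute_properties(molecule: Molecule) -> PropertyVector:
    """Compute the seven-descriptor property vector for a record.

    Counts follow standard medicinal-chemistry conventions: rotatable bonds
    exclude amide C–N (RDKit default), donors are N/O bearing at least one
    hydrogen, acceptors are N/O with an available lone pair. logP is the
    Crippen atomic-contribution estimate.
    """
    m = molecule.mol
    if m.GetNumAtoms() == 0:
        raise ValueError(f"cannot compute properties of empty molecule {molecule.record_id!r}")
    return PropertyVector(
        mw=float(Descriptors.MolWt(m)),
        n_n=sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 7),
        n_o=sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 8),
        n_rot=int(Lipinski.NumRotatableBonds(m)),
        n_hbd=int(Lipinski.NumHDonors(m)),
        n_hba=int(Lipinski.NumHAcceptors(m)),
        logp=float(Crippen.MolLogP(m)),
    )
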