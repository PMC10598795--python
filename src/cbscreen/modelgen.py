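"""Pharmacophore model derivation and refinement.

Structure-based models are read off a protein–ligand complex: ligand
features are kept only where the protein environment supports the
interaction (polar contact within distance/angle criteria, hydrophobic
enclosure), and exclusion volumes are placed on protein heavy atoms
around the ligand. Ligand-based models align a set of known actives by
the screening engine's correspondence matcher and keep either the
features common to every active (*shared* mode) or the deduplicated
union (*merged* mode). ``optimize_model`` is a greedy, enrichment-guided
hill climb over candidate edits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import ConformerEnsemble, Molecule
from .enrichment import ConfusionMatrix, DatasetTotals, MetricsReport, compute_metrics
from .errors import CbscreenError, EmptyModelError, LibraryError
from .features import DEFAULT_RULES, Feature, FeatureSet, PerceptionRules, perceive_features
from .model import ExclusionVolume, ModelEdit, PharmacophoreModel, apply_edits
from .geometry import angle_between
from .screening import DEFAULT_SETTINGS, MatchSettings, match_model, screen_library

log = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}
PROTEIN_POLAR = {"N", "O"}
PROTEIN_APOLAR = {"C", "S"}


@dataclass
class ProteinLigandComplex:
    """A protein–ligand crystal complex in one coordinate frame.

    Protein atoms are parallel arrays (element symbol, xyz, residue name,
    residue number, chain id); the ligand is a single-conformer ensemble;
    waters are oxygen coordinates.
    """

    elements: list[str]
    coords: np.ndarray
    res_names: list[str]
    res_seq: list[int]
    chains: list[str]
    ligand: ConformerEnsemble
    waters: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.waters = np.asarray(self.waters, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if not (len(self.elements) == len(self.res_names) == len(self.res_seq) == len(self.chains) == n):
            raise ValueError("protein atom arrays must have equal length")

    def transformed(self, R, t) -> "ProteinLigandComplex":
        lig = self.ligand
        molh = Chem.Mol(lig.molecule.mol)
        for cid in lig.conf_ids:
            conf = molh.GetConformer(cid)
            pos = np.array(conf.GetPositions()) @ np.asarray(R).T + np.asarray(t)
            for i, p in enumerate(pos):
                conf.SetAtomPosition(i, tuple(float(x) for x in p))
        lig2 = ConformerEnsemble(
            molecule=Molecule(molh, lig.molecule.record_id, lig.molecule.source), conf_ids=list(lig.conf_ids)
        )
        return ProteinLigandComplex(
            elements=list(self.elements),
            coords=self.coords @ np.asarray(R).T + np.asarray(t),
            res_names=list(self.res_names),
            res_seq=list(self.res_seq),
            chains=list(self.chains),
            ligand=lig2,
            waters=self.waters @ np.asarray(R).T + np.asarray(t) if len(self.waters) else self.waters,
        )


def read_complex(path: str | Path, ligand_resname: str | None = None) -> ProteinLigandComplex:
    """Read a PDB complex: ATOM/HETATM records, altloc 'A' preferred, first model.

    The ligand is the HETATM residue named ``ligand_resname`` (or the
    largest non-water het residue); its bonds are perceived from the
    residue's PDB block.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"complex file not found: {path}")
    prot = {"elements": [], "coords": [], "res_names": [], "res_seq": [], "chains": []}
    waters = []
    het_lines: dict[tuple, list[str]] = {}
    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec == "ENDMDL":
            break  # first model only
        if rec not in ("ATOM  ", "HETATM"):
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        resname = line[17:20].strip()
        element = (line[76:78].strip() or line[12:16].strip()[:1]).capitalize()
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        if rec == "ATOM  ":
            if element == "H":
                continue
            prot["elements"].append(element)
            prot["coords"].append(xyz)
            prot["res_names"].append(resname)
            prot["res_seq"].append(int(line[22:26]))
            prot["chains"].append(line[21].strip() or "A")
        else:
            if resname in WATER_RESNAMES:
                if element == "O":
                    waters.append(xyz)
                continue
            key = (line[21], resname, int(line[22:26]))
            het_lines.setdefault(key, []).append(line)
    if ligand_resname is not None:
        candidates = {k: v for k, v in het_lines.items() if k[1] == ligand_resname}
        if not candidates:
            raise LibraryError(f"ligand residue {ligand_resname!r} not found in {path}")
    else:
        candidates = het_lines
    if not candidates:
        raise LibraryError(f"no ligand HETATM residue found in {path}")
    key = max(candidates, key=lambda k: (len(candidates[k]), k))
    block = "\n".join(candidates[key]) + "\nEND\n"
    mol = Chem.MolFromPDBBlock(block, sanitize=True, removeHs=False, proximityBonding=True)
    if mol is None:
        raise LibraryError(f"could not perceive ligand residue {key} in {path}")
    ligand = ConformerEnsemble(molecule=Molecule(mol, record_id=key[1], source=str(path)), conf_ids=[0])
    return ProteinLigandComplex(
        elements=prot["elements"],
        coords=np.array(prot["coords"], dtype=float).reshape(-1, 3),
        res_names=prot["res_names"],
        res_seq=prot["res_seq"],
        chains=prot["chains"],
        ligand=ligand,
        waters=np.array(waters, dtype=float).reshape(-1, 3),
    )


@dataclass(frozen=True)
class SBCriteria:
    """Geometric thresholds for structure-based derivation (Å / degrees).

    Standard crystallographic-interaction cutoffs: donor–acceptor heavy
    atom distance <= 3.5 Å with a D–H···A angle >= 130° (the angle test
    is skipped when the ligand carries no explicit hydrogens), 4.5 Å
    hydrophobic contact shell, exclusion volumes on protein heavy atoms
    within 6.0 Å of the ligand.
    """

    polar_dist: float = 3.5
    min_angle: float = 130.0
    hydrophobic_shell: float = 4.5
    min_apolar_contacts: int = 3
    xvol_shell: float = 6.0
    xvol_radius: float = 1.0
    contact_shell: float = 8.0


def _donor_angle_ok(mol, conf_pos, donor_idx, acceptor_xyz, criteria) -> bool:
    """D-H...A angle at the hydrogen; True when no explicit H is present."""
    atom = mol.GetAtomWithIdx(donor_idx)
    hs = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
    if not hs:
        return True
    for h in hs:
        hp = conf_pos[h]
        try:
            ang = angle_between(conf_pos[donor_idx] - hp, np.asarray(acceptor_xyz) - hp)
        except ValueError:
            continue
        if ang >= criteria.min_angle:
            return True
    return False


def derive_sb_model(
    cx: ProteinLigandComplex,
    criteria: SBCriteria = SBCriteria(),
    include_waters: bool = False,
    rules: PerceptionRules = DEFAULT_RULES,
    name: str = "SB",
) -> PharmacophoreModel:
    """Derive a structure-based pharmacophore from a complex.

    Each ligand feature is retained only if the protein (or, with
    ``include_waters``, a water bridging ligand and protein) supports the
    interaction; exclusion volumes are placed on every protein heavy atom
    within the configured shell of the ligand.
    """
    lig_fs = perceive_features(cx.ligand, 0, rules)
    lig_coords = cx.ligand.coords(0)
    if len(cx.coords) == 0 or len(lig_coords) == 0:
        raise EmptyModelError("complex has no protein or no ligand atoms")
    dmin = np.min(np.linalg.norm(cx.coords[:, None, :] - lig_coords[None, :, :], axis=-1))
    if dmin > criteria.contact_shell:
        raise EmptyModelError(f"no protein atom within {criteria.contact_shell} Å of the ligand")

    mol = cx.ligand.molecule.mol
    conf_pos = np.array(mol.GetConformer(cx.ligand.conf_ids[0]).GetPositions(), dtype=float)
    polar_mask = np.array([e in PROTEIN_POLAR for e in cx.elements])
    apolar_mask = np.array([e in PROTEIN_APOLAR for e in cx.elements])

    features: list[Feature] = []
    # a ligand donor can bond to any protein N/O; a ligand acceptor needs a
    # protein donor, and with element-only protein atoms that means nitrogen
    # (backbone and side-chain N nearly always carry hydrogen, whereas a
    # carbonyl O does not)
    donor_partner_mask = np.array([e == "N" for e in cx.elements])
    for f in lig_fs.features:
        if f.kind in ("HBD", "HBA"):
            partner_mask = polar_mask if f.kind == "HBD" else donor_partner_mask
            d = np.linalg.norm(cx.coords - f.anchor, axis=1)
            near = np.where(partner_mask & (d <= criteria.polar_dist))[0]
            partner = None
            if len(near):
                cand = near[np.argsort(d[near])]
                for idx in cand:
                    if f.kind == "HBA" or _donor_angle_ok(mol, conf_pos, f.source_atoms[0], cx.coords[idx], criteria):
                        partner = cx.coords[idx]
                        break
            if partner is None and include_waters and len(cx.waters):
                dw = np.linalg.norm(cx.waters - f.anchor, axis=1)
                for wi in np.argsort(dw):
                    if dw[wi] > criteria.polar_dist:
                        break
                    dwp = np.linalg.norm(cx.coords[polar_mask] - cx.waters[wi], axis=1)
                    if len(dwp) and dwp.min() <= criteria.polar_dist:
                        partner = cx.waters[wi]  # bridge: point the feature at the water
                        break
            if partner is not None:
                direction = partner - f.anchor
                features.append(replace(f, direction=direction / np.linalg.norm(direction)))
        elif f.kind == "HC":
            d = np.linalg.norm(cx.coords[apolar_mask] - f.anchor, axis=1)
            if (d <= criteria.hydrophobic_shell).sum() >= criteria.min_apolar_contacts:
                features.append(f)
        elif f.kind == "AI":
            d = np.linalg.norm(cx.coords[apolar_mask] - f.anchor, axis=1)
            if (d <= criteria.hydrophobic_shell).sum() >= criteria.min_apolar_contacts:
                features.append(f)
    if not features:
        raise EmptyModelError("no ligand-protein contacts satisfied the derivation criteria")

    dmat = np.linalg.norm(cx.coords[:, None, :] - lig_coords[None, :, :], axis=-1)
    xvol_idx = np.where(dmat.min(axis=1) <= criteria.xvol_shell)[0]
    xvols = [ExclusionVolume(center=cx.coords[i], radius=criteria.xvol_radius) for i in xvol_idx]

    return PharmacophoreModel(
        name=name,
        features=features,
        xvols=xvols,
        provenance=[f"sb:{cx.ligand.record_id}", f"xvols:{len(xvols)}"],
    )


def _representative(featuresets: list[FeatureSet]) -> FeatureSet:
    return max(featuresets, key=lambda fs: (len(fs.features), -fs.conformer_index))


def derive_lb_model(
    actives: list,
    mode: str = "shared",
    reference: str | None = None,
    settings: MatchSettings = DEFAULT_SETTINGS,
    merge_dist: float = 1.0,
    name: str = "LB",
) -> PharmacophoreModel:
    """Derive a ligand-based model by correspondence alignment of actives.

    The reference is the active with the most perceived features (ties by
    record id) unless given explicitly. Every other active is aligned to
    the reference features by the screening engine (best conformer, best
    partial mapping); *shared* mode keeps reference features mapped in
    every active, *merged* mode keeps the union of aligned features
    deduplicated by kind within ``merge_dist`` Å.
    """
    if mode not in ("shared", "merged"):
        raise CbscreenError(f"unknown ligand-based mode {mode!r}")
    if not actives:
        raise CbscreenError("at least one active is required")
    from .screening import featuresets_of

    per_active = [featuresets_of(a) for a in actives]
    reps = [_representative(fss) for fss in per_active]
    if reference is not None:
        ref_pos = next((i for i, r in enumerate(reps) if r.record_id == reference), None)
        if ref_pos is None:
            raise CbscreenError(f"reference record {reference!r} not among actives")
    else:
        ref_pos = min(range(len(reps)), key=lambda i: (-len(reps[i].features), reps[i].record_id))
    ref = reps[ref_pos]
    ref_features = [replace(f) for f in ref.features]
    parents = [r.record_id for r in reps]

    matched_in_all = set(range(len(ref_features)))
    aligned_sets: list[FeatureSet] = []
    align_model = PharmacophoreModel(name="_align", features=ref_features, min_required=1)
    for i, fss in enumerate(per_active):
        if i == ref_pos:
            continue
        best = match_model(align_model, fss, settings)
        if best is None:
            matched_in_all = set()
            continue
        matched_in_all &= {mi for mi, _ in best.mapping}
        fs = fss[_conf_pos(fss, best.conformer_index)]
        aligned_sets.append(fs.transformed(best.rotation, best.translation))

    if mode == "shared":
        keep = [ref_features[i] for i in sorted(matched_in_all)]
        if not keep:
            raise EmptyModelError("shared mode found no feature common to every active")
        features = keep
    else:
        features = list(ref_features)
        for fs in aligned_sets:
            for f in fs.features:
                if not any(
                    g.kind == f.kind and np.linalg.norm(g.anchor - f.anchor) <= merge_dist for g in features
                ):
                    features.append(replace(f))
    return PharmacophoreModel(
        name=name, features=features, provenance=[f"lb:{mode}", "parents:" + ",".join(parents)]
    )


def _conf_pos(featuresets: list[FeatureSet], conformer_index: int) -> int:
    for i, fs in enumerate(featuresets):
        if fs.conformer_index == conformer_index:
            return i
    raise CbscreenError(f"conformer {conformer_index} missing from feature sets")


def _ef_key(report: MetricsReport) -> float:
    return -np.inf if report.ef is None else report.ef


def _evaluate(model, actives, decoys, settings) -> MetricsReport:
    hits_a = screen_library(model, actives, settings)
    hits_d = screen_library(model, decoys, settings)
    tp, fp = len(hits_a.hits), len(hits_d.hits)
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=len(decoys) - fp, fn=len(actives) - tp)
    totals = DatasetTotals(n_actives=len(actives), n_decoys=len(decoys))
    return compute_metrics(cm, totals)


def _candidate_edit_lists(model: PharmacophoreModel, radius_step: float, radius_bounds: tuple[float, float]):
    lo, hi = radius_bounds
    for i in range(len(model.features)):
        if len(model.features) > 1:
            yield [ModelEdit("remove_feature", {"index": i})]
        r = model.features[i].radius
        for delta in (-radius_step, radius_step):
            new_r = r + delta
            if lo <= new_r <= hi:
                yield [ModelEdit("set_radius", {"index": i, "radius": new_r})]
    if model.xvols:
        grow = []
        for i, xv in enumerate(model.xvols):
            grow.append(ModelEdit("remove_xvol", {"index": 0}))
        grown = [ExclusionVolume(center=xv.center, radius=xv.radius + radius_step) for xv in model.xvols]
        grow += [ModelEdit("add_xvol", {"xvol": xv}) for xv in grown]
        yield grow


def optimize_model(
    model: PharmacophoreModel,
    actives: list,
    decoys: list,
    budget: int = 20,
    settings: MatchSettings = DEFAULT_SETTINGS,
    sensitivity_floor: float = 0.0,
    radius_step: float = 0.25,
    radius_bounds: tuple[float, float] = (0.5, 3.0),
) -> tuple[PharmacophoreModel, MetricsReport]:
    """Greedy enrichment-guided refinement.

    Candidate moves are feature removal, per-feature radius ±``radius_step``,
    and exclusion-volume growth. A move is accepted only if the enrichment
    factor strictly increases while sensitivity stays at or above the
    floor; the climb stops at the edit budget or a local optimum. The
    returned report carries the discard flag (EF < 4) of the final model.
    """
    if not actives or not decoys:
        raise CbscreenError("optimization requires non-empty actives and decoys")
    current = model
    report = _evaluate(current, actives, decoys, settings)
    for _ in range(int(budget)):
        best_edit, best_model, best_report = None, None, report
        for edits in _candidate_edit_lists(current, radius_step, radius_bounds):
            cand = apply_edits(current, edits)
            cand_report = _evaluate(cand, actives, decoys, settings)
            if cand_report.sensitivity < sensitivity_floor:
                continue
            if _ef_key(cand_report) > _ef_key(best_report):
                best_edit, best_model, best_report = edits, cand, cand_report
        if best_edit is None:
            break
        log.info("model %s: accepted %s (EF %s -> %s)", current.name,
                 [e.verb for e in best_edit], report.ef, best_report.ef)
        current, report = best_model, best_report
    return current, report
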