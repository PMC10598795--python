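import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from cbscreen.chemio import ConformerEnsemble, Molecule, embed_conformers
from cbscreen.errors import CbscreenError, EmptyModelError
from cbscreen.features import Feature, FeatureSet
from cbscreen.geometry import random_rotation
from cbscreen.model import PharmacophoreModel, model_equal
from cbscreen.modelgen import (
    ProteinLigandComplex,
    SBCriteria,
    derive_lb_model,
    derive_sb_model,
    optimize_model,
    read_complex,
)
from cbscreen.synthetic import make_feature_benchmark, make_random_model


def _embedded(smiles, rid, seed=1):
    return embed_conformers(Molecule.from_smiles(smiles, rid), seed=seed)


def _methanol_with_acceptor(distance):
    """Toy complex: methanol O-H pointing straight at a protein carbonyl O."""
    mol = Chem.AddHs(Chem.MolFromSmiles("CO"))
    AllChem.EmbedMolecule(mol, randomSeed=1)
    pos = np.array(mol.GetConformer().GetPositions())
    o = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
    h = next(nb.GetIdx() for nb in mol.GetAtomWithIdx(o).GetNeighbors() if nb.GetAtomicNum() == 1)
    d = pos[h] - pos[o]
    d /= np.linalg.norm(d)
    acc = pos[o] + distance * d
    lig = ConformerEnsemble(molecule=Molecule(mol, "toy-ligand"), conf_ids=[0])
    return (
        ProteinLigandComplex(
            elements=["O", "C"],
            coords=np.array([acc, acc + [1.2, 0.0, 0.0]]),
            res_names=["GLY", "GLY"],
            res_seq=[1, 1],
            chains=["A", "A"],
            ligand=lig,
        ),
        d,
    )


def _buried_benzene():
    """Benzene ring surrounded by six apolar protein carbons at ~4 A."""
    mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
    AllChem.EmbedMolecule(mol, randomSeed=1)
    pos = np.array(mol.GetConformer().GetPositions())
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    centroid = pos[heavy].mean(axis=0)
    shell = []
    for k in range(6):
        ang = 2 * np.pi * k / 6
        shell.append(centroid + 4.0 * np.array([np.cos(ang), np.sin(ang), 0.3 * (-1) ** k]))
    lig = ConformerEnsemble(molecule=Molecule(mol, "benz-ligand"), conf_ids=[0])
    return ProteinLigandComplex(
        elements=["C"] * 6,
        coords=np.array(shell),
        res_names=["LEU"] * 6,
        res_seq=list(range(1, 7)),
        chains=["A"] * 6,
        ligand=lig,
    )


class TestStructureBased:
    def test_donor_contact_yields_one_hbd_toward_acceptor(self):
        cx, d = _methanol_with_acceptor(2.9)
        model = derive_sb_model(cx)
        assert [f.kind for f in model.features] == ["HBD"]
        assert model.features[0].direction @ d == pytest.approx(1.0, abs=1e-6)

    def test_stretched_contact_gives_no_polar_features(self):
        cx, _ = _methanol_with_acceptor(4.5)
        with pytest.raises(EmptyModelError):
            derive_sb_model(cx)

    def test_buried_aromatic_ring_gives_ai_and_hc(self):
        model = derive_sb_model(_buried_benzene())
        assert sorted(f.kind for f in model.features) == ["AI", "HC"]

    def test_xvol_centers_are_protein_atoms(self):
        cx = _buried_benzene()
        model = derive_sb_model(cx)
        assert model.xvols
        for xv in model.xvols:
            d = np.linalg.norm(cx.coords - xv.center, axis=1)
            assert d.min() == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_of_complex_transforms_model_covariantly(self, rng):
        cx = _buried_benzene()
        R = random_rotation(rng)
        t = rng.uniform(-8, 8, 3)
        m1 = derive_sb_model(cx).transformed(R, t)
        m2 = derive_sb_model(cx.transformed(R, t))
        assert model_equal(m1, m2, tol=1e-6)

    def test_water_bridge_feature_requires_flag(self):
        cx, d = _methanol_with_acceptor(2.9)
        # move the direct partner away, add a bridging water near ligand + protein
        lig_o = cx.ligand.coords(0)[1]
        water = lig_o + 2.8 * np.array([0.0, 1.0, 0.0])
        cx_far = ProteinLigandComplex(
            elements=["N"],
            coords=water[None, :] + np.array([[0.0, 2.8, 0.0]]),
            res_names=["GLY"],
            res_seq=[1],
            chains=["A"],
            ligand=cx.ligand,
            waters=water[None, :],
        )
        with pytest.raises(EmptyModelError):
            derive_sb_model(cx_far, include_waters=False)
        model = derive_sb_model(cx_far, include_waters=True)
        assert {f.kind for f in model.features} <= {"HBD", "HBA"}
        assert len(model.features) >= 1


class TestReadComplex:
    def test_pdb_round_trip_toy_file(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  C1  LIG A  90       2.000   1.200   0.000  1.00  0.00           C\n"
            "HETATM    4  C2  LIG A  90       3.400   1.200   0.000  1.00  0.00           C\n"
            "HETATM    5  O1  HOH A  99       5.000   5.000   5.000  1.00  0.00           O\n"
            "END\n"
        )
        cx = read_complex(pdb)
        assert cx.elements == ["N", "C"]
        assert cx.ligand.molecule.record_id == "LIG"
        assert cx.ligand.coords(0).shape == (2, 3)
        assert cx.waters.shape == (1, 3)


def _cloud(rid, feats):
    return FeatureSet(record_id=rid, conformer_index=0, features=feats,
                      coords=np.array([f.anchor for f in feats]))


class TestLigandBased:
    def test_single_active_returns_its_own_features(self):
        tol = _embedded("Cc1ccccc1O", "cresol")
        model = derive_lb_model([tol], mode="shared")
        from cbscreen.features import perceive_features

        best = max((perceive_features(tol, i) for i in range(tol.n_conformers)),
                   key=lambda fs: len(fs.features))
        assert sorted(model.kinds()) == sorted(best.kinds())

    def test_two_copies_shared_equals_merged(self):
        a = _embedded("Cc1ccccc1O", "copy1", seed=4)
        b = _embedded("Cc1ccccc1O", "copy2", seed=4)
        shared = derive_lb_model([a, b], mode="shared")
        merged = derive_lb_model([a, b], mode="merged")
        assert model_equal(shared, merged, tol=1e-6)

    def test_constructed_overlap_controls_shared_feature_count(self, rng):
        ref = _cloud("ref", [
            Feature("AI", [0.0, 0.0, 0.0]),
            Feature("HBA", [3.5, 0.0, 0.0]),
            Feature("HBD", [0.0, 4.0, 0.0]),
        ])
        # second cloud shares only the AI+HBA pair, rigidly moved
        R = random_rotation(rng)
        t = np.array([5.0, -2.0, 1.0])
        pair = _cloud("other", [
            Feature("AI", [0.0, 0.0, 0.0]),
            Feature("HBA", [3.5, 0.0, 0.0]),
        ]).transformed(R, t)
        shared = derive_lb_model([ref, pair], mode="shared")
        assert sorted(shared.kinds()) == ["AI", "HBA"]
        merged = derive_lb_model([ref, pair], mode="merged")
        assert len(shared.features) <= len(merged.features)

    def test_shared_with_zero_common_features_errors(self):
        a = _cloud("a", [Feature("AI", [0, 0, 0]), Feature("AI", [3, 0, 0])])
        b = _cloud("b", [Feature("HBD", [0, 0, 0]), Feature("HBD", [3, 0, 0])])
        with pytest.raises(EmptyModelError):
            derive_lb_model([a, b], mode="shared")

    def test_unknown_mode_rejected(self):
        with pytest.raises(CbscreenError):
            derive_lb_model([_cloud("a", [Feature("AI", [0, 0, 0])])], mode="both")


class TestOptimize:
    def test_local_optimum_returned_unchanged(self, bench_model, small_benchmark):
        # perfect separation: no edit can raise EF above the ceiling D/A
        refined, report = optimize_model(
            bench_model, small_benchmark.actives, small_benchmark.decoys, budget=3
        )
        assert model_equal(refined, bench_model)
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_spurious_feature_blocking_all_actives_is_removed(self, bench_model, small_benchmark):
        spoiled = PharmacophoreModel(
            name="spoiled",
            features=list(bench_model.features) + [Feature("HBD", [99.0, 99.0, 99.0])],
            xvols=list(bench_model.xvols),
        )
        from cbscreen.screening import screen_library

        assert not screen_library(spoiled, small_benchmark.actives).hits
        refined, report = optimize_model(
            spoiled, small_benchmark.actives, small_benchmark.decoys, budget=4
        )
        assert len(refined.features) == len(bench_model.features)
        assert report.ef is not None and report.ef > 0

    def test_discard_flag_follows_final_ef(self, bench_model, small_benchmark):
        _, report = optimize_model(bench_model, small_benchmark.actives, small_benchmark.decoys, budget=1)
        assert report.discard == (report.ef is None or report.ef < 4)

    def test_empty_libraries_rejected(self, bench_model):
        with pytest.raises(CbscreenError):
            optimize_model(bench_model, [], [], budget=1)
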