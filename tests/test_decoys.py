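import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from cbscreen.chemio import Molecule, PropertyVector, PROPERTY_FIELDS, compute_properties
from cbscreen.decoys import (
    compute_window,
    diversity_select,
    exclude_actives,
    filter_pool,
    generate_decoys,
)
from cbscreen.errors import ConfigError
from cbscreen.synthetic import make_molecular_benchmark


def pv(mw=300.0, n_n=1, n_o=2, n_rot=3, n_hbd=1, n_hba=2, logp=2.0):
    return PropertyVector(mw=mw, n_n=n_n, n_o=n_o, n_rot=n_rot, n_hbd=n_hbd, n_hba=n_hba, logp=logp)


class TestWindow:
    def test_single_active_degenerates(self):
        w = compute_window([pv(mw=321.5)])
        s = w.stats["mw"]
        assert s.min == s.max == s.mean == 321.5 and s.sd == 0.0

    def test_two_active_arithmetic(self):
        w = compute_window([pv(mw=300.0), pv(mw=500.0)])
        s = w.stats["mw"]
        assert (s.min, s.max, s.mean) == (300.0, 500.0, 400.0)

    def test_window_matches_independent_recomputation(self, rng):
        rows = [pv(mw=float(rng.uniform(200, 600)), logp=float(rng.normal(2, 1)),
                   n_rot=int(rng.integers(0, 10))) for _ in range(10)]
        w = compute_window(rows)
        for f in PROPERTY_FIELDS:
            xs = np.array([getattr(r, f) for r in rows], dtype=float)
            assert w.stats[f].min == pytest.approx(xs.min())
            assert w.stats[f].max == pytest.approx(xs.max())
            assert w.stats[f].mean == pytest.approx(xs.mean())
            assert w.stats[f].sd == pytest.approx(xs.std())

    def test_empty_actives_error(self):
        with pytest.raises(ValueError):
            compute_window([])


class TestFilterPool:
    def test_actives_survive_their_own_window(self):
        props = [pv(mw=m) for m in (300, 350, 400)]
        mols = [Molecule.from_smiles("CCO", f"a{i}") for i in range(3)]
        w = compute_window(props)
        kept, rej = filter_pool(list(zip(mols, props)), w, mode="minmax")
        assert len(kept) == 3 and all(v == 0 for v in rej.values())

    def test_out_of_window_rejection_is_counted(self):
        w = compute_window([pv(mw=300), pv(mw=400)])
        kept, rej = filter_pool([(Molecule.from_smiles("CCO", "big"), pv(mw=650))], w)
        assert kept == [] and rej["mw"] == 1

    def test_brute_force_agreement_on_random_pool(self, rng):
        actives = [pv(mw=float(rng.uniform(250, 450)), logp=float(rng.normal(2, 0.5)))
                   for _ in range(8)]
        w = compute_window(actives)
        pool = [(Molecule.from_smiles("CCO", f"p{i}"),
                 pv(mw=float(rng.uniform(100, 700)), logp=float(rng.normal(2, 2))))
                for i in range(100)]
        for mode, k in (("minmax", 2.0), ("mean_sd", 1.5)):
            kept, _ = filter_pool(pool, w, mode=mode, k=k)
            expected = []
            for mol, p in pool:
                ok = True
                for f in PROPERTY_FIELDS:
                    x, s = getattr(p, f), w.stats[f]
                    ok &= (s.min <= x <= s.max) if mode == "minmax" else (abs(x - s.mean) <= k * s.sd)
                if ok:
                    expected.append(mol.record_id)
            assert [m.record_id for m, _ in kept] == expected

    def test_unknown_mode_is_config_error(self):
        w = compute_window([pv()])
        with pytest.raises(ConfigError):
            filter_pool([], w, mode="quantile")


class TestExcludeActives:
    def test_disjoint_subset_unchanged(self):
        subset = [Molecule.from_smiles("CCO", "eth")]
        actives = [Molecule.from_smiles("c1ccccc1", "benz")]
        assert exclude_actives(subset, actives) == subset

    def test_salt_form_of_active_is_removed(self):
        subset = [Molecule.from_smiles("c1ccc(N)cc1.Cl", "aniline-salt"),
                  Molecule.from_smiles("CCO", "eth")]
        actives = [Molecule.from_smiles("Nc1ccccc1", "aniline")]
        out = exclude_actives(subset, actives)
        assert [m.record_id for m in out] == ["eth"]

    def test_subset_equal_to_actives_empties(self, caplog):
        actives = [Molecule.from_smiles("CCO", "eth")]
        with caplog.at_level("WARNING"):
            assert exclude_actives(list(actives), actives) == []

    def test_extra_known_list_also_excludes(self):
        subset = [Molecule.from_smiles("CCO", "eth")]
        out = exclude_actives(subset, [], extra_known=[Molecule.from_smiles("OCC", "same")])
        assert out == []


class TestDiversitySelect:
    def test_duplicates_collapse_to_one_representative(self):
        subset = [Molecule.from_smiles("Cc1ccccc1O", f"dup{i}") for i in range(10)]
        ds = diversity_select(subset, n_target=5, seed=1)
        assert len(ds) == 1

    def test_mutually_dissimilar_set_is_identity(self):
        subset = [Molecule.from_smiles(s, f"d{i}") for i, s in enumerate(
            ["CCO", "c1ccccc1", "CC(=O)N", "CCCCCCCC", "c1ccncc1"])]
        ds = diversity_select(subset, n_target=10, seed=1)
        assert [m.record_id for m in ds.records] == [m.record_id for m in subset]

    def test_two_constructed_clusters_give_one_representative_each(self):
        cluster_a = ["CCCCCCCCCCCCCCCC", "CCCCCCCCCCCCCCCCC", "CCCCCCCCCCCCCCCCCC"]
        cluster_b = ["COCCOCCOCCOC", "COCCOCCOCCOCCOC", "COCCOCCOCCOCCOCCOC"]
        mols = [Molecule.from_smiles(s, f"m{i}") for i, s in enumerate(cluster_a + cluster_b)]
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = [gen.GetFingerprint(m.mol) for m in mols]
        # construction check: tight within clusters, loose across
        for grp in (range(0, 3), range(3, 6)):
            for i in grp:
                for j in grp:
                    if i < j:
                        assert DataStructs.TanimotoSimilarity(fps[i], fps[j]) > 0.6
        for i in range(0, 3):
            for j in range(3, 6):
                assert DataStructs.TanimotoSimilarity(fps[i], fps[j]) < 0.3
        ds = diversity_select(mols, n_target=2, threshold=0.6, seed=1)
        assert len(ds) == 2
        picked = {m.record_id for m in ds.records}
        assert len(picked & {"m0", "m1", "m2"}) == 1
        assert len(picked & {"m3", "m4", "m5"}) == 1

    def test_deterministic_and_bounded(self):
        pool = make_molecular_benchmark(["c1ccccc1", "c1ccncc1", "CCCCO"], n_variants=25, seed=5)
        a = diversity_select(pool, n_target=6, seed=9)
        b = diversity_select(pool, n_target=6, seed=9)
        assert [m.record_id for m in a.records] == [m.record_id for m in b.records]
        assert len(a) <= 6


class TestPipeline:
    def test_generated_decoys_satisfy_all_invariants(self):
        actives = [Molecule.from_smiles(s, f"A{i}") for i, s in enumerate(
            ["c1ccc(O)cc1", "c1ccc(N)cc1", "Cc1ccccc1", "c1ccncc1", "COc1ccccc1"])]
        pool = make_molecular_benchmark(["c1ccccc1", "c1ccncc1", "Cc1ccco1"], n_variants=40, seed=1)
        ds = generate_decoys(actives, pool, n_target=8, seed=3)
        assert 1 <= len(ds) <= 8
        w = compute_window([compute_properties(m) for m in actives])
        keys = {m.canonical_key() for m in actives}
        for m in ds.records:
            assert m.canonical_key() not in keys
            assert w.contains(compute_properties(m))
        assert ds.provenance["initial_pool"] == len(pool)
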