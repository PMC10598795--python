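import numpy as np
import pytest

from cbscreen.errors import CbscreenError
from cbscreen.features import Feature, FeatureSet
from cbscreen.geometry import random_rotation
from cbscreen.model import ExclusionVolume, PharmacophoreModel
from cbscreen.screening import (
    DEFAULT_SETTINGS,
    HitList,
    MatchResult,
    MatchSettings,
    consensus_summary,
    consensus_table,
    match_featureset,
    match_model,
    screen_library,
)
from oracles import brute_force_match


def _cloud(rid, feats, conformer_index=0):
    return FeatureSet(record_id=rid, conformer_index=conformer_index, features=feats,
                      coords=np.array([f.anchor for f in feats]))


def _model_from(fs, name="m", **kw):
    return PharmacophoreModel(name=name, features=[Feature(f.kind, f.anchor.copy(), f.radius)
                                                   for f in fs.features], **kw)


class TestMatchBasics:
    def test_self_match_is_exact(self, benzene_features):
        model = _model_from(benzene_features)
        r = match_featureset(model, benzene_features)
        assert r is not None
        assert r.n_matched == len(model.features)
        assert r.rmsd == pytest.approx(0.0, abs=1e-9)
        assert r.fit_score == pytest.approx(len(model.features) + 1, abs=1e-6)

    def test_kind_incompatibility_is_no_match(self):
        model = PharmacophoreModel(name="donor", features=[Feature("HBD", [0, 0, 0])])
        lig = _cloud("apolar", [Feature("HC", [0, 0, 0]), Feature("AI", [3, 0, 0])])
        assert match_featureset(model, lig) is None

    def test_rigid_invariance_of_match(self, small_benchmark, rng):
        model = small_benchmark.model
        fs = small_benchmark.actives[0]
        base = match_featureset(model, fs)
        R, t = random_rotation(rng), rng.uniform(-30, 30, 3)
        moved = match_featureset(model, fs.transformed(R, t))
        assert moved is not None
        assert moved.n_matched == base.n_matched
        assert moved.fit_score == pytest.approx(base.fit_score, abs=1e-6)
        model_moved = model.transformed(R, t)
        again = match_featureset(model_moved, fs)
        assert again is not None and again.n_matched == base.n_matched

    def test_best_conformer_policy_prefers_score_then_rmsd_then_index(self):
        model = PharmacophoreModel(name="pair", features=[
            Feature("HBA", [0.0, 0.0, 0.0]), Feature("AI", [3.0, 0.0, 0.0]),
        ])
        exact = _cloud("r", model.features, conformer_index=1)
        jittered = _cloud("r", [Feature("HBA", [0.3, 0.0, 0.0]), Feature("AI", [3.0, 0.2, 0.0])],
                          conformer_index=0)
        best = match_model(model, [jittered, exact])
        assert best.conformer_index == 1


class TestMonotonicity:
    def test_added_xvol_never_increases_hits(self, bench_model, small_benchmark):
        base_hits = screen_library(bench_model, small_benchmark.library).record_ids
        centre = bench_model.anchors().mean(axis=0)
        blocked = PharmacophoreModel(
            name="blocked", features=list(bench_model.features),
            xvols=list(bench_model.xvols) + [ExclusionVolume(centre, 1.0)],
        )
        blocked_hits = screen_library(blocked, small_benchmark.library).record_ids
        assert blocked_hits <= base_hits

    def test_removing_feature_never_decreases_hits(self, bench_model, small_benchmark):
        base_hits = screen_library(bench_model, small_benchmark.library).record_ids
        reduced = PharmacophoreModel(name="reduced", features=list(bench_model.features[1:]))
        reduced_hits = screen_library(reduced, small_benchmark.library).record_ids
        assert base_hits <= reduced_hits


def _random_instance(rng):
    """A direction-free random matcher instance (model + small ensemble)."""
    kinds = ["HBD", "HBA", "HC", "AI"]
    n_model = int(rng.integers(2, 6))
    model = PharmacophoreModel(
        name="rnd",
        features=[Feature(kinds[rng.integers(4)], rng.uniform(-5, 5, 3)) for _ in range(n_model)],
        min_required=int(rng.integers(1, n_model + 1)),
    )
    ensemble = []
    for ci in range(int(rng.integers(1, 4))):
        if rng.random() < 0.5:
            # jittered partial copy of the model: matches are plentiful
            feats = [Feature(f.kind, f.anchor + rng.normal(0, 0.4, 3)) for f in model.features]
            if len(feats) > 1 and rng.random() < 0.5:
                feats = feats[1:]
        else:
            feats = [Feature(kinds[rng.integers(4)], rng.uniform(-5, 5, 3))
                     for _ in range(int(rng.integers(1, 7)))]
        R, t = random_rotation(rng), rng.uniform(-10, 10, 3)
        ensemble.append(_cloud("r", feats, conformer_index=ci).transformed(R, t))
    return model, ensemble


class TestBruteForceEquivalence:
    def test_clique_matcher_equals_exhaustive_search(self, rng):
        """Spot sample; the full 200-instance comparison runs in the acceptance suite."""
        settings = DEFAULT_SETTINGS
        n_matched = 0
        for _ in range(40):
            model, ensemble = _random_instance(rng)
            for fs in ensemble:
                mine = match_featureset(model, fs, settings)
                oracle = brute_force_match(model, fs, settings)
                assert (mine is None) == (oracle is None)
                if mine is not None:
                    n_matched += 1
                    assert mine.n_matched == oracle[0]
                    assert mine.fit_score == pytest.approx(oracle[1], abs=1e-6)
                    assert mine.rmsd == pytest.approx(oracle[2], abs=1e-6)
        assert n_matched > 10  # both branches exercised


class TestScreenAndConsensus:
    def test_incompatible_library_gives_zero_hits(self, bench_model):
        lib = [_cloud(f"x{i}", [Feature("HC", [float(i), 0, 0])]) for i in range(5)]
        if all(k != "HC" for k in bench_model.kinds()):
            assert not screen_library(bench_model, lib).hits

    def test_hitlist_unique_sorted_records(self, bench_model, small_benchmark):
        hl = screen_library(bench_model, small_benchmark.library)
        ids = [h.record_id for h in hl.hits]
        assert len(ids) == len(set(ids))
        scores = [h.fit_score for h in hl.hits]
        assert scores == sorted(scores, reverse=True)
        assert hl.library_size == len(small_benchmark.library)

    def test_consensus_single_model(self, bench_model, small_benchmark):
        hl = screen_library(bench_model, small_benchmark.library)
        rows = consensus_table([hl])
        assert rows and all(r.n_models == 1 for r in rows)

    def test_consensus_triple_overlap(self):
        def mk(model, ids):
            hits = [MatchResult(model, rid, 0, ((0, 0),), 0.0, 2.0) for rid in ids]
            return HitList(model=model, hits=hits, library_size=10)

        rows = consensus_table([mk("A", ["r1", "r2"]), mk("B", ["r1"]), mk("C", ["r1", "r3"])])
        by_id = {r.record_id: r for r in rows}
        assert by_id["r1"].n_models == 3
        assert by_id["r1"].models_matched == ("A", "B", "C")
        summary = consensus_summary(rows, library_size=10)
        assert summary == {"single": 2, "double": 0, "triple_plus": 1, "total": 3,
                           "pct_of_library": 30.0}

    def test_consensus_rejects_mismatched_libraries(self):
        a = HitList(model="A", hits=[], library_size=10)
        b = HitList(model="B", hits=[], library_size=11)
        with pytest.raises(CbscreenError):
            consensus_table([a, b])

    def test_direction_cone_enforced(self):
        model = PharmacophoreModel(name="dir", features=[
            Feature("HBD", [0.0, 0.0, 0.0], direction=[0, 0, 1]),
            Feature("HBA", [3.0, 0.0, 0.0]),
            Feature("HC", [0.0, 3.0, 0.0]),
        ])
        good = _cloud("good", [
            Feature("HBD", [0.0, 0.0, 0.0], direction=[0, 0, 1]),
            Feature("HBA", [3.0, 0.0, 0.0]),
            Feature("HC", [0.0, 3.0, 0.0]),
        ])
        bad = _cloud("bad", [
            Feature("HBD", [0.0, 0.0, 0.0], direction=[0, 1, 0]),
            Feature("HBA", [3.0, 0.0, 0.0]),
            Feature("HC", [0.0, 3.0, 0.0]),
        ])
        assert match_featureset(model, good) is not None
        assert match_featureset(model, bad) is None

    def test_xvol_clash_uses_vdw_allowance(self):
        feats = [Feature("HBA", [0.0, 0.0, 0.0]), Feature("AI", [4.0, 0.0, 0.0]),
                 Feature("HC", [0.0, 4.0, 0.0])]
        lig = _cloud("lig", feats)
        clash_center = np.array([0.0, 0.0, 2.0])  # 2.0 < 1.0 + 1.2 from the first anchor
        model = PharmacophoreModel(name="xv", features=feats,
                                   xvols=[ExclusionVolume(clash_center, 1.0)])
        assert match_featureset(model, lig) is None
        far = PharmacophoreModel(name="xv2", features=feats,
                                 xvols=[ExclusionVolume([0.0, 0.0, 3.0], 1.0)])
        assert match_featureset(far, lig) is not None
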