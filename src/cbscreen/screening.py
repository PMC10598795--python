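"""Geometric pharmacophore matching and library screening.

Matching one conformer against a model proceeds in three stages:

1. **Correspondence graph.** Nodes are kind-compatible (model feature,
   ligand feature) pairs; an edge joins two nodes when the pairwise
   anchor-distance discrepancy is within ``eps`` plus the two model
   features' radius slack. Any mapping that can pass the final tolerance
   test is a clique in this graph (triangle inequality), so clique
   enumeration loses nothing.
2. **Clique enumeration.** Maximal cliques (networkx) of size at least
   ``min_required``, plus all their sub-mappings of admissible size —
   a larger clique can fail the tolerance test while a subset passes.
3. **Rigid verification.** Each candidate mapping is superposed by
   least-squares (Kabsch); it is accepted only if every mapped ligand
   anchor lies inside its model feature's tolerance sphere, directional
   features agree within the angular cone, and no ligand heavy atom
   penetrates an exclusion volume.

The fit score is a transparent surrogate: ``|mapping| + (1 - rmsd/rmax)``
clipped at zero, so matched-feature count dominates and RMSD breaks ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .chemio import ConformerEnsemble
from .errors import CbscreenError
from .features import FeatureSet, perceive_features
from .geometry import angle_between, apply_transform, kabsch
from .model import PharmacophoreModel


@dataclass(frozen=True)
class MatchSettings:
    """Geometric tolerances of the matcher.

    eps — pair-distance consistency slack (Å) added on top of the two
    model features' radii; rmax — RMSD scale of the fit score (Å);
    vdw_allowance — van der Waals allowance added to exclusion-volume
    radii in the clash test (Å); cone_deg — angular tolerance for
    directional features (degrees).
    """

    eps: float = 0.5
    rmax: float = 2.0
    vdw_allowance: float = 1.2
    cone_deg: float = 30.0


DEFAULT_SETTINGS = MatchSettings()


@dataclass
class MatchResult:
    """Best accepted mapping of one library record against one model."""

    model: str
    record_id: str
    conformer_index: int
    mapping: tuple[tuple[int, int], ...]  # (model feature idx, ligand feature idx)
    rmsd: float
    fit_score: float
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None

    @property
    def n_matched(self) -> int:
        return len(self.mapping)


@dataclass
class HitList:
    """Per-model screening outcome: best match per matching record."""

    model: str
    hits: list[MatchResult]
    library_size: int

    @property
    def record_ids(self) -> set[str]:
        return {h.record_id for h in self.hits}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": h.record_id,
                "model": h.model,
                "conformer": h.conformer_index,
                "n_matched": h.n_matched,
                "rmsd": h.rmsd,
                "fit_score": h.fit_score,
            }
            for h in self.hits
        ]
        return pd.DataFrame(rows, columns=["record_id", "model", "conformer", "n_matched", "rmsd", "fit_score"])


@dataclass
class ConsensusRow:
    record_id: str
    models_matched: tuple[str, ...]
    best_score: float

    @property
    def n_models(self) -> int:
        return len(self.models_matched)


def featuresets_of(ens, settings=None) -> list[FeatureSet]:
    """Normalize a screening input to a list of per-conformer feature sets.

    Accepts a ConformerEnsemble (features are perceived per conformer),
    a single FeatureSet (abstract feature cloud), or a list of FeatureSet.
    """
    if isinstance(ens, FeatureSet):
        return [ens]
    if isinstance(ens, ConformerEnsemble):
        return [perceive_features(ens, i) for i in range(ens.n_conformers)]
    if isinstance(ens, (list, tuple)) and all(isinstance(x, FeatureSet) for x in ens):
        return list(ens)
    raise TypeError(f"cannot screen object of type {type(ens).__name__}")


def _candidate_mappings(model: PharmacophoreModel, fs: FeatureSet, settings: MatchSettings):
    """Yield injective kind-compatible mappings surviving distance pruning."""
    nodes = [
        (i, j)
        for i, mf in enumerate(model.features)
        for j, lf in enumerate(fs.features)
        if mf.kind == lf.kind
    ]
    need = model.required
    if len(nodes) < need:
        return
    manchor = model.anchors()
    lanchor = fs.anchors()
    dm = np.linalg.norm(manchor[:, None, :] - manchor[None, :, :], axis=-1)
    dl = np.linalg.norm(lanchor[:, None, :] - lanchor[None, :, :], axis=-1)
    radii = np.array([f.radius for f in model.features])

    G = nx.Graph()
    G.add_nodes_from(nodes)
    for a in range(len(nodes)):
        i, j = nodes[a]
        for b in range(a + 1, len(nodes)):
            k, l = nodes[b]
            if i == k or j == l:
                continue
            if abs(dm[i, k] - dl[j, l]) <= settings.eps + radii[i] + radii[k]:
                G.add_edge(nodes[a], nodes[b])

    seen: set[frozenset] = set()
    for clique in nx.find_cliques(G):
        if len(clique) < need:
            continue
        for size in range(need, len(clique) + 1):
            for subset in combinations(clique, size):
                # a subset of a clique is injective iff its pairs collide nowhere;
                # clique edges already guarantee i!=k and j!=l pairwise
                key = frozenset(subset)
                if key not in seen:
                    seen.add(key)
                    yield subset


def _verify_mapping(model, fs, mapping, settings):
    """Superpose a mapping and apply tolerance/direction/xvol acceptance.

    Returns (rmsd, R, t) if accepted, else None.
    """
    midx = [m for m, _ in mapping]
    lidx = [l for _, l in mapping]
    P = fs.anchors()[lidx]
    Q = model.anchors()[midx]
    R, t, res = kabsch(P, Q)
    moved = apply_transform(R, t, P)
    for row, mi in zip(moved, midx):
        mf = model.features[mi]
        if np.linalg.norm(row - mf.anchor) > mf.radius + 1e-9:
            return None
    for (mi, li) in mapping:
        mf = model.features[mi]
        lf = fs.features[li]
        if mf.direction is not None and lf.direction is not None:
            ang = angle_between(R @ lf.direction, mf.direction)
            # ring normals are sign-ambiguous: compare the acute angle for AI
            if mf.kind == "AI":
                ang = min(ang, 180.0 - ang)
            if ang > settings.cone_deg + 1e-9:
                return None
    if model.xvols and len(fs.coords):
        lig = apply_transform(R, t, fs.coords)
        for xv in model.xvols:
            d = np.linalg.norm(lig - xv.center, axis=1)
            if np.any(d < xv.radius + settings.vdw_allowance):
                return None
    return res, R, t


def _score(n_matched: int, res: float, settings: MatchSettings) -> float:
    return n_matched + max(0.0, 1.0 - res / settings.rmax)


def match_featureset(
    model: PharmacophoreModel, fs: FeatureSet, settings: MatchSettings = DEFAULT_SETTINGS
) -> MatchResult | None:
    """Match a single feature set against a model; best accepted mapping or None."""
    if not model.features:
        raise CbscreenError(f"model {model.name!r} has no features")
    best = None
    best_key = None
    for mapping in _candidate_mappings(model, fs, settings):
        ver = _verify_mapping(model, fs, mapping, settings)
        if ver is None:
            continue
        res, R, t = ver
        score = _score(len(mapping), res, settings)
        key = (-score, res)
        if best_key is None or key < best_key:
            best_key = key
            best = MatchResult(
                model=model.name,
                record_id=fs.record_id,
                conformer_index=fs.conformer_index,
                mapping=tuple(sorted(mapping)),
                rmsd=res,
                fit_score=score,
                rotation=R,
                translation=t,
            )
    return best


def match_model(model: PharmacophoreModel, ens, settings: MatchSettings = DEFAULT_SETTINGS) -> MatchResult | None:
    """Match every conformer of a record; best conformer wins.

    Ties are broken by lower RMSD, then lower conformer index, so the
    result is deterministic.
    """
    best = None
    best_key = None
    for fs in featuresets_of(ens):
        r = match_featureset(model, fs, settings)
        if r is None:
            continue
        key = (-r.fit_score, r.rmsd, r.conformer_index)
        if best_key is None or key < best_key:
            best_key = key
            best = r
    return best


def screen_library(
    model: PharmacophoreModel, lib: list, settings: MatchSettings = DEFAULT_SETTINGS
) -> HitList:
    """Screen a library (ensembles or feature clouds) against one model."""
    hits = []
    for ens in lib:
        r = match_model(model, ens, settings)
        if r is not None:
            hits.append(r)
    hits.sort(key=lambda h: (-h.fit_score, h.rmsd, h.record_id))
    return HitList(model=model.name, hits=hits, library_size=len(lib))


def consensus_table(hitlists: list[HitList]) -> list[ConsensusRow]:
    """Merge per-model hit lists into one row per distinct record.

    Rows partition into single (n=1), double (n=2) and triple-plus
    consensus classes; all hit lists must cover the same library.
    """
    if not hitlists:
        raise CbscreenError("consensus requires at least one hit list")
    sizes = {h.library_size for h in hitlists}
    if len(sizes) != 1:
        raise CbscreenError(f"hit lists cover libraries of different sizes: {sorted(sizes)}")
    acc: dict[str, dict] = {}
    for hl in hitlists:
        for h in hl.hits:
            entry = acc.setdefault(h.record_id, {"models": [], "best": -np.inf})
            entry["models"].append(hl.model)
            entry["best"] = max(entry["best"], h.fit_score)
    rows = [
        ConsensusRow(record_id=rid, models_matched=tuple(sorted(set(e["models"]))), best_score=float(e["best"]))
        for rid, e in acc.items()
    ]
    rows.sort(key=lambda r: (-r.n_models, -r.best_score, r.record_id))
    return rows


def consensus_summary(rows: list[ConsensusRow], library_size: int) -> dict:
    """Class totals (n=1 / n=2 / n>=3) with percentage of the library."""
    n1 = sum(1 for r in rows if r.n_models == 1)
    n2 = sum(1 for r in rows if r.n_models == 2)
    n3 = sum(1 for r in rows if r.n_models >= 3)
    total = len(rows)
    return {
        "single": n1,
        "double": n2,
        "triple_plus": n3,
        "total": total,
        "pct_of_library": 100.0 * total / library_size if library_size else float("nan"),
    }


def consensus_frame(rows: list[ConsensusRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "n_models": r.n_models,
                "models": "|".join(r.models_matched),
                "best_score": r.best_score,
            }
            for r in rows
        ],
        columns=["record_id", "n_models", "models", "best_score"],
    )
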