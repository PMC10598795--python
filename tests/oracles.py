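"""Independent oracles used by the test suite.

The brute-force matcher enumerates every kind-compatible injective
mapping directly (no correspondence graph, no clique search) and uses
scipy's ``Rotation.align_vectors`` for the superposition, so it shares
no search machinery with the production matcher.
"""

import warnings
from itertools import combinations, permutations

import numpy as np
from scipy.spatial.transform import Rotation


def _superpose(P, Q):
    """Rotation+translation mapping P onto Q via scipy; returns (moved, rmsd)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    if len(P) == 1:
        return Q.copy(), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(Q - cq, P - cp)
    moved = rot.apply(P - cp) + cq
    return moved, float(np.sqrt(((moved - Q) ** 2).sum() / len(P)))


def brute_force_match(model, fs, settings):
    """Exhaustive search over all kind-compatible injections.

    Returns (size, fit_score, rmsd) of the best accepted mapping, or None.
    Intended for direction-free, exclusion-volume-free instances where
    acceptance is fully determined by the anchor geometry.
    """
    nm, nl = len(model.features), len(fs.features)
    need = model.required
    manchors = model.anchors()
    lanchors = fs.anchors()
    best = None
    best_key = None
    for size in range(need, min(nm, nl) + 1):
        for msub in combinations(range(nm), size):
            for lsub in permutations(range(nl), size):
                if any(model.features[i].kind != fs.features[j].kind for i, j in zip(msub, lsub)):
                    continue
                moved, res = _superpose(lanchors[list(lsub)], manchors[list(msub)])
                if any(
                    np.linalg.norm(moved[k] - model.features[i].anchor) > model.features[i].radius + 1e-9
                    for k, i in enumerate(msub)
                ):
                    continue
                score = size + max(0.0, 1.0 - res / settings.rmax)
                key = (-score, res)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (size, score, res)
    return best


def brute_force_best_over_conformers(model, featuresets, settings):
    best = None
    for fs in featuresets:
        r = brute_force_match(model, fs, settings)
        if r is None:
            continue
        if best is None or (-r[1], r[2]) < (-best[1], best[2]):
            best = r
    return best
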