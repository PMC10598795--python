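"""Property-matched, actives-free, diversity-clustered decoy sets.

The pipeline mirrors standard benchmark-set construction: compute the
actives' property window over the seven descriptors, filter a candidate
pool into that window (min–max by default, mean ± k·SD as an
alternative), remove anything structurally identical to a known active,
then pick diverse representatives by sphere-exclusion (leader)
clustering on Morgan fingerprints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemio import Molecule, PropertyVector, PROPERTY_FIELDS, compute_properties
from .errors import ConfigError

log = logging.getLogger(__name__)

DEFAULT_TANIMOTO_THRESHOLD = 0.6
#: decoy-set size used in the reference campaign
DEFAULT_N_TARGET = 4901


@dataclass(frozen=True)
class PropertyStats:
    min: float
    max: float
    mean: float
    sd: float


@dataclass
class PropertyWindow:
    """Per-descriptor min/max/mean/sd over the actives set."""

    stats: dict[str, PropertyStats]

    def contains(self, props: PropertyVector, mode: str = "minmax", k: float = 2.0) -> bool:
        return not self.violations(props, mode, k)

    def violations(self, props: PropertyVector, mode: str = "minmax", k: float = 2.0) -> list[str]:
        if mode not in ("minmax", "mean_sd"):
            raise ConfigError(f"unknown filter mode {mode!r}")
        out = []
        for f in PROPERTY_FIELDS:
            x = getattr(props, f)
            s = self.stats[f]
            if mode == "minmax":
                ok = s.min <= x <= s.max
            else:
                ok = abs(x - s.mean) <= k * s.sd
            if not ok:
                out.append(f)
        return out


@dataclass
class DecoySet:
    """Final decoy records plus full provenance of their construction."""

    records: list[Molecule]
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=1)


def compute_window(actives_props: list[PropertyVector]) -> PropertyWindow:
    """Min/max/mean/sd of every descriptor over the actives (population SD)."""
    if not actives_props:
        raise ValueError("cannot compute a property window from zero actives")
    stats = {}
    for f in PROPERTY_FIELDS:
        xs = np.array([getattr(p, f) for p in actives_props], dtype=float)
        stats[f] = PropertyStats(min=float(xs.min()), max=float(xs.max()), mean=float(xs.mean()), sd=float(xs.std()))
    return PropertyWindow(stats=stats)


def filter_pool(
    pool: list[tuple[Molecule, PropertyVector]],
    window: PropertyWindow,
    mode: str = "minmax",
    k: float = 2.0,
) -> tuple[list[tuple[Molecule, PropertyVector]], dict[str, int]]:
    """Keep pool records inside the window; report per-property rejections."""
    if mode not in ("minmax", "mean_sd"):
        raise ConfigError(f"unknown filter mode {mode!r}")
    kept = []
    rejections = {f: 0 for f in PROPERTY_FIELDS}
    for mol, props in pool:
        bad = window.violations(props, mode=mode, k=k)
        if bad:
            for f in bad:
                rejections[f] += 1
        else:
            kept.append((mol, props))
    return kept, rejections


def exclude_actives(
    subset: list[Molecule], actives: list[Molecule], extra_known: list[Molecule] | None = None
) -> list[Molecule]:
    """Drop records whose salt-stripped canonical key matches any known active."""
    known = {m.canonical_key() for m in actives}
    if extra_known:
        known |= {m.canonical_key() for m in extra_known}
    kept = [m for m in subset if m.canonical_key() not in known]
    removed = len(subset) - len(kept)
    if removed:
        log.warning("excluded %d records matching known actives", removed)
    if not kept:
        log.warning("actives exclusion removed every candidate record")
    return kept


def _fingerprints(mols: list[Molecule]):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return [gen.GetFingerprint(m.mol) for m in mols]


def diversity_select(
    subset: list[Molecule],
    n_target: int = DEFAULT_N_TARGET,
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
    seed: int = 7,
) -> DecoySet:
    """Sphere-exclusion (leader) clustering; one representative per cluster.

    Records are visited in input order; a record starts a new cluster when
    its Tanimoto similarity to every existing leader is below the
    threshold. If more clusters exist than ``n_target``, representatives
    are subsampled deterministically by seed; if fewer, all are returned
    with a warning.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    fps = _fingerprints(subset)
    leaders: list[int] = []
    for i, fp in enumerate(fps):
        if all(DataStructs.TanimotoSimilarity(fp, fps[j]) < threshold for j in leaders):
            leaders.append(i)
    reps = [subset[i] for i in leaders]
    subsampled = False
    if len(reps) > n_target:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(reps), size=n_target, replace=False))
        reps = [reps[i] for i in pick]
        subsampled = True
    elif len(reps) < n_target:
        log.warning("only %d diverse clusters available (requested %d)", len(reps), n_target)
    return DecoySet(
        records=reps,
        provenance={
            "pool_size": len(subset),
            "n_clusters": len(leaders),
            "n_target": n_target,
            "threshold": threshold,
            "seed": seed,
            "subsampled": subsampled,
        },
    )


def generate_decoys(
    actives: list[Molecule],
    pool: list[Molecule],
    n_target: int = DEFAULT_N_TARGET,
    mode: str = "minmax",
    k: float = 2.0,
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
    seed: int = 7,
    extra_known: list[Molecule] | None = None,
) -> DecoySet:
    """Full decoy pipeline: window -> filter -> exclude actives -> diversify.

    The output invariants (window membership, no canonical-key overlap
    with the actives) are re-asserted on every returned record rather
    than assumed from construction.
    """
    actives_props = [compute_properties(m) for m in actives]
    window = compute_window(actives_props)
    pool_props = [(m, compute_properties(m)) for m in pool]
    kept, rejections = filter_pool(pool_props, window, mode=mode, k=k)
    survivors = exclude_actives([m for m, _ in kept], actives, extra_known)
    decoys = diversity_select(survivors, n_target=n_target, threshold=threshold, seed=seed)

    known = {m.canonical_key() for m in actives} | {m.canonical_key() for m in (extra_known or [])}
    for rec in decoys.records:
        assert rec.canonical_key() not in known, f"decoy {rec.record_id} collides with a known active"
        assert window.contains(compute_properties(rec), mode=mode, k=k), (
            f"decoy {rec.record_id} escaped the property window"
        )
    decoys.provenance.update(
        {
            "initial_pool": len(pool),
            "after_property_filter": len(kept),
            "after_actives_exclusion": len(survivors),
            "property_rejections": rejections,
            "mode": mode,
            "k": k,
        }
    )
    return decoys
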