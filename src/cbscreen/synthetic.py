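"""Synthetic benchmarks: every input the pipeline needs, with known truth.

Three generators stand in for the data a screening campaign would buy or
measure:

* **feature benchmarks** — abstract feature clouds: actives carry the
  model's feature geometry (optionally jittered, plus distractor
  features, randomly rigid-transformed); decoys share the actives'
  kind-count distribution but have randomized geometry, rejection-sampled
  so they do not embed the model. These decouple matcher correctness from
  conformer-generator behavior.
* **molecular benchmarks** — real small molecules made by deterministic
  substituent decoration of template SMILES, for end-to-end tests of
  structure IO -> features -> screening.
* **assay curves** — logistic polymerization time courses whose amplitude
  is scaled by a dose–response factor with known IC50 and slope, plus
  Gaussian noise.

Everything is deterministic per seed, and planted-active embeddability is
re-verified after generation by a direct known-correspondence geometric
check rather than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import Molecule, PropertyVector, compute_properties
from .errors import CbscreenError
from .features import DEFAULT_RADII, FEATURE_KINDS, Feature, FeatureSet
from .geometry import apply_transform, kabsch, random_rotation
from .model import PharmacophoreModel
from .bioassay import KineticTrace
from .screening import DEFAULT_SETTINGS, MatchSettings, match_featureset

#: default feature count of generated benchmark models; enough geometric
#: constraint that random decoy geometry rarely embeds by accident
DEFAULT_MODEL_FEATURES = 5
#: spatial extent (Å) of generated models and decoy clouds
DEFAULT_EXTENT = 8.0
#: distractor features added per active, drawn uniformly from this range
DISTRACTOR_RANGE = (0, 3)


@dataclass
class SyntheticBenchmark:
    """A planted-model screening benchmark with complete truth labels."""

    model: PharmacophoreModel
    actives: list[FeatureSet]
    decoys: list[FeatureSet]
    labels: dict[str, bool]
    seed: int
    noise_sd: float

    @property
    def library(self) -> list[FeatureSet]:
        return list(self.actives) + list(self.decoys)

    def active_ids(self) -> set[str]:
        return {fs.record_id for fs in self.actives}

    def decoy_ids(self) -> set[str]:
        return {fs.record_id for fs in self.decoys}

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "actives": [fs.to_dict() for fs in self.actives],
            "decoys": [fs.to_dict() for fs in self.decoys],
            "labels": dict(self.labels),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "SyntheticBenchmark":
        d = json.loads(Path(path).read_text())
        return cls(
            model=PharmacophoreModel.from_dict(d["model"]),
            actives=[FeatureSet.from_dict(f) for f in d["actives"]],
            decoys=[FeatureSet.from_dict(f) for f in d["decoys"]],
            labels=d["labels"],
            seed=int(d["seed"]),
            noise_sd=float(d["noise_sd"]),
        )


def make_random_model(
    n_features: int = DEFAULT_MODEL_FEATURES,
    seed: int = 0,
    extent: float = DEFAULT_EXTENT,
    min_separation: float = 2.5,
    radius: float | None = None,
    name: str = "synthetic-model",
) -> PharmacophoreModel:
    """A random pharmacophore: typed features scattered in a cube.

    Anchors keep at least ``min_separation`` Å apart so tolerance spheres
    do not degenerate into one blob.
    """
    rng = np.random.default_rng(seed)
    anchors: list[np.ndarray] = []
    while len(anchors) < n_features:
        cand = rng.uniform(-extent / 2, extent / 2, size=3)
        if all(np.linalg.norm(cand - a) >= min_separation for a in anchors):
            anchors.append(cand)
    kinds = [FEATURE_KINDS[rng.integers(len(FEATURE_KINDS))] for _ in range(n_features)]
    features = [
        Feature(kind=k, anchor=a, radius=radius if radius is not None else DEFAULT_RADII[k])
        for k, a in zip(kinds, anchors)
    ]
    return PharmacophoreModel(name=name, features=features, provenance=[f"synthetic:seed={seed}"])


def planted_embeds(model: PharmacophoreModel, fs: FeatureSet, planted: list[int]) -> bool:
    """Direct geometric check that the planted correspondence still embeds.

    Independent of the clique matcher: superposes the *known* planted
    feature indices onto the model and tests every tolerance sphere.
    """
    P = np.array([fs.features[i].anchor for i in planted])
    Q = model.anchors()
    R, t, _ = kabsch(P, Q)
    moved = apply_transform(R, t, P)
    return all(
        np.linalg.norm(moved[k] - mf.anchor) <= mf.radius + 1e-9 for k, mf in enumerate(model.features)
    )


def make_feature_benchmark(
    model: PharmacophoreModel,
    n_act: int = 50,
    n_dec: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    settings: MatchSettings = DEFAULT_SETTINGS,
    max_attempts: int = 200,
) -> SyntheticBenchmark:
    """Generate planted actives and rejection-sampled decoys for a model."""
    if not model.features:
        raise CbscreenError("benchmark generation needs a non-empty model")
    if noise_sd < 0:
        raise CbscreenError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    center = model.anchors().mean(axis=0)
    extent = max(2.0 * np.max(np.linalg.norm(model.anchors() - center, axis=1)), 4.0)
    kinds = model.kinds()

    actives: list[FeatureSet] = []
    for i in range(n_act):
        planted_feats = [
            Feature(kind=f.kind, anchor=f.anchor + rng.normal(0.0, noise_sd, size=3), radius=f.radius)
            for f in model.features
        ]
        n_extra = int(rng.integers(DISTRACTOR_RANGE[0], DISTRACTOR_RANGE[1] + 1))
        extras = [
            Feature(
                kind=FEATURE_KINDS[rng.integers(len(FEATURE_KINDS))],
                anchor=center + rng.uniform(-extent, extent, size=3),
                radius=DEFAULT_RADII["HC"],
            )
            for _ in range(n_extra)
        ]
        feats = planted_feats + extras
        R = random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        fs = FeatureSet(
            record_id=f"ACT{i:04d}",
            conformer_index=0,
            features=feats,
            coords=np.array([f.anchor for f in feats]),
        ).transformed(R, t)
        if noise_sd == 0.0 and not planted_embeds(model, fs, list(range(len(model.features)))):
            raise CbscreenError(f"noise-free active ACT{i:04d} failed the planted-embedding check")
        actives.append(fs)

    decoys: list[FeatureSet] = []
    for i in range(n_dec):
        for attempt in range(max_attempts):
            n_extra = int(rng.integers(DISTRACTOR_RANGE[0], DISTRACTOR_RANGE[1] + 1))
            dec_kinds = kinds + [FEATURE_KINDS[rng.integers(len(FEATURE_KINDS))] for _ in range(n_extra)]
            feats = [
                Feature(kind=k, anchor=rng.uniform(-extent, extent, size=3), radius=DEFAULT_RADII[k])
                for k in dec_kinds
            ]
            fs = FeatureSet(
                record_id=f"DEC{i:04d}",
                conformer_index=0,
                features=feats,
                coords=np.array([f.anchor for f in feats]),
            )
            if match_featureset(model, fs, settings) is None:
                decoys.append(fs)
                break
        else:
            raise CbscreenError(
                f"could not generate decoy {i} in {max_attempts} attempts; "
                "the model may be too permissive (few features or wide tolerances)"
            )

    labels = {fs.record_id: True for fs in actives}
    labels.update({fs.record_id: False for fs in decoys})
    return SyntheticBenchmark(
        model=model, actives=actives, decoys=decoys, labels=labels, seed=seed, noise_sd=noise_sd
    )


#: substituents used by the molecular decorator (atom label -> SMILES fragment)
DECORATION_SET = ("C", "O", "N", "F", "Cl")


def make_molecular_benchmark(
    templates: list[str],
    n_variants: int = 10,
    seed: int = 0,
    window=None,
    source: str = "synthetic",
) -> list[Molecule]:
    """Deterministic substituent decoration of template SMILES.

    Each variant replaces one hydrogen of a template with a small
    substituent; the templates themselves come first. Decorations that
    break valence are skipped. When ``window`` (a PropertyWindow) is
    given, only variants inside it are kept.
    """
    mols: list[Molecule] = []
    seen: set[str] = set()
    candidates: list[tuple[str, str]] = []  # (smiles, label)
    for ti, smi in enumerate(templates):
        base = Chem.MolFromSmiles(smi)
        if base is None:
            raise CbscreenError(f"unparsable template SMILES: {smi!r}")
        candidates.append((Chem.MolToSmiles(base), f"T{ti}"))
        for atom in base.GetAtoms():
            if atom.GetTotalNumHs() < 1:
                continue
            for sub in DECORATION_SET:
                rw = Chem.RWMol(base)
                new_idx = rw.AddAtom(Chem.Atom(sub))
                rw.AddBond(atom.GetIdx(), new_idx, Chem.BondType.SINGLE)
                try:
                    prod = rw.GetMol()
                    Chem.SanitizeMol(prod)
                except Exception:
                    continue
                candidates.append((Chem.MolToSmiles(prod), f"T{ti}_{atom.GetIdx()}{sub}"))
    rng = np.random.default_rng(seed)
    order = list(range(len(templates))) + sorted(
        range(len(templates), len(candidates)), key=lambda _: rng.random()
    )
    for idx in order:
        smi, label = candidates[idx]
        if smi in seen:
            continue
        seen.add(smi)
        mol = Molecule.from_smiles(smi, record_id=f"SYN{len(mols):04d}_{label}", source=source)
        if window is not None and not window.contains(compute_properties(mol)):
            continue
        mols.append(mol)
        if len(mols) >= n_variants:
            break
    return mols


@dataclass
class SyntheticAssay:
    """Noisy polymerization plate with known ground-truth potency."""

    true_ic50: float
    true_hill: float
    concentrations: list[float]
    traces: list[KineticTrace] = field(default_factory=list)  # includes the blank
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def blank(self) -> KineticTrace:
        return next(t for t in self.traces if t.concentration is None)

    @property
    def test_traces(self) -> list[KineticTrace]:
        return [t for t in self.traces if t.concentration is not None]


DEFAULT_CONCS = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)


def polymerization_fraction(conc: float, ic50: float, hill: float) -> float:
    """Fraction of blank amplitude remaining at a given inhibitor dose."""
    return 1.0 / (1.0 + (conc / ic50) ** hill)


def make_assay_curves(
    true_ic50: float,
    hill: float = 1.0,
    concs: tuple[float, ...] = DEFAULT_CONCS,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 60.0,
    dt: float = 0.5,
) -> SyntheticAssay:
    """Simulated plate: logistic blank, dose-scaled inhibited wells.

    The blank follows base + amp / (1 + exp(-(t - t0)/tau)); each
    inhibited trace scales the blank's amplitude-above-baseline by the
    dose–response fraction, so the noise-free % inhibition at any
    timepoint is exactly 100·(1 − fraction). Gaussian noise in AU is
    added per sample.
    """
    if true_ic50 <= 0:
        raise CbscreenError("true_ic50 must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    base, amp, t0, tau = 100.0, 1000.0, 15.0, 5.0
    blank_clean = base + amp / (1.0 + np.exp(-(times - t0) / tau))
    traces = [
        KineticTrace(
            times=times,
            signal=blank_clean + rng.normal(0.0, noise_sd, size=times.shape),
            label="blank",
            concentration=None,
        )
    ]
    for c in concs:
        frac = polymerization_fraction(c, true_ic50, hill)
        clean = blank_clean[0] + (blank_clean - blank_clean[0]) * frac
        traces.append(
            KineticTrace(
                times=times,
                signal=clean + rng.normal(0.0, noise_sd, size=times.shape),
                label=f"c={c:g}uM",
                concentration=float(c),
            )
        )
    return SyntheticAssay(
        true_ic50=float(true_ic50), true_hill=float(hill), concentrations=[float(c) for c in concs],
        traces=traces, noise_sd=float(noise_sd), seed=int(seed),
    )


def make_dose_response_data(
    true_ic50: float,
    hill: float = 1.0,
    concs: tuple[float, ...] = DEFAULT_CONCS,
    noise_sd_pp: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Response-level simulation: % polymerization with Gaussian noise.

    noise_sd_pp is the response noise in percentage points, the natural
    scale for recovery studies of the IC50 fitter.
    """
    rng = np.random.default_rng(seed)
    concs = np.asarray(concs, dtype=float)
    clean = 100.0 * np.array([polymerization_fraction(c, true_ic50, hill) for c in concs])
    return concs, clean + rng.normal(0.0, noise_sd_pp, size=concs.shape)


def write_plate_csv(assay: SyntheticAssay, path) -> None:
    """Long-format plate CSV (well,label,concentration_uM,time_min,signal)."""
    import pandas as pd

    rows = []
    for wi, trace in enumerate(assay.traces):
        for t, s in zip(trace.times, trace.signal):
            rows.append(
                {
                    "well": f"W{wi:02d}",
                    "label": trace.label,
                    "concentration_uM": "" if trace.concentration is None else trace.concentration,
                    "time_min": t,
                    "signal": s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
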