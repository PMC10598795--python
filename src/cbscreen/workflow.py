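"""End-to-end workflow: inputs -> screen -> evaluate -> consensus -> report.

A run is driven by one YAML config with explicit seeds, validated up
front (every offending field reported at once). Inputs are either a
synthetic feature benchmark generated on the fly or molecular libraries
plus model files. Every stage's output is persisted under the run
directory, and a manifest records config hash, versions, per-stage
counts and per-model metrics, so re-running the same config reproduces
the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioassay import fit_dose_response, percent_inhibition, read_plate_csv
from .chemio import embed_conformers, read_library
from .enrichment import (
    DatasetTotals,
    combine_models,
    compute_metrics,
    confusion_from_hits,
    metrics_frame,
)
from .errors import ValidationError
from .model import PharmacophoreModel
from .screening import MatchSettings, consensus_frame, consensus_summary, consensus_table, screen_library
from .synthetic import SyntheticBenchmark, make_feature_benchmark, make_random_model

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated workflow configuration; see ``from_yaml``."""

    seed: int
    output_dir: Path
    synthetic: dict | None = None
    library: dict | None = None
    model_paths: list[Path] = field(default_factory=list)
    screening: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError([f"config file not found: {path}"])
        data = yaml.safe_load(path.read_text()) or {}
        problems: list[str] = []
        if "seed" not in data:
            problems.append("seed: missing (seeds must be explicit)")
        if "output_dir" not in data:
            problems.append("output_dir: missing")
        synthetic = data.get("synthetic")
        library = data.get("library")
        if (synthetic is None) == (library is None):
            problems.append("exactly one of 'synthetic' or 'library' must be given")
        model_paths = [Path(p) for p in data.get("models", [])]
        for p in model_paths:
            if not p.exists():
                problems.append(f"models: file not found: {p}")
        if library is not None:
            for key in ("actives", "decoys"):
                if key not in library:
                    problems.append(f"library.{key}: missing")
                elif not Path(library[key]).exists():
                    problems.append(f"library.{key}: file not found: {library[key]}")
            if not model_paths:
                problems.append("models: at least one model file is required in library mode")
        assay = data.get("assay", {})
        if "plate_csv" in assay and not Path(assay["plate_csv"]).exists():
            problems.append(f"assay.plate_csv: file not found: {assay['plate_csv']}")
        if problems:
            raise ValidationError(problems)
        return cls(
            seed=int(data["seed"]),
            output_dir=Path(data["output_dir"]),
            synthetic=synthetic,
            library=library,
            model_paths=model_paths,
            screening=data.get("screening", {}),
            assay=assay,
            raw=data,
        )

    def settings(self) -> MatchSettings:
        return MatchSettings(**self.screening) if self.screening else MatchSettings()

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    versions: dict
    stage_counts: dict
    model_metrics: dict
    consensus: dict
    started: str
    finished: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _resolve_inputs(config: RunConfig):
    """Produce (actives, decoys, models) from either input mode."""
    models = [PharmacophoreModel.load(p) for p in config.model_paths]
    if config.synthetic is not None:
        spec = dict(config.synthetic)
        model_spec = spec.get("model", {})
        model = make_random_model(
            n_features=int(model_spec.get("n_features", 5)),
            seed=int(model_spec.get("seed", config.seed)),
        )
        bench = make_feature_benchmark(
            model,
            n_act=int(spec.get("n_actives", 30)),
            n_dec=int(spec.get("n_decoys", 100)),
            noise_sd=float(spec.get("noise_sd", 0.0)),
            seed=config.seed,
        )
        return bench.actives, bench.decoys, [model] + models, bench
    lib = config.library
    conf = lib.get("conformers", {})
    max_n = int(conf.get("max_n", 25))
    conf_seed = int(conf.get("seed", config.seed))
    actives = [embed_conformers(m, max_n=max_n, seed=conf_seed) for m in read_library(lib["actives"])]
    decoys = [embed_conformers(m, max_n=max_n, seed=conf_seed) for m in read_library(lib["decoys"])]
    return actives, decoys, models, None


def run_workflow(config: RunConfig) -> RunManifest:
    """Execute all stages; every intermediate is written to the run dir."""
    started = datetime.now(timezone.utc).isoformat()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    settings = config.settings()

    actives, decoys, models, bench = _resolve_inputs(config)
    if bench is not None:
        bench.model.save(out / "benchmark_model.json")
    library = list(actives) + list(decoys)
    active_ids = {a.record_id if hasattr(a, "record_id") else a.molecule.record_id for a in actives}
    decoy_ids = {d.record_id if hasattr(d, "record_id") else d.molecule.record_id for d in decoys}
    totals = DatasetTotals(n_actives=len(actives), n_decoys=len(decoys))

    hitlists = []
    named_reports = []
    model_metrics = {}
    for model in models:
        hl = screen_library(model, library, settings)
        hl.to_frame().to_csv(out / f"hits_{model.name}.csv", index=False)
        hitlists.append(hl)
        cm = confusion_from_hits(hl.record_ids, active_ids, decoy_ids)
        rep = compute_metrics(cm, totals)
        named_reports.append((model.name, cm, rep))
        model_metrics[model.name] = {**rep.rounded(2), "discard": rep.discard,
                                     "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
    combined_cm = combine_models(hitlists, active_ids, decoy_ids)
    combined_rep = compute_metrics(combined_cm, totals)
    named_reports.append(("Combined", combined_cm, combined_rep))
    model_metrics["Combined"] = {**combined_rep.rounded(2), "discard": combined_rep.discard,
                                 "tp": combined_cm.tp, "fp": combined_cm.fp,
                                 "tn": combined_cm.tn, "fn": combined_cm.fn}
    metrics_frame(named_reports, totals).to_csv(out / "metrics.csv", index=False)

    rows = consensus_table(hitlists)
    consensus_frame(rows).to_csv(out / "consensus.csv", index=False)
    consensus = consensus_summary(rows, library_size=len(library))

    stage_counts = {
        "n_actives": len(actives),
        "n_decoys": len(decoys),
        "library_size": len(library),
        "n_models": len(models),
        "hits_per_model": {hl.model: len(hl.hits) for hl in hitlists},
    }

    if "plate_csv" in config.assay:
        traces, blank = read_plate_csv(config.assay["plate_csv"])
        t_eval = float(config.assay.get("t_eval", 41.5))
        results = [percent_inhibition(tr, blank, t_eval=t_eval) for tr in traces]
        rows_a = [
            {"label": r.label, "concentration_uM": r.concentration,
             "pct_inhibition": r.pct_inhibition, "band": r.band}
            for r in results
        ]
        pd.DataFrame(rows_a).to_csv(out / "inhibition.csv", index=False)
        dosed = [r for r in results if r.concentration is not None]
        if len({r.concentration for r in dosed}) >= 4:
            fit = fit_dose_response(
                np.array([r.concentration for r in dosed]),
                np.array([100.0 - r.pct_inhibition for r in dosed]),
            )
            pd.DataFrame(
                [{"ic50_uM": fit.ic50, "hill": fit.hill, "ci95_low": fit.ci95[0],
                  "ci95_high": fit.ci95[1], "converged": fit.converged}]
            ).to_csv(out / "dose_response.csv", index=False)
            stage_counts["assay_fit_converged"] = fit.converged

    # manifest self-consistency: hits never exceed the library
    for hl in hitlists:
        assert len(hl.hits) <= len(library)
    assert consensus["single"] + consensus["double"] + consensus["triple_plus"] == consensus["total"]

    manifest = RunManifest(
        config_hash=config.config_hash(),
        versions={"cbscreen": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        stage_counts=stage_counts,
        model_metrics=model_metrics,
        consensus=consensus,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.save(out / "manifest.json")
    return manifest
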