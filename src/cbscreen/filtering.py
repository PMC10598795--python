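"""Post-screening hit prioritization.

Virtual hits are triaged before purchase: rule-of-five properties,
PAINS/Brenk substructure alerts (RDKit's curated filter catalogs, or
custom pattern files such as a reactive-group list), then ranked by
consensus overlap and fit score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import FilterCatalog

import logging

from .chemio import Molecule, PropertyVector
from .errors import CatalogError, CbscreenError
from .screening import ConsensusRow

log = logging.getLogger(__name__)

LIPINSKI_LIMITS = {"mw": 500.0, "logp": 5.0, "n_hbd": 5, "n_hba": 10}

_BUILTIN = {
    "pains": FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS,
    "brenk": FilterCatalog.FilterCatalogParams.FilterCatalogs.BRENK,
}


@dataclass
class AlertCatalog:
    """A named set of substructure alerts.

    Either one of RDKit's curated catalogs (``pains``, ``brenk``) or a
    custom text file with one ``SMARTS<whitespace>label`` entry per line
    (e.g. a reactive/unstable functional-group list).
    """

    name: str
    patterns: list[tuple[str, str]] = field(default_factory=list)  # (smarts, label) for custom
    _queries: list = field(default_factory=list, repr=False)
    _rdkit_catalog: object | None = field(default=None, repr=False)

    @classmethod
    def builtin(cls, name: str) -> "AlertCatalog":
        key = name.lower()
        if key not in _BUILTIN:
            raise CatalogError(f"unknown builtin catalog {name!r}; available: {sorted(_BUILTIN)}")
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(_BUILTIN[key])
        return cls(name=key, _rdkit_catalog=FilterCatalog.FilterCatalog(params))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "AlertCatalog":
        path = Path(path)
        if not path.exists():
            raise CatalogError(f"catalog file not found: {path}")
        patterns: list[tuple[str, str]] = []
        queries = []
        labels = set()
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smarts = parts[0]
            label = parts[1].strip() if len(parts) > 1 else f"pattern_{i}"
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise CatalogError(f"unparsable SMARTS on line {i + 1} of {path}: {smarts!r}")
            if label in labels:
                raise CatalogError(f"duplicate alert label {label!r} in {path}")
            labels.add(label)
            patterns.append((smarts, label))
            queries.append(q)
        return cls(name=name or path.stem, patterns=patterns, _queries=queries)

    def matches(self, mol: Chem.Mol) -> list[str]:
        if self._rdkit_catalog is not None:
            hits = self._rdkit_catalog.GetMatches(mol)
            return sorted(h.GetDescription() for h in hits)
        return [label for (_, label), q in zip(self.patterns, self._queries) if mol.HasSubstructMatch(q)]


def load_catalogs(names_or_paths: list[str]) -> list[AlertCatalog]:
    out = []
    for item in names_or_paths:
        if item.lower() in _BUILTIN:
            out.append(AlertCatalog.builtin(item))
        else:
            out.append(AlertCatalog.from_file(item))
    return out


def lipinski_check(props: PropertyVector, limits: dict = LIPINSKI_LIMITS) -> tuple[int, list[str]]:
    """Rule-of-five violations: MW<=500, logP<=5, HBD<=5, HBA<=10.

    Boundary values pass ("no more than" semantics).
    """
    violated = [rule for rule, limit in limits.items() if getattr(props, rule) > limit]
    return len(violated), violated


def alert_screen(mol: Molecule | Chem.Mol, catalog: AlertCatalog) -> list[str]:
    """All alert labels whose substructure pattern matches the molecule."""
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    return catalog.matches(rdmol)


@dataclass
class FilterReport:
    record_id: str
    lipinski_violations: int
    violated_rules: list[str]
    alerts: dict[str, list[str]]  # catalog name -> labels
    passed: bool

    @property
    def n_alerts(self) -> int:
        return sum(len(v) for v in self.alerts.values())


def filter_record(
    record_id: str,
    props: PropertyVector,
    mol: Molecule,
    catalogs: list[AlertCatalog] = (),
    max_violations: int = 1,
) -> FilterReport:
    """One record's full triage: rule-of-five plus every alert catalog."""
    n, rules = lipinski_check(props)
    alerts = {cat.name: alert_screen(mol, cat) for cat in catalogs}
    passed = n <= max_violations and all(not v for v in alerts.values())
    return FilterReport(
        record_id=record_id, lipinski_violations=n, violated_rules=rules, alerts=alerts, passed=passed
    )


@dataclass
class RankedHit:
    record_id: str
    n_models: int
    best_score: float
    passed: bool
    rank: int


def rank_candidates(
    rows: list[ConsensusRow], reports: list[FilterReport], demote_failed: bool = False
) -> list[RankedHit]:
    """Rank consensus rows by (models matched, fit score, record id).

    Records failing the filters are excluded, or demoted below all
    passing records when ``demote_failed``; ranks are unique and 1-based.
    """
    by_id = {r.record_id: r for r in reports}
    missing = [r.record_id for r in rows if r.record_id not in by_id]
    if missing:
        raise CbscreenError(f"filter reports missing for records: {sorted(missing)[:5]}")
    survivors = []
    for row in rows:
        rep = by_id[row.record_id]
        if not rep.passed and not demote_failed:
            continue
        survivors.append((row, rep))
    if not survivors:
        log.warning("every candidate failed the hit filters")
    survivors.sort(key=lambda t: (not t[1].passed, -t[0].n_models, -t[0].best_score, t[0].record_id))
    return [
        RankedHit(
            record_id=row.record_id,
            n_models=row.n_models,
            best_score=row.best_score,
            passed=rep.passed,
            rank=i + 1,
        )
        for i, (row, rep) in enumerate(survivors)
    ]
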