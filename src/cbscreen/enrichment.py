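"""Confusion matrices and virtual-screening enrichment metrics.

For a screen of A actives spiked into a database of D = A + decoys
compounds, a model retrieving tp actives and fp decoys scores:

* sensitivity = tp / (tp + fn)
* specificity = tn / (tn + fp)
* accuracy    = (tp + tn) / D
* yield of actives (YoA, precision) = tp / (tp + fp)
* enrichment factor EF = YoA / (A / D)

EF uses the actives fraction of the *full* screened set as its
denominator, so EF = YoA · D / A wherever YoA is defined. Models with
EF below 4 are flagged for discard. YoA and EF are reported as missing
(None), not zero, when the model retrieves nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import CbscreenError

#: models below this enrichment factor are flagged for discard
EF_DISCARD_THRESHOLD = 4.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13), as screening reports print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")


@dataclass(frozen=True)
class DatasetTotals:
    """Screened-set composition: A actives, D = A + decoys database size."""

    n_actives: int
    n_decoys: int

    def __post_init__(self):
        if self.n_actives < 1:
            raise ValueError("at least one active is required")
        if self.n_decoys < 0:
            raise ValueError("decoy count must be non-negative")

    @property
    def n_database(self) -> int:
        return self.n_actives + self.n_decoys


@dataclass(frozen=True)
class MetricsReport:
    """The five screening-quality metrics plus the EF discard flag.

    ``yoa`` and ``ef`` are None when the model retrieved nothing
    (tp + fp = 0); a model with undefined or sub-threshold EF is flagged
    for discard.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    yoa: float | None
    ef: float | None
    discard: bool

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k in ("accuracy", "sensitivity", "specificity", "yoa", "ef"):
            v = getattr(self, k)
            out[k] = None if v is None else round_half_up(v, ndigits)
        return out


def confusion_from_hits(hits: set, active_ids: set, decoy_ids: set) -> ConfusionMatrix:
    """Tabulate a hit set against the actives/decoys truth partition."""
    active_ids = set(active_ids)
    decoy_ids = set(decoy_ids)
    if active_ids & decoy_ids:
        raise CbscreenError("active and decoy id sets overlap")
    hits = set(hits)
    stray = hits - active_ids - decoy_ids
    if stray:
        raise CbscreenError(f"hits outside the screened library: {sorted(stray)[:5]}")
    tp = len(hits & active_ids)
    fp = len(hits & decoy_ids)
    return ConfusionMatrix(tp=tp, fp=fp, tn=len(decoy_ids) - fp, fn=len(active_ids) - tp)


def compute_metrics(cm: ConfusionMatrix, totals: DatasetTotals) -> MetricsReport:
    """All five metrics for one confusion matrix; see the module docstring."""
    if cm.tp + cm.fn != totals.n_actives or cm.fp + cm.tn != totals.n_decoys:
        raise CbscreenError(
            f"confusion matrix {cm} inconsistent with totals "
            f"(A={totals.n_actives}, decoys={totals.n_decoys})"
        )
    sens = cm.tp / totals.n_actives
    spec = cm.tn / totals.n_decoys if totals.n_decoys else 1.0
    acc = (cm.tp + cm.tn) / totals.n_database
    retrieved = cm.tp + cm.fp
    if retrieved == 0:
        yoa = ef = None
        discard = True
    else:
        yoa = cm.tp / retrieved
        ef = yoa * totals.n_database / totals.n_actives
        discard = ef < EF_DISCARD_THRESHOLD
    return MetricsReport(
        sensitivity=sens, specificity=spec, accuracy=acc, yoa=yoa, ef=ef, discard=discard
    )


def combine_models(hitlists: list, active_ids: set, decoy_ids: set) -> ConfusionMatrix:
    """Union semantics: a record is positive if retrieved by any model."""
    library = len(set(active_ids)) + len(set(decoy_ids))
    for hl in hitlists:
        if hl.library_size != library:
            raise CbscreenError(
                f"hit list for model {hl.model!r} covers {hl.library_size} records, "
                f"but the truth sets cover {library}"
            )
    union: set = set()
    for hl in hitlists:
        union |= hl.record_ids
    return confusion_from_hits(union, active_ids, decoy_ids)


def prospective_hit_rate(n_tested: int, n_active: int) -> float:
    """Percentage of experimentally tested virtual hits confirmed active."""
    if n_tested < 1:
        raise CbscreenError("at least one tested compound is required")
    if not 0 <= n_active <= n_tested:
        raise CbscreenError(f"active count {n_active} outside [0, {n_tested}]")
    return round_half_up(100.0 * n_active / n_tested, 1)


def metrics_frame(named_reports: list[tuple[str, ConfusionMatrix, MetricsReport]], totals: DatasetTotals) -> pd.DataFrame:
    """Report table in the column order screening campaigns conventionally print."""
    rows = []
    for name, cm, rep in named_reports:
        r = rep.rounded(2)
        rows.append(
            {
                "Model": name,
                "Actives": cm.tp,
                "Decoy": cm.fp,
                "TPs": cm.tp,
                "FPs": cm.fp,
                "TNs": cm.tn,
                "FNs": cm.fn,
                "Accuracy": r["accuracy"],
                "Sensitivity": r["sensitivity"],
                "Specificity": r["specificity"],
                "YoA": r["yoa"],
                "EF": r["ef"],
            }
        )
    return pd.DataFrame(rows)
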