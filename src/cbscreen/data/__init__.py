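"""Packaged reference tables from a 16-model colchicine-site screening campaign.

The campaign screened 95 known β-tubulin colchicine-site inhibitors
spiked into 4901 property-matched decoys (theoretical validation), three
commercial/curated libraries (single-hit accounting), and followed up 41
purchased virtual hits in a tubulin polymerization assay (prospective
performance and inhibition screen). These tables serve as regression
fixtures for the enrichment and assay-classification arithmetic.
"""

from importlib import resources

import pandas as pd

#: actives / database size of the theoretical-validation screen
N_ACTIVES = 95
N_DECOYS = 4901

#: library sizes of the three screened databases
LIBRARY_SIZES = {"specs": 208761, "specs_np": 736, "phytchem": 735}

#: printed single-hit totals per database: (count, percent of library)
SINGLE_HIT_TOTALS = {"specs": (10852, 5.20), "specs_np": (40, 5.43), "phytchem": (48, 6.53)}

#: overall prospective outcome: tested hits, confirmed actives, hit rate (%)
PROSPECTIVE_OVERALL = (41, 11, 26.8)


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def theoretical_validation() -> pd.DataFrame:
    """Per-model confusion matrices and printed 2-dp quality metrics."""
    return _load("theoretical_validation.csv")


def single_hits() -> pd.DataFrame:
    """Per-model single-hit counts against the three screened libraries."""
    return _load("single_hits.csv")


def prospective_performance() -> pd.DataFrame:
    """Per-model tested/active counts and printed hit rates (%)."""
    return _load("prospective_performance.csv")


def inhibition_screen() -> pd.DataFrame:
    """Percent-inhibition outcomes of the assayed compounds (mean, SD)."""
    return _load("inhibition_screen.csv")
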