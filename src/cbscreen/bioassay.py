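"""Tubulin polymerization assay analysis.

Kinetic traces (fluorescence vs time) are normalized against the
uninhibited blank at a fixed evaluation timepoint:

    pct_inhibition = 100 * (1 - (trace(t) - trace(0)) / (blank(t) - blank(0)))

with t = 41.5 min by default and linear interpolation between plate-reader
samples. Percent inhibition maps onto activity bands (inactive / weak /
moderate / high at 25/50/75% by default), and dose–response series are
fitted with the variable-slope log-logistic model

    y(c) = 100 / (1 + 10^((log10 c - log10 IC50) * h))

where y is % polymerization (of blank) and h > 0 for an inhibitor. The
95% CI comes from the asymptotic covariance on the log10 IC50 scale
(t quantile, n - 2 degrees of freedom), which reproduces the asymmetric
intervals assay software reports; a pairs bootstrap stands in when the
covariance is unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .enrichment import prospective_hit_rate
from .errors import AssayError

log = logging.getLogger(__name__)

T_EVAL_DEFAULT = 41.5
#: band edges in % inhibition: below first -> inactive, ... , above last -> high
BAND_EDGES = (25.0, 50.0, 75.0)
BAND_NAMES = ("inactive", "weak", "moderate", "high")


@dataclass
class KineticTrace:
    """One well's polymerization time course.

    times in minutes (strictly increasing), signal in fluorescence AU;
    ``concentration`` is the test concentration in μM, or None for the
    blank (vehicle) well.
    """

    times: np.ndarray
    signal: np.ndarray
    label: str
    concentration: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise AssayError(f"trace {self.label!r}: times and signal must be equal-length 1D")
        if len(self.times) < 2:
            raise AssayError(f"trace {self.label!r}: need at least two timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise AssayError(f"trace {self.label!r}: times must be strictly increasing")

    def value_at(self, t: float) -> float:
        if not self.times[0] <= t <= self.times[-1]:
            raise AssayError(f"trace {self.label!r} does not cover t={t} min")
        return float(np.interp(t, self.times, self.signal))

    def amplitude_at(self, t: float, baseline: str = "first") -> float:
        base = self.signal[0] if baseline == "first" else 0.0
        return self.value_at(t) - base


@dataclass
class InhibitionResult:
    label: str
    concentration: float | None
    pct_inhibition: float
    band: str


@dataclass
class DoseResponseFit:
    """Variable-slope IC50 fit results."""

    ic50: float
    hill: float
    ci95: tuple[float, float]
    converged: bool
    residual_norm: float
    n_points: int
    message: str = ""


def assign_band(pct: float, edges: tuple[float, ...] = BAND_EDGES, names: tuple[str, ...] = BAND_NAMES) -> str:
    """Monotone band assignment from % inhibition."""
    idx = int(np.searchsorted(np.asarray(edges, dtype=float), pct, side="right"))
    return names[idx]


def percent_inhibition(
    trace: KineticTrace,
    blank: KineticTrace,
    t_eval: float = T_EVAL_DEFAULT,
    baseline: str = "first",
    edges: tuple[float, ...] = BAND_EDGES,
) -> InhibitionResult:
    """% inhibition of the blank's polymerization amplitude at ``t_eval``.

    ``baseline='first'`` subtracts each trace's initial signal (the
    default); ``baseline='raw'`` compares raw endpoint signals.
    """
    amp_blank = blank.amplitude_at(t_eval, baseline)
    if amp_blank <= 0:
        raise AssayError(
            f"blank {blank.label!r} shows no polymerization at t={t_eval} min (amplitude {amp_blank:.3g})"
        )
    amp = trace.amplitude_at(t_eval, baseline)
    pct = 100.0 * (1.0 - amp / amp_blank)
    return InhibitionResult(
        label=trace.label, concentration=trace.concentration, pct_inhibition=pct, band=assign_band(pct, edges)
    )


def dose_response(logc: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    """% polymerization under the variable-slope model (h > 0 inhibits)."""
    return 100.0 / (1.0 + 10.0 ** ((logc - log_ic50) * hill))


def fit_dose_response(
    concs: np.ndarray,
    responses: np.ndarray,
    bootstrap_seed: int = 0,
) -> DoseResponseFit:
    """Fit IC50 and slope to (% polymerization vs concentration) data.

    Degenerate inputs (no usable dynamic range, non-convergence) return
    ``converged=False`` with a diagnostic message instead of raising.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(concs)) < 4:
        raise AssayError("at least four distinct concentrations are required")
    if np.any(concs <= 0):
        raise AssayError("concentrations must be positive")
    logc = np.log10(concs)

    span = responses.max() - responses.min()
    if span < 10.0:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), ci95=(float("nan"), float("nan")),
            converged=False, residual_norm=float("nan"), n_points=len(concs),
            message=f"no dose response: dynamic range {span:.1f} percentage points",
        )

    # initial log IC50: concentration closest to the half-maximal response
    p0 = (float(logc[np.argmin(np.abs(responses - 50.0))]), 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            dose_response, logc, responses, p0=p0,
            bounds=([logc.min() - 3.0, 0.05], [logc.max() + 3.0, 10.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), ci95=(float("nan"), float("nan")),
            converged=False, residual_norm=float("nan"), n_points=len(concs),
            message=f"fit failed: {exc}",
        )
    log_ic50, hill = popt
    resid = responses - dose_response(logc, *popt)
    residual_norm = float(np.linalg.norm(resid))
    dof = max(len(concs) - 2, 1)
    tq = stats.t.ppf(0.975, dof)
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    if np.isfinite(se):
        lo, hi = 10.0 ** (log_ic50 - tq * se), 10.0 ** (log_ic50 + tq * se)
        message = "asymptotic CI"
    else:
        lo, hi = _bootstrap_ci(logc, responses, p0, seed=bootstrap_seed)
        message = "bootstrap CI (ill-conditioned covariance)"
    return DoseResponseFit(
        ic50=float(10.0**log_ic50), hill=float(hill), ci95=(float(lo), float(hi)),
        converged=True, residual_norm=residual_norm, n_points=len(concs), message=message,
    )


def _bootstrap_ci(logc, responses, p0, seed: int, n_boot: int = 199) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    estimates = []
    n = len(logc)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(logc[idx])) < 4:
            continue
        try:
            popt, _ = optimize.curve_fit(
                dose_response, logc[idx], responses[idx], p0=p0,
                bounds=([logc.min() - 3.0, 0.05], [logc.max() + 3.0, 10.0]), maxfev=5000,
            )
            estimates.append(popt[0])
        except (RuntimeError, ValueError):
            continue
    if len(estimates) < 20:
        return float("nan"), float("nan")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(10.0**lo), float(10.0**hi)


@dataclass
class ScreenSummary:
    """Active/inactive discrimination screen outcome."""

    results: list[InhibitionResult]
    active_cut: float
    calls: list[bool] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def n_active(self) -> int:
        return sum(self.calls)

    @property
    def hit_rate(self) -> float:
        return prospective_hit_rate(self.n_tested, self.n_active)


def classify_screen(results: list[InhibitionResult], active_cut: float = 25.0) -> ScreenSummary:
    """Call each compound active/inactive at the cut; feeds the hit rate."""
    calls = [r.pct_inhibition >= active_cut for r in results]
    return ScreenSummary(results=results, active_cut=active_cut, calls=calls)


def read_plate_csv(path) -> tuple[list[KineticTrace], KineticTrace]:
    """Read long-format plate data (well,label,concentration_uM,time_min,signal).

    Returns (test traces, blank trace); the blank is the row group with an
    empty/NaN concentration or the label 'blank'.
    """
    df = pd.read_csv(path)
    required = {"label", "concentration_uM", "time_min", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise AssayError(f"plate CSV missing columns: {sorted(missing)}")
    traces = []
    blank = None
    group_cols = ["well", "label"] if "well" in df.columns else ["label"]
    for key, grp in df.groupby(group_cols, sort=True):
        grp = grp.sort_values("time_min")
        label = key[-1] if isinstance(key, tuple) else key
        conc = grp["concentration_uM"].iloc[0]
        is_blank = pd.isna(conc) or str(label).lower() == "blank"
        trace = KineticTrace(
            times=grp["time_min"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            label=str(label),
            concentration=None if is_blank else float(conc),
        )
        if is_blank:
            blank = trace
        else:
            traces.append(trace)
    if blank is None:
        raise AssayError("plate CSV contains no blank trace")
    return traces, blank


def plot_dose_response(fit: DoseResponseFit, concs, responses, ax=None):
    """Concentration–response plot with the fitted curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    concs = np.asarray(concs, dtype=float)
    ax.semilogx(concs, responses, "o", label="data")
    if fit.converged:
        grid = np.logspace(np.log10(concs.min()), np.log10(concs.max()), 200)
        ax.semilogx(grid, dose_response(np.log10(grid), np.log10(fit.ic50), fit.hill),
                    "-", label=f"IC50 = {fit.ic50:.2g} uM")
    ax.set_xlabel("concentration (uM)")
    ax.set_ylabel("% polymerization")
    ax.legend()
    return ax
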