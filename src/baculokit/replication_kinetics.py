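"""Absolute qPCR quantification and viral replication kinetics.

A standard curve (ordinary least squares of Ct on log10 copy number) converts
cycle-threshold values to absolute copy numbers; viral copies are normalised
against host actin-gene copies to give viral copies per 1e5 actin copies.
The normalised trajectory is segmented into the canonical infection phases -
decreasing, latent, exponential, stationary - from per-interval log2 growth
rates, and fold change over a window is summarised as doublings
(log2 fold) and doubling time (window length / doublings).

Replicate Ct values are averaged on the Ct scale before any conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import BaculokitError, FitError

PHASES = ("decreasing", "latent", "exponential", "stationary")


@dataclass(frozen=True)
class StandardCurve:
    slope: float        # Ct per log10(copies); negative for a real dilution
    intercept: float    # Ct at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class NormalizedSeries:
    times: np.ndarray           # hours post infection
    values: np.ndarray          # viral copies per `per` host actin copies
    per: float = 1e5
    phase_labels: list[str] | None = None   # one label per interval

    def value_at(self, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise BaculokitError(f"time point {t} not in series")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class KineticsSummary:
    window: tuple[float, float]
    fold_change: float
    doublings: float
    doubling_time: float | None
    rounded_doublings: int
    rounded_doubling_time: float | None


def _ct_means(ct) -> np.ndarray:
    arr = np.asarray(ct, dtype=float)
    if arr.ndim == 2:
        arr = arr.mean(axis=1)
    return arr


def fit_standard_curve(log10_copies, ct) -> StandardCurve:
    """OLS fit of mean Ct on log10 copy number.

    ``ct`` may be per-dilution means or a 2-D array of replicates (averaged
    on the Ct scale).  Requires at least three dilution points with
    non-degenerate copy numbers and a negative slope.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = _ct_means(ct)
    if x.size < 3:
        raise FitError("standard curve needs at least 3 dilution points")
    if x.size != y.size:
        raise FitError("copies and Ct lengths differ")
    if np.ptp(x) == 0:
        raise FitError("zero variance in copy numbers")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise FitError(f"non-negative slope {res.slope:.3g}: "
                       "not a valid dilution series")
    curve = StandardCurve(slope=float(res.slope),
                          intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2))
    if not 0.8 <= curve.efficiency <= 1.1:
        warnings.warn(f"amplification efficiency {curve.efficiency:.2f} "
                      "outside [0.8, 1.1]", stacklevel=2)
    return curve


def quantify(curve: StandardCurve, ct: float) -> float:
    """Absolute copies for one Ct value by inverting the standard curve."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def normalize(viral_copies, actin_copies, per: float = 1e5,
              times=None) -> NormalizedSeries:
    """Viral copies per ``per`` host actin copies, time point by time point."""
    v = np.asarray(viral_copies, dtype=float)
    a = np.asarray(actin_copies, dtype=float)
    if v.shape != a.shape:
        raise BaculokitError("viral and actin series differ in length")
    if np.any(a == 0):
        t_bad = (np.asarray(times)[a == 0] if times is not None
                 else np.flatnonzero(a == 0))
        raise BaculokitError(f"zero actin copies at {t_bad}")
    if times is None:
        times = np.arange(v.size, dtype=float)
    return NormalizedSeries(times=np.asarray(times, dtype=float),
                            values=v / a * per, per=per)


def annotate_phases(series: NormalizedSeries,
                    eps_log2_per_h: float = 0.05,
                    expo_log2_per_h: float = 0.5) -> NormalizedSeries:
    """Label each between-sample interval with an infection phase.

    Intervals with log2 rate below ``-eps`` are decreasing; at or above
    ``expo`` exponential; the remainder are latent before the first
    exponential interval and stationary after it.
    """
    t, v = series.times, series.values
    if t.size < 3:
        raise BaculokitError("phase annotation needs at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise BaculokitError("times must be strictly increasing")
    if np.any(v <= 0):
        raise BaculokitError("values must be positive")
    rates = np.diff(np.log2(v)) / np.diff(t)
    expo_idx = np.flatnonzero(rates >= expo_log2_per_h)
    first_expo = expo_idx[0] if expo_idx.size else rates.size
    labels = []
    for k, r in enumerate(rates):
        if r < -eps_log2_per_h:
            labels.append("decreasing")
        elif r >= expo_log2_per_h:
            labels.append("exponential")
        elif k < first_expo:
            labels.append("latent")
        else:
            labels.append("stationary")
    return replace(series, phase_labels=labels)


def kinetics_summary(series: NormalizedSeries,
                     window: tuple[float, float]) -> KineticsSummary:
    """Fold change, doublings and doubling time across a time window."""
    t1, t2 = window
    v1, v2 = series.value_at(t1), series.value_at(t2)
    if v1 == 0:
        raise BaculokitError(f"zero value at window start t={t1}")
    fold = v2 / v1
    doublings = float(np.log2(fold))
    dt = (t2 - t1) / doublings if doublings != 0 else None
    rounded = int(round(doublings))
    rdt = (t2 - t1) / rounded if rounded != 0 else None
    return KineticsSummary(window=(t1, t2), fold_change=float(fold),
                           doublings=doublings, doubling_time=dt,
                           rounded_doublings=rounded,
                           rounded_doubling_time=rdt)


def quantify_series(curve: StandardCurve, ct_table) -> np.ndarray:
    """Copy numbers for an array of (replicate-averaged) Ct values."""
    cts = _ct_means(ct_table)
    return np.array([quantify(curve, c) for c in cts])


def analyze_experiment(standards, samples, per: float = 1e5,
                       viral_target: str = "rr2b",
                       actin_target: str = "actin",
                       eps_log2_per_h: float = 0.05,
                       expo_log2_per_h: float = 0.5) -> dict:
    """Full pipeline over tidy standards/samples tables.

    ``standards``: DataFrame with columns target, log10_copies, ct_1..ct_n.
    ``samples``: DataFrame with columns time_h, target, ct_1..ct_n.
    Returns the fitted curves, the normalised phase-labelled series and a
    12-48 h style kinetics summary over the detected exponential phase.
    """
    ct_cols = [c for c in standards.columns if c.startswith("ct_")]
    curves = {}
    for target, grp in standards.groupby("target"):
        curves[target] = fit_standard_curve(
            grp["log10_copies"].to_numpy(), grp[ct_cols].to_numpy())
    ct_cols_s = [c for c in samples.columns if c.startswith("ct_")]
    series = {}
    for target, grp in samples.groupby("target"):
        grp = grp.sort_values("time_h")
        series[target] = (grp["time_h"].to_numpy(dtype=float),
                          quantify_series(curves[target],
                                          grp[ct_cols_s].to_numpy()))
    tv, viral = series[viral_target]
    ta, actin = series[actin_target]
    if not np.array_equal(tv, ta):
        raise BaculokitError("viral and actin time points differ")
    norm = normalize(viral, actin, per=per, times=tv)
    norm = annotate_phases(norm, eps_log2_per_h, expo_log2_per_h)
    expo = [k for k, lab in enumerate(norm.phase_labels)
            if lab == "exponential"]
    summary = None
    if expo:
        window = (float(norm.times[expo[0]]), float(norm.times[expo[-1] + 1]))
        summary = kinetics_summary(norm, window)
    return {"curves": curves, "series": norm, "summary": summary}
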