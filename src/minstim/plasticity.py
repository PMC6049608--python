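"""Field-potential analysis: fEPSP rising slopes, LTP time courses, and
input-output (basal transmission) fits.

Conventions implemented here:

* the fEPSP rising slope is the least-squares line through the samples
  between 20% and 80% of the fEPSP amplitude on the rising (falling-
  voltage) phase;
* LTP time courses are normalized to the pre-induction baseline mean
  (baseline = 100% by construction) and quantified as the mean normalized
  response in a named post-induction window minus 100% — 2-3 h
  post-induction for the long-lasting form ("3h-LTP"), 1-2 h for the
  short-lasting form ("2h-LTP");
* basal transmission is a single slope fitted (through the origin) to the
  input-output function of fEPSP slope vs fiber-volley amplitude, each
  experiment normalized to the wild-type population mean of its recording
  condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sweeps import SweepSet

__all__ = [
    "SlopeFitParams",
    "PlasticityCourse",
    "LTP_WINDOWS",
    "fit_fepsp_slope",
    "normalize_course",
    "quantify_ltp",
    "fit_io_slope",
    "normalize_io",
]

#: Named quantification windows, minutes post-induction.
LTP_WINDOWS: dict[str, tuple[float, float]] = {
    "3h-LTP": (120.0, 180.0),
    "2h-LTP": (60.0, 120.0),
}


@dataclass
class SlopeFitParams:
    """Constants of the rising-slope fit.

    The 20-80% amplitude band is the published convention; the peak search
    region and the fiber-volley exclusion (minimum onset latency) are
    analysis choices, configurable here.
    """

    amplitude_fraction_low: float = 0.2
    amplitude_fraction_high: float = 0.8
    baseline_window_ms: float = 5.0  # ends at the stimulus
    search_window_ms: tuple[float, float] = (1.5, 20.0)  # post-stimulus
    min_onset_latency_ms: float = 2.0  # fiber-volley exclusion
    onset_fraction: float = 0.1  # amplitude fraction defining onset
    noise_floor_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.amplitude_fraction_low < self.amplitude_fraction_high < 1:
            raise ValueError("need 0 < low < high < 1 amplitude fractions")


class NoResponseError(ValueError):
    """No fEPSP exceeding the noise floor was found."""


class ResolutionError(ValueError):
    """Too few samples in the 20-80% band to fit a line."""


def fit_fepsp_slope(
    sweep: SweepSet | np.ndarray,
    params: SlopeFitParams | None = None,
    *,
    dt_ms: float | None = None,
    stim_time_ms: float | None = None,
) -> float:
    """20-80% rising slope of a single field sweep, mV/ms.

    Accepts either a single-sweep :class:`SweepSet` or a raw trace plus
    ``dt_ms``/``stim_time_ms``.  Finds the largest negative deflection in
    the search window whose onset latency exceeds the fiber-volley
    exclusion minimum, then fits a least-squares line to the samples whose
    amplitude lies in the 20-80% band on the rising phase.
    """
    params = params or SlopeFitParams()
    if isinstance(sweep, SweepSet):
        trace = sweep.data[0]
        dt_ms = sweep.dt_ms
        stim_time_ms = sweep.stim_time_ms
    else:
        trace = np.asarray(sweep, dtype=float)
        if dt_ms is None or stim_time_ms is None:
            raise ValueError("raw traces require dt_ms and stim_time_ms")

    n = len(trace)
    istim = int(round(stim_time_ms / dt_ms))
    ib0 = max(0, istim - int(round(params.baseline_window_ms / dt_ms)))
    if ib0 >= istim:
        raise ValueError("baseline window does not fit before the stimulus")
    baseline = float(trace[ib0:istim].mean())
    noise_sd = float(trace[ib0:istim].std(ddof=1)) if istim - ib0 > 1 else 0.0
    dev = trace - baseline

    lo, hi = params.search_window_ms
    i0 = istim + int(np.ceil(lo / dt_ms))
    i1 = min(n, istim + int(np.ceil(hi / dt_ms)))
    if i1 - i0 < 3:
        raise ValueError("search window too short")

    peak_idx = _select_peak(dev, i0, i1, istim, dt_ms, params, noise_sd)
    peak = dev[peak_idx]

    onset_level = params.onset_fraction * peak  # negative
    pre = dev[istim:peak_idx]
    above = np.flatnonzero(pre > onset_level)
    onset_idx = istim + (above[-1] + 1 if above.size else 0)

    lo_level = params.amplitude_fraction_low * peak
    hi_level = params.amplitude_fraction_high * peak
    seg = dev[onset_idx : peak_idx + 1]
    band = np.flatnonzero((seg <= lo_level) & (seg >= hi_level))
    if band.size < 3:
        raise ResolutionError(
            f"only {band.size} samples in the "
            f"{params.amplitude_fraction_low:.0%}-{params.amplitude_fraction_high:.0%} band"
        )
    tt = (onset_idx + band) * dt_ms
    coeffs = np.polyfit(tt, trace[onset_idx + band], 1)
    return float(coeffs[0])


def _select_peak(
    dev: np.ndarray,
    i0: int,
    i1: int,
    istim: int,
    dt_ms: float,
    params: SlopeFitParams,
    noise_sd: float,
) -> int:
    """Index of the fEPSP peak: deepest negative deflection whose onset
    latency clears the fiber-volley exclusion."""
    seg = dev[i0:i1]
    floor = -params.noise_floor_multiplier * noise_sd
    order = np.argsort(seg)  # most negative first
    for j in order:
        idx = i0 + j
        if seg[j] >= floor and not (noise_sd == 0.0 and seg[j] < 0):
            break  # candidates from here on do not clear the noise floor
        onset_level = params.onset_fraction * seg[j]
        pre = dev[istim:idx]
        above = np.flatnonzero(pre > onset_level)
        onset_idx = istim + (above[-1] + 1 if above.size else 0)
        if (onset_idx - istim) * dt_ms >= params.min_onset_latency_ms:
            return idx
    raise NoResponseError("no fEPSP exceeding the noise floor in the search window")


# ---------------------------------------------------------------------------
# LTP time course


@dataclass
class PlasticityCourse:
    """Normalized fEPSP slope time course around an induction event.

    ``normalized`` is in % of the pre-induction baseline mean, so the
    baseline mean is 100% exactly by construction.
    """

    times_min: np.ndarray
    slopes: np.ndarray
    normalized: np.ndarray
    induction_time_min: float

    def window_mean(self, window: tuple[float, float]) -> float:
        """Mean normalized response (%) in ``[t0, t1)`` minutes
        post-induction."""
        t0, t1 = window
        t = self.times_min - self.induction_time_min
        mask = (t >= t0) & (t < t1)
        if not mask.any():
            raise ValueError(f"no time points in window {window} min post-induction")
        return float(self.normalized[mask].mean())

    def window_summaries(self, windows: dict | None = None) -> pd.DataFrame:
        windows = windows or LTP_WINDOWS
        rows = []
        for name, win in windows.items():
            try:
                rows.append(
                    {"window": name, "mean_pct": self.window_mean(win),
                     "ltp_pct": self.window_mean(win) - 100.0}
                )
            except ValueError:
                rows.append({"window": name, "mean_pct": np.nan, "ltp_pct": np.nan})
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Time course as % baseline with the induction marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.times_min - self.induction_time_min
        ax.plot(t, self.normalized, "o", ms=3)
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
        ax.axhline(100.0, color="grey", lw=0.8)
        ax.set_xlabel("time from induction (min)")
        ax.set_ylabel("fEPSP slope (% baseline)")
        return ax


def normalize_course(
    slopes, times_min, induction_time_min: float, min_baseline: int = 5
) -> PlasticityCourse:
    """Normalize a slope series to its pre-induction baseline mean.

    Requires at least ``min_baseline`` sweeps before the induction time.
    """
    slopes = np.asarray(list(slopes), dtype=float)
    times = np.asarray(list(times_min), dtype=float)
    if slopes.shape != times.shape:
        raise ValueError("slopes and times must have equal length")
    base_mask = times < induction_time_min
    if base_mask.sum() < min_baseline:
        raise ValueError(
            f"need >= {min_baseline} baseline sweeps before induction, "
            f"got {int(base_mask.sum())}"
        )
    base_mean = slopes[base_mask].mean()
    if base_mean == 0:
        raise ValueError("baseline mean slope is zero; cannot normalize")
    return PlasticityCourse(
        times_min=times,
        slopes=slopes,
        normalized=slopes / base_mean * 100.0,
        induction_time_min=induction_time_min,
    )


def quantify_ltp(course: PlasticityCourse, window: tuple[float, float] | str) -> float:
    """Percent potentiation: mean normalized response in the window - 100.

    ``window`` is (t0, t1) minutes post-induction or a named window from
    :data:`LTP_WINDOWS`.
    """
    if isinstance(window, str):
        window = LTP_WINDOWS[window]
    if window[0] < 0:
        raise ValueError("quantification window must lie post-induction")
    return course.window_mean(window) - 100.0


# ---------------------------------------------------------------------------
# Input-output (basal transmission)


def fit_io_slope(points, through_origin: bool = True) -> float:
    """Single slope of the input-output function (fEPSP slope vs fiber
    volley).

    ``points`` are (fiber_volley_mv, fepsp_slope_mv_per_ms) pairs from >= 3
    stimulation steps.  The default fit is through the origin
    (``sum(xy)/sum(x^2)``) since the input-output function passes through
    (0, 0) physically; ``through_origin=False`` fits an intercept as well
    and returns only the slope.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (fiber_volley, fepsp_slope) pairs")
    if arr.shape[0] < 3:
        raise ValueError("input-output fit requires at least 3 stimulation steps")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == 0):
        raise ValueError("all fiber-volley amplitudes are zero; fit is degenerate")
    if through_origin:
        return float(np.sum(x * y) / np.sum(x * x))
    return float(np.polyfit(x, y, 1)[0])


def normalize_io(
    table: pd.DataFrame,
    slope_col: str = "io_slope",
    genotype_col: str = "genotype",
    condition_col: str = "condition",
    wildtype_label: str = "WT",
) -> pd.DataFrame:
    """Normalize per-experiment I/O slopes to the wild-type mean of their
    recording condition.

    Adds a ``normalized`` column; the wild-type group mean within each
    condition is 1.0 exactly.  Raises if any condition lacks wild-type
    experiments.
    """
    out = table.copy()
    out["normalized"] = np.nan
    for cond, grp in table.groupby(condition_col):
        wt = grp[grp[genotype_col] == wildtype_label]
        if len(wt) == 0:
            raise ValueError(f"no {wildtype_label!r} experiments in condition {cond!r}")
        ref = wt[slope_col].mean()
        out.loc[grp.index, "normalized"] = grp[slope_col] / ref
    return out
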