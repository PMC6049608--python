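"""Event detection: baseline and noise estimation, peak and charge
measurement, failure classification, and experiment-level QC.

Classification follows the two-criterion convention of minimal-stimulation
analysis:

* at the depolarized potential (+40 mV) a sweep is a failure when the
  baseline-subtracted charge in the 5-40 ms post-stimulus window does not
  exceed the charge threshold (equality counts as a failure);
* at the hyperpolarized potential (-60 mV) a sweep is a failure when the
  peak magnitude — measured after subtracting the average-failure trace,
  which removes the stimulus artifact — is smaller than ``noise_multiplier``
  times the signal noise (equality counts as a success).

Signal noise is the per-sweep sample SD in a short pre-stimulus window,
averaged over all sweeps at a holding potential.

The average-failure template at -60 mV is itself defined by the failures,
so classification runs as a fixed-point iteration: classify on raw peaks,
build the template from the failures, re-measure and re-classify, repeat
(at most ``max_template_iterations`` rounds; in practice it converges in
two).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .simulate import SimulationConfig, single_quantum_window_charge
from .sweeps import EVENT_TABLE_COLUMNS, EventTable, SweepSet

__all__ = [
    "DetectionParams",
    "NoiseEstimate",
    "QCVerdict",
    "estimate_noise",
    "measure_charge",
    "measure_peak",
    "classify_failures",
    "qc_experiment",
]


@dataclass
class DetectionParams:
    """Tunable constants of the detection stage.

    The defaults are the published conventions: 0.9 pC charge threshold,
    5-40 ms charge window, 3 ms noise window, 25 ms NMDA read time, and a
    failure criterion of twice the signal noise.  ``peak_smoothing_ms`` is
    a short boxcar applied before the windowed extremum is taken; see the
    methods note for why raw-sample extrema cannot be compared against a
    per-sample noise SD.
    """

    charge_failure_threshold: float = 0.9  # pC
    charge_window: tuple[float, float] = (5.0, 40.0)  # ms post-stimulus
    noise_window_length: float = 3.0  # ms
    noise_window_gap: float = 1.0  # ms: window ends this long before stim
    baseline_window_ms: float = 8.0  # ms; longer than the noise window so the
    # baseline mean's error does not dominate the charge integral
    peak_search_window_hyper: tuple[float, float] = (1.0, 10.0)  # ms post-stim
    nmda_read_time: float = 25.0  # ms post-stimulus
    noise_multiplier: float = 2.0
    trend_alpha: float = 0.05
    max_noise_sd: float = 3.0  # pA
    peak_smoothing_ms: float = 0.6
    max_template_iterations: int = 5
    acquisition_rf_range: tuple[float, float] = (0.10, 0.40)

    def __post_init__(self) -> None:
        if self.charge_failure_threshold <= 0:
            raise ValueError("charge_failure_threshold must be > 0")
        if not 0 < self.trend_alpha < 1:
            raise ValueError("trend_alpha must be in (0, 1)")
        for lo, hi in (self.charge_window, self.peak_search_window_hyper):
            if not 0 <= lo < hi:
                raise ValueError("windows must satisfy 0 <= start < end")

    @classmethod
    def for_simulation(cls, config: SimulationConfig, **overrides) -> "DetectionParams":
        """Detection parameters internally consistent with a simulation.

        The published 0.9 pC charge threshold presumes compound events far
        larger than a single ~4 pA quantum; on simulated data the threshold
        is instead set to a quarter of the analytic single-quantum charge in
        the charge window.  The charge integral averages the noise down to a
        few fC, so the threshold sits far above the noise yet below the
        charge of quanta drawn small by amplitude variability (at cv_q = 0.3
        a quarter-quantum cut misses < 1% of single quanta, where a
        half-quantum cut would miscount ~5% of them as failures).
        """
        base = cls(**{k: v for k, v in overrides.items() if k != "charge_failure_threshold"})
        q_charge = single_quantum_window_charge(
            config.q_nmda,
            config.tau_rise_slow,
            config.tau_decay_slow,
            base.charge_window,
        )
        return replace(
            base,
            charge_failure_threshold=overrides.get(
                "charge_failure_threshold", 0.25 * q_charge
            ),
            max_noise_sd=overrides.get("max_noise_sd", max(3.0, 2.0 * config.noise_sd)),
        )


@dataclass
class NoiseEstimate:
    """Signal noise of a recording: mean over sweeps of the per-sweep SD
    in the noise window."""

    sd: float  # pA
    n_sweeps: int
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def _noise_window(sweeps: SweepSet, params: DetectionParams) -> tuple[float, float]:
    end = sweeps.stim_time_ms - params.noise_window_gap
    start = end - params.noise_window_length
    if start < 0:
        raise ValueError(
            f"noise window [{start:.2f}, {end:.2f}) ms does not fit before the stimulus"
        )
    return (start, end)


def estimate_noise(sweeps: SweepSet, params: DetectionParams) -> NoiseEstimate:
    """Mean over sweeps of the per-sweep sample SD in the noise window."""
    window = _noise_window(sweeps, params)
    sl = sweeps.window_slice(*window)
    per_sweep_sd = sweeps.data[:, sl].std(axis=1, ddof=1)
    return NoiseEstimate(
        sd=float(per_sweep_sd.mean()), n_sweeps=sweeps.n_sweeps, window_ms=window
    )


def _baselines(sweeps: SweepSet, params: DetectionParams) -> np.ndarray:
    end = sweeps.stim_time_ms - params.noise_window_gap
    start = max(0.0, end - params.baseline_window_ms)
    if end <= start:
        raise ValueError("baseline window does not fit before the stimulus")
    sl = sweeps.window_slice(start, end)
    return sweeps.data[:, sl].mean(axis=1)


def measure_charge(
    trace: np.ndarray,
    params: DetectionParams,
    *,
    dt_ms: float,
    stim_time_ms: float,
) -> float:
    """Baseline-subtracted charge magnitude over the charge window, pC.

    Trapezoidal integral of the current deviation from baseline (the mean
    of the noise window) over ``[stim + 5, stim + 40) ms``; 1 pA*ms =
    1 fC, so the result is divided by 1000.
    """
    holder = SweepSet(
        data=np.asarray(trace, dtype=float)[None, :],
        sampling_rate_hz=1000.0 / dt_ms,
        stim_time_ms=stim_time_ms,
    )
    return float(_charges(holder, params)[0])


def _charges(sweeps: SweepSet, params: DetectionParams) -> np.ndarray:
    base = _baselines(sweeps, params)
    lo, hi = params.charge_window
    sl = sweeps.window_slice(sweeps.stim_time_ms + lo, sweeps.stim_time_ms + hi)
    # trapezoid over the closed interval [lo, hi]: include the right edge
    # sample when it exists so a constant deviation integrates exactly
    stop = min(sl.stop + 1, sweeps.n_samples)
    dev = sweeps.data[:, sl.start : stop] - base[:, None]
    pa_ms = np.trapezoid(dev, dx=sweeps.dt_ms, axis=1)
    return np.abs(pa_ms) / 1000.0


def _smooth(data: np.ndarray, params: DetectionParams, dt_ms: float) -> np.ndarray:
    n = max(1, int(round(params.peak_smoothing_ms / dt_ms)))
    if n <= 1:
        return data
    return uniform_filter1d(data, size=n, axis=-1, mode="nearest")


def measure_peak(
    trace: np.ndarray,
    average_failure: np.ndarray | None,
    params: DetectionParams,
    *,
    dt_ms: float,
    stim_time_ms: float,
    direction: int = -1,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Windowed peak of a single sweep: (signed amplitude pA, latency ms).

    Subtracts ``average_failure`` when given (removes the stimulus
    artifact), subtracts the baseline, applies the boxcar smoothing, then
    takes the extremum in ``direction`` (-1: most negative, +1: most
    positive) within the search window (default: the hyperpolarized peak
    window).  Latency is ms after the stimulus.
    """
    trace = np.asarray(trace, dtype=float)
    if average_failure is not None:
        average_failure = np.asarray(average_failure, dtype=float)
        if average_failure.shape != trace.shape:
            raise ValueError("average_failure must have the same length as the sweep")
        trace = trace - average_failure
    holder = SweepSet(
        data=trace[None, :], sampling_rate_hz=1000.0 / dt_ms, stim_time_ms=stim_time_ms
    )
    amps, lats = _peaks(holder, params, direction=direction, window=window)
    return float(amps[0]), float(lats[0])


def _peaks(
    sweeps: SweepSet,
    params: DetectionParams,
    direction: int,
    window: tuple[float, float] | None = None,
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    data = sweeps.data
    if template is not None:
        data = data - template[None, :]
        holder = replace(sweeps, data=data)
    else:
        holder = sweeps
    base = _baselines(holder, params)
    dev = _smooth(data - base[:, None], params, sweeps.dt_ms)
    lo, hi = window if window is not None else params.peak_search_window_hyper
    sl = sweeps.window_slice(sweeps.stim_time_ms + lo, sweeps.stim_time_ms + hi)
    if sl.start == sl.stop:
        raise ValueError("empty peak search window")
    seg = dev[:, sl]
    if direction < 0:
        idx = np.argmin(seg, axis=1)
    else:
        idx = np.argmax(seg, axis=1)
    amps = seg[np.arange(len(seg)), idx]
    lats = (sl.start + idx) * sweeps.dt_ms - sweeps.stim_time_ms
    return amps, lats


def _read_amplitude(
    sweeps: SweepSet, params: DetectionParams, read_time_ms: float
) -> np.ndarray:
    """Baseline-subtracted smoothed amplitude at a fixed post-stimulus time."""
    base = _baselines(sweeps, params)
    dev = _smooth(sweeps.data - base[:, None], params, sweeps.dt_ms)
    i = sweeps.sample_index(sweeps.stim_time_ms + read_time_ms)
    i = min(i, sweeps.n_samples - 1)
    return dev[:, i]


def classify_failures(
    sweeps: SweepSet, params: DetectionParams, noise: NoiseEstimate | None = None
) -> EventTable:
    """Build the per-sweep event table with failure flags.

    The holding potential of the sweep set selects the criterion:
    +40 mV uses the charge threshold ("did not exceed" — equality is a
    failure); -60 mV uses the peak-vs-noise criterion ("smaller than twice
    the signal noise" — equality is a success) with iterative
    average-failure subtraction.
    """
    hp = sweeps.holding_potential_mv
    if hp is None:
        raise ValueError("classification requires a holding potential in the metadata")
    if noise is None:
        noise = estimate_noise(sweeps, params)
    base = _baselines(sweeps, params)

    if hp > 0:
        charges = _charges(sweeps, params)
        failures = charges <= params.charge_failure_threshold
        amps = _read_amplitude(sweeps, params, params.nmda_read_time)
        peak_amps, peak_lats = _peaks(
            sweeps, params, direction=+1, window=params.charge_window
        )
    elif hp < 0:
        # tiny absolute floor so noiseless recordings (sd = 0) still classify
        # exact-zero peaks as failures
        threshold = max(params.noise_multiplier * noise.sd, 1e-9)
        template: np.ndarray | None = None
        # Pass 1 is provisional and unsmoothed: without the average-failure
        # template the artifact is still in the trace, and smoothing would
        # smear it into the peak window.
        raw_params = replace(params, peak_smoothing_ms=0.0)
        peak_amps, peak_lats = _peaks(sweeps, raw_params, direction=-1)
        failures = np.abs(peak_amps) < threshold
        for _ in range(params.max_template_iterations):
            if not failures.any():
                break
            template = sweeps.data[failures].mean(axis=0)
            peak_amps, peak_lats = _peaks(sweeps, params, direction=-1, template=template)
            new_failures = np.abs(peak_amps) < threshold
            if np.array_equal(new_failures, failures):
                failures = new_failures
                break
            failures = new_failures
        amps = peak_amps
        charges = _charges(sweeps, params)
    else:
        raise ValueError(f"unknown holding potential: {hp} mV")

    frame = pd.DataFrame(
        {
            "sweep_index": np.arange(sweeps.n_sweeps),
            "order_index": np.asarray(sweeps.order_index),
            "timestamp_s": np.asarray(sweeps.timestamp_s),
            "holding_potential_mv": hp,
            "baseline_pa": base,
            "noise_context": f"sd={noise.sd:.4g}pA",
            "peak_pa": peak_amps,
            "peak_latency_ms": peak_lats,
            "amplitude_pa": amps,
            "charge_pc": charges,
            "is_failure": failures,
            "qc_excluded": False,
            "qc_reason": "",
        }
    )
    return EventTable(frame=frame, experiment_id=sweeps.experiment_id)


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCVerdict:
    """Experiment-level QC outcome.

    ``status`` is ``"pass"``, ``"excluded"``, or ``"indeterminate"`` (too
    few sweeps to test for trends).  ``p_values`` maps component-test names
    to their OLS-slope p-values; each component runs at
    ``trend_alpha / n_tests`` so the experiment-level false-exclusion rate
    is held at ``trend_alpha``.
    """

    status: str
    reasons: list = field(default_factory=list)
    p_values: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


_MIN_TREND_SWEEPS = 10


def _trend_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value for a nonzero OLS slope of y on x."""
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    p = res.pvalue
    return 1.0 if np.isnan(p) else float(p)


def qc_experiment(
    events: EventTable | tuple | list,
    params: DetectionParams,
    noise: NoiseEstimate | tuple | list,
) -> tuple[list[EventTable], QCVerdict]:
    """Apply experiment-level exclusion rules.

    Excludes the experiment when (a) the failure indicator or the success
    amplitude drifts linearly with acquisition order at either holding
    potential (run-up/run-down), or (b) the background noise exceeds
    ``max_noise_sd``.  Also emits an advisory warning when the depolarized
    failure fraction falls outside the 10-40% acquisition target.

    Returns the event tables with their ``qc_excluded`` flags set when the
    experiment is excluded, plus the :class:`QCVerdict`.
    """
    tables = [events] if isinstance(events, EventTable) else list(events)
    noises = [noise] if isinstance(noise, NoiseEstimate) else list(noise)
    if len(noises) != len(tables):
        raise ValueError("one NoiseEstimate per EventTable is required")

    reasons: list[str] = []
    advisories: list[str] = []
    pvals: dict[str, float] = {}
    indeterminate = False

    for tab, nz in zip(tables, noises):
        hp = tab.frame["holding_potential_mv"].iloc[0]
        label = f"{hp:+.0f}mV"
        if nz.sd > params.max_noise_sd:
            reasons.append(f"noise ({label}: sd {nz.sd:.2f} pA > {params.max_noise_sd} pA)")
        if len(tab.frame) < _MIN_TREND_SWEEPS:
            indeterminate = True
            continue
        order = tab.frame["order_index"].to_numpy(dtype=float)
        fail = tab.frame["is_failure"].to_numpy(dtype=float)
        pvals[f"failure_trend_{label}"] = _trend_pvalue(order, fail)
        succ = ~tab.frame["is_failure"].astype(bool)
        if succ.sum() >= 3:
            pvals[f"amplitude_trend_{label}"] = _trend_pvalue(
                order[succ], tab.frame.loc[succ, "amplitude_pa"].to_numpy(dtype=float)
            )
        if hp > 0:
            rf = fail.mean()
            lo, hi = params.acquisition_rf_range
            if not lo <= rf <= hi:
                advisories.append(
                    f"depolarized failure fraction {rf:.2f} outside "
                    f"acquisition target [{lo:.0%}, {hi:.0%}]"
                )

    if pvals:
        level = params.trend_alpha / len(pvals)
        for name, p in pvals.items():
            if p < level:
                reasons.append(f"trend ({name}: p={p:.3g} < {level:.3g})")

    if reasons:
        status = "excluded"
    elif indeterminate and not pvals:
        status = "indeterminate"
    else:
        status = "pass"

    out_tables = []
    for tab in tables:
        frame = tab.frame.copy()
        if status == "excluded":
            frame["qc_excluded"] = True
            frame["qc_reason"] = "; ".join(reasons)
        out_tables.append(EventTable(frame=frame, experiment_id=tab.experiment_id))
    return out_tables, QCVerdict(
        status=status, reasons=reasons, p_values=pvals, warnings=advisories
    )
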