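"""Synthetic minimal-stimulation sweeps and fEPSP time courses.

The generator is the inverse of the analysis model: transmitter release per
trial is Poisson with mean quantal content ``m``; a fraction ``s`` of the
stimulated synapses is silent (NMDA receptors only), so silent synapses
contribute quanta only at the depolarized holding potential.  Per sweep the
quantum count is therefore

* Poisson(``m_total``) at +40 mV (all synapses conduct), and
* Poisson(``m_total * (1 - s)``) at -60 mV (only AMPA-containing synapses).

Each quantum adds a peak-normalized biexponential EPSC waveform — fast
kinetics at -60 mV (AMPA-like, inward/negative), slow kinetics at +40 mV
(NMDA-like, outward/positive) — with a truncated-normal amplitude multiplier
so amplitudes never change sign, plus a biphasic stimulus artifact and
Gaussian instrument noise.  Every draw comes from one seeded generator:
identical config and seed give bit-identical sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .sweeps import SweepSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "InvalidConfigError",
    "simulate_minstim_experiment",
    "simulate_fepsp_course",
    "biexp_waveform",
    "biexp_peak_time",
    "single_quantum_window_charge",
]


class InvalidConfigError(ValueError):
    """A simulation config violates its invariants."""


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of ``exp(-t/tau_decay) - exp(-t/tau_rise)``, ms."""
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    )


def biexp_waveform(
    t_ms: np.ndarray, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Peak-normalized biexponential, zero for t < 0.

    ``w(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / w(t_peak)`` so the
    waveform peaks at exactly 1.
    """
    if not 0 < tau_rise < tau_decay:
        raise InvalidConfigError("need 0 < tau_rise < tau_decay")
    t = np.asarray(t_ms, dtype=float)
    tp = biexp_peak_time(tau_rise, tau_decay)
    norm = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    w = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0) / norm
    return w


def single_quantum_window_charge(
    q: float,
    tau_rise: float,
    tau_decay: float,
    window: tuple[float, float] = (5.0, 40.0),
) -> float:
    """Analytic charge (pC) of one quantum of peak amplitude ``q`` pA over
    the post-stimulus ``window`` (ms).

    Closed-form integral of the peak-normalized biexponential; used to pick
    internally consistent failure thresholds for simulated data.
    """
    tp = biexp_peak_time(tau_rise, tau_decay)
    norm = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    a, b = window

    def _integral(t: float) -> float:
        # antiderivative of exp(-t/td) - exp(-t/tr)
        return -tau_decay * np.exp(-t / tau_decay) + tau_rise * np.exp(-t / tau_rise)

    pa_ms = q / norm * (_integral(b) - _integral(a))
    return pa_ms / 1000.0  # pA*ms -> pC


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated minimal-stimulation cell.

    Defaults emulate the recordings the model was built for: 5 kHz
    sampling, quantal amplitudes ~4.4 pA (slow/NMDA component at +40 mV)
    and ~9.7 pA magnitude (fast/AMPA component at -60 mV), ~2 pA baseline
    noise, and a mean quantal content that puts the +40 mV failure
    fraction inside the 10-40% acquisition target (``m_total = 1.5`` gives
    ``exp(-1.5) = 22%``).

    ``drift_slope`` imposes a linear trend on the per-sweep release mean
    (fractional change from first to last sweep is ``drift_slope``); it
    exists to exercise the run-up/run-down QC exclusion.
    """

    n_sweeps_per_potential: int = 40
    m_total: float = 1.5
    silent_fraction: float = 0.0
    q_nmda: float = 4.4  # pA, peak of the slow waveform at +40 mV
    q_ampa: float = 9.7  # pA magnitude, peak of the fast waveform at -60 mV
    cv_q: float = 0.3
    tau_rise_fast: float = 1.0  # ms
    tau_decay_fast: float = 8.0  # ms
    tau_rise_slow: float = 5.0  # ms
    tau_decay_slow: float = 60.0  # ms
    noise_sd: float = 2.0  # pA
    sampling_rate: float = 5000.0  # Hz
    stim_time: float = 10.0  # ms
    sweep_length: float = 120.0  # ms
    artifact_amplitude: float = 50.0  # pA
    drift_slope: float = 0.0
    stim_interval_s: float = 5.0  # 0.2 Hz stimulation
    seed: int = 0

    def validate(self) -> None:
        if self.n_sweeps_per_potential <= 0:
            raise InvalidConfigError("n_sweeps_per_potential must be >= 1")
        if not 0 <= self.silent_fraction < 1:
            raise InvalidConfigError("silent_fraction must be in [0, 1)")
        if self.m_total <= 0:
            raise InvalidConfigError("m_total must be > 0")
        for name in ("tau_rise_fast", "tau_decay_fast", "tau_rise_slow", "tau_decay_slow"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if not self.tau_rise_fast < self.tau_decay_fast:
            raise InvalidConfigError("tau_rise_fast must be < tau_decay_fast")
        if not self.tau_rise_slow < self.tau_decay_slow:
            raise InvalidConfigError("tau_rise_slow must be < tau_decay_slow")
        if self.cv_q < 0 or self.noise_sd < 0:
            raise InvalidConfigError("cv_q and noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be > 0")
        if self.sweep_length <= self.stim_time + 40.0:
            raise InvalidConfigError(
                "sweep_length must exceed stim_time + 40 ms (charge window must fit)"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the simulator actually did, for judging the estimators.

    ``rf_*`` are the analytic failure probabilities (``exp(-m)``), not the
    empirical fractions; the empirical fractions follow from the stored
    quantum counts.  ``q_depol_read25`` is the 25-ms read of a single
    slow quantum — the quantal size on the scale the +40 mV potency
    measurement uses.
    """

    counts_hyper: np.ndarray
    counts_depol: np.ndarray
    failures_hyper: np.ndarray
    failures_depol: np.ndarray
    rf_hyper: float
    rf_depol: float
    silent_fraction: float
    m_total: float
    q_ampa: float
    q_nmda: float
    q_depol_read25: float

    @property
    def empirical_rf_hyper(self) -> float:
        return float(np.mean(self.failures_hyper))

    @property
    def empirical_rf_depol(self) -> float:
        return float(np.mean(self.failures_depol))


def _amplitude_multipliers(rng: np.random.Generator, counts: np.ndarray, cv: float) -> np.ndarray:
    """Summed amplitude multipliers, one value per sweep.

    Each quantum scales by ``1 + cv*eps`` with ``eps`` standard normal
    truncated below ``-1/cv`` (multiplier stays positive).  Returns the
    per-sweep sum over its quanta.
    """
    total = int(counts.sum())
    if total == 0:
        return np.zeros(len(counts))
    if cv == 0:
        return counts.astype(float)
    eps = rng.standard_normal(total)
    lo = -1.0 / cv
    bad = eps < lo
    while bad.any():  # truncation: resample the rare below-bound draws
        eps[bad] = rng.standard_normal(int(bad.sum()))
        bad = eps < lo
    mult = 1.0 + cv * eps
    out = np.zeros(len(counts))
    np.add.at(out, np.repeat(np.arange(len(counts)), counts), mult)
    return out


def _artifact(n_samples: int, dt_ms: float, stim_time: float, amplitude: float) -> np.ndarray:
    """Biphasic 1-ms stimulus artifact starting at stim_time."""
    t = np.arange(n_samples) * dt_ms - stim_time
    art = np.zeros(n_samples)
    art[(t >= 0) & (t < 0.5)] = amplitude
    art[(t >= 0.5) & (t < 1.0)] = -amplitude
    return art


def _simulate_potential(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    m: float,
    q_signed: float,
    tau_rise: float,
    tau_decay: float,
    holding_mv: float,
) -> tuple[SweepSet, np.ndarray]:
    n = cfg.n_sweeps_per_potential
    dt = 1000.0 / cfg.sampling_rate
    n_samples = int(round(cfg.sweep_length / dt))
    t = np.arange(n_samples) * dt

    idx = np.arange(n)
    if n > 1 and cfg.drift_slope != 0.0:
        m_per_sweep = m * (1.0 + cfg.drift_slope * (idx / (n - 1) - 0.5))
        m_per_sweep = np.clip(m_per_sweep, 0.0, None)
    else:
        m_per_sweep = np.full(n, m)
    counts = rng.poisson(m_per_sweep)

    mult = _amplitude_multipliers(rng, counts, cfg.cv_q)
    wave = biexp_waveform(t - cfg.stim_time, tau_rise, tau_decay)
    data = (q_signed * mult)[:, None] * wave[None, :]
    data += _artifact(n_samples, dt, cfg.stim_time, cfg.artifact_amplitude)[None, :]
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)

    sweeps = SweepSet(
        data=data,
        sampling_rate_hz=cfg.sampling_rate,
        stim_time_ms=cfg.stim_time,
        holding_potential_mv=holding_mv,
        order_index=idx,
        timestamp_s=idx * cfg.stim_interval_s,
    )
    return sweeps, counts


def simulate_minstim_experiment(
    config: SimulationConfig,
) -> tuple[SweepSet, SweepSet, GroundTruth]:
    """Simulate one minimal-stimulation experiment at both holding potentials.

    Returns the -60 mV sweep set, the +40 mV sweep set, and the ground
    truth (per-sweep quantum counts, analytic failure rates, true quantal
    sizes).  Deterministic for a given config (the seed lives in the
    config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m_hyper = config.m_total * (1.0 - config.silent_fraction)

    sweeps_hyper, counts_hyper = _simulate_potential(
        rng,
        config,
        m=m_hyper,
        q_signed=-config.q_ampa,  # inward at -60 mV
        tau_rise=config.tau_rise_fast,
        tau_decay=config.tau_decay_fast,
        holding_mv=-60.0,
    )
    sweeps_depol, counts_depol = _simulate_potential(
        rng,
        config,
        m=config.m_total,
        q_signed=+config.q_nmda,  # outward at +40 mV
        tau_rise=config.tau_rise_slow,
        tau_decay=config.tau_decay_slow,
        holding_mv=+40.0,
    )

    read25 = float(
        config.q_nmda
        * biexp_waveform(
            np.array([25.0]), config.tau_rise_slow, config.tau_decay_slow
        )[0]
    )
    truth = GroundTruth(
        counts_hyper=counts_hyper,
        counts_depol=counts_depol,
        failures_hyper=counts_hyper == 0,
        failures_depol=counts_depol == 0,
        rf_hyper=float(np.exp(-m_hyper)),
        rf_depol=float(np.exp(-config.m_total)),
        silent_fraction=config.silent_fraction,
        m_total=config.m_total,
        q_ampa=config.q_ampa,
        q_nmda=config.q_nmda,
        q_depol_read25=read25,
    )
    return sweeps_hyper, sweeps_depol, truth


# ---------------------------------------------------------------------------
# fEPSP / LTP fixture generator


def simulate_fepsp_course(
    baseline_slope: float = -0.15,
    potentiation_factor: float = 1.5,
    induction_time: float = 20.0,
    duration: float = 80.0,
    interval: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 5000.0,
    stim_time: float = 10.0,
    sweep_length: float = 60.0,
    synaptic_delay: float = 3.0,
) -> tuple[list[SweepSet], np.ndarray, np.ndarray]:
    """Synthetic fEPSP time course with a potentiation step at induction.

    Parameters
    ----------
    baseline_slope
        Expected 20-80% rising slope before induction, mV/ms (negative:
        fEPSPs are negative-going).
    potentiation_factor
        Multiplicative step applied to the response after ``induction_time``
        (1.5 -> 50% potentiation).
    induction_time, duration, interval
        Minutes.  One field sweep is emitted per ``interval``.
    noise_cv
        Multiplicative trial-to-trial amplitude noise (CV).

    Returns ``(sweeps, times_min, true_slopes)`` where ``sweeps`` is one
    single-trace field SweepSet per time point.
    """
    if interval <= 0:
        raise InvalidConfigError("interval must be > 0")
    if duration <= induction_time:
        raise InvalidConfigError("duration must exceed induction_time")
    if potentiation_factor <= 0:
        raise InvalidConfigError("potentiation_factor must be > 0")

    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate
    n_samples = int(round(sweep_length / dt))
    t = np.arange(n_samples) * dt

    tau_rise, tau_decay = 2.0, 12.0  # field kinetics, ms
    # synaptic delay keeps the fEPSP onset clear of the fiber-volley
    # exclusion window used by the slope fitter
    wave = biexp_waveform(t - stim_time - synaptic_delay, tau_rise, tau_decay)
    # slope of the unit waveform over its own 20-80% rising band, mV/ms
    unit_slope = _unit_rising_slope(wave, dt)

    times = np.arange(0.0, duration, interval)
    sweeps: list[SweepSet] = []
    true_slopes = np.empty(len(times))
    for i, tm in enumerate(times):
        factor = potentiation_factor if tm >= induction_time else 1.0
        amp = (baseline_slope / unit_slope) * factor
        if noise_cv > 0:
            amp *= max(0.0, 1.0 + noise_cv * rng.standard_normal())
        trace = amp * wave
        true_slopes[i] = amp * unit_slope
        sweeps.append(
            SweepSet(
                data=trace[None, :],
                sampling_rate_hz=sampling_rate,
                stim_time_ms=stim_time,
                holding_potential_mv=None,
                order_index=np.array([i]),
                timestamp_s=np.array([tm * 60.0]),
            )
        )
    return sweeps, times, true_slopes


def _unit_rising_slope(wave: np.ndarray, dt_ms: float) -> float:
    """Least-squares slope of the 20-80% rising band of a unit waveform."""
    ipeak = int(np.argmax(wave))
    peak = wave[ipeak]
    rising = wave[: ipeak + 1]
    band = np.flatnonzero((rising >= 0.2 * peak) & (rising <= 0.8 * peak))
    tt = band * dt_ms
    coeffs = np.polyfit(tt, rising[band], 1)
    return float(coeffs[0])
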