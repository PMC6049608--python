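"""Poisson quantal-release model and the silent-synapse estimators.

Under minimal stimulation the number of quanta released per trial is
modeled as Poisson with mean quantal content ``m``:

    P(k) = m^k e^{-m} / k!,   so the failure rate  r_f = P(0) = e^{-m}
    and  m = -ln(r_f).

Silent synapses (NMDA receptors only) conduct at +40 mV but not at -60 mV,
so with a silent fraction ``s`` the effective content at -60 mV is
``m (1 - s)`` while at +40 mV it is ``m``.  Dividing the log failure rates
cancels ``m``:

    s = 1 - ln(r_f,-60) / ln(r_f,+40)

which is the estimator implemented here.  Sampling noise can push the
estimate below zero; such values are flagged, never clipped.

Synaptic potency S (mean amplitude of successes) relates to the mean
quantal size q through the zero-truncated Poisson mean:

    S = -ln(r_f) * q            ("published" variant, the published relation)
    S = -ln(r_f) * q / (1-r_f)  ("corrected" variant: E[k | k >= 1] = m/(1-e^{-m}))

Both variants are always fitted and reported; the corrected one is the
exact conditional mean when potency is computed over successes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .detection import DetectionParams, _peaks, _read_amplitude, estimate_noise
from .sweeps import EventTable, SweepSet

__all__ = [
    "FailureRateEstimate",
    "PotencyFit",
    "AmpaNmdaRatio",
    "GroupSummary",
    "QuantalSummary",
    "QuantalExperimentModel",
    "estimate_failure_rate",
    "mean_quantal_content",
    "poisson_pmf",
    "silent_fraction_estimate",
    "compute_potency",
    "fit_quantal_size",
    "fit_both_variants",
    "ampa_nmda_ratio",
    "summarize_groups",
    "group_silent_fraction",
]


# ---------------------------------------------------------------------------
# Elementary estimators


def poisson_pmf(k: int, m: float) -> float:
    """P(k) = m^k e^{-m} / k! for integer k >= 0 and content m > 0."""
    if m <= 0:
        raise ValueError("mean quantal content m must be > 0")
    kf = float(k)
    if kf < 0 or kf != int(kf):
        raise ValueError("k must be a non-negative integer")
    k = int(kf)
    return math.exp(k * math.log(m) - m - math.lgamma(k + 1))


def mean_quantal_content(rf: float) -> float:
    """m = -ln(r_f); defined for 0 < r_f <= 1.

    ``r_f = 0`` (no failures observed) leaves m unbounded; report a lower
    bound from the exact binomial interval on r_f instead.
    """
    if rf == 0:
        raise ValueError(
            "rf = 0: mean quantal content is unbounded; report a bound from "
            "the exact binomial confidence interval on the failure rate"
        )
    if not 0 < rf <= 1:
        raise ValueError(f"failure rate must be in (0, 1], got {rf}")
    return -math.log(rf)


def silent_fraction_estimate(rf_hyper: float, rf_depol: float) -> float:
    """s = 1 - ln(r_f,-60) / ln(r_f,+40).

    Requires 0 < rf_hyper <= 1 and 0 < rf_depol < 1 (rf_depol = 1 means
    zero quantal content and the ratio is undefined).  Negative values —
    possible when sampling noise makes rf_hyper < rf_depol — are returned
    as-is; callers flag them.
    """
    if not 0 < rf_hyper <= 1:
        raise ValueError(f"rf_hyper must be in (0, 1], got {rf_hyper}")
    if not 0 < rf_depol < 1:
        raise ValueError(f"rf_depol must be in (0, 1), got {rf_depol}")
    return 1.0 - math.log(rf_hyper) / math.log(rf_depol)


@dataclass
class FailureRateEstimate:
    """Observed failure fraction with an exact binomial interval."""

    rf: float
    n_events: int
    n_failures: int
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_failures > self.n_events:
            raise ValueError("n_failures cannot exceed n_events")


def estimate_failure_rate(
    events: EventTable, ci_level: float = 0.95
) -> FailureRateEstimate:
    """Failure fraction over non-excluded sweeps with a Clopper-Pearson
    (exact tail-inversion) interval."""
    included = events.included
    n = len(included)
    if n == 0:
        raise ValueError("all sweeps are QC-excluded; cannot estimate a failure rate")
    k = int(included["is_failure"].astype(bool).sum())
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="beta")
    return FailureRateEstimate(
        rf=k / n, n_events=n, n_failures=k, ci_low=float(lo), ci_high=float(hi),
        ci_level=ci_level,
    )


def compute_potency(events: EventTable) -> float:
    """Synaptic potency: mean amplitude of the successes, pA (signed).

    Uses the measurement stored in ``amplitude_pa`` (template-subtracted
    peak at -60 mV; 25-ms read at +40 mV).
    """
    included = events.included
    succ = included[~included["is_failure"].astype(bool)]
    if len(succ) == 0:
        raise ValueError("no successes; potency is undefined")
    return float(succ["amplitude_pa"].mean())


# ---------------------------------------------------------------------------
# Potency-vs-failure-rate quantal-size fit


@dataclass
class PotencyFit:
    """Mean quantal size fitted from (r_f, potency) points.

    The model is linear in q given r_f — ``S = x(r_f) * q`` with
    ``x = -ln(r_f)`` (variant "published") or ``x = -ln(r_f)/(1-r_f)``
    (variant "corrected") — so q, its standard error, and the confidence
    interval come from the through-origin least-squares solution.
    """

    q: float
    se: float
    ci_low: float
    ci_high: float
    variant: str
    n: int
    residual_sd: float
    ci_level: float = 0.95


def _design(rf: np.ndarray, variant: str) -> np.ndarray:
    if variant == "published":
        return -np.log(rf)
    if variant == "corrected":
        return -np.log(rf) / (1.0 - rf)
    raise ValueError(f"unknown variant {variant!r}; use 'published' or 'corrected'")


def fit_quantal_size(points, variant: str = "published", ci_level: float = 0.95) -> PotencyFit:
    """Least-squares fit of the mean quantal size q to potency-vs-r_f points.

    ``points`` is a sequence of ``(rf, potency)`` pairs (or an (n, 2)
    array) from >= 3 experiments, all with 0 < rf < 1.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (rf, potency) pairs")
    if arr.shape[0] < 3:
        raise ValueError("quantal-size fit requires at least 3 experiments")
    rf, potency = arr[:, 0], arr[:, 1]
    if np.any((rf <= 0) | (rf >= 1)):
        raise ValueError("all failure rates must lie strictly in (0, 1)")
    x = _design(rf, variant)
    sxx = float(np.sum(x * x))
    q = float(np.sum(x * potency) / sxx)
    resid = potency - q * x
    n = len(x)
    dof = n - 1
    rss = float(np.sum(resid**2))
    se = math.sqrt(rss / dof / sxx)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, dof)
    return PotencyFit(
        q=q,
        se=se,
        ci_low=q - tcrit * se,
        ci_high=q + tcrit * se,
        variant=variant,
        n=n,
        residual_sd=math.sqrt(rss / dof),
        ci_level=ci_level,
    )


def fit_both_variants(points, ci_level: float = 0.95) -> dict[str, PotencyFit]:
    """Both potency-fit variants on the same points; reports always carry both."""
    return {v: fit_quantal_size(points, v, ci_level) for v in ("published", "corrected")}


# ---------------------------------------------------------------------------
# AMPA/NMDA ratio


@dataclass
class AmpaNmdaRatio:
    """AMPA/NMDA receptor ratio from averaged EPSCs.

    ``ampa_component`` is the peak magnitude of the averaged EPSC at
    -60 mV; ``nmda_component`` is the averaged-EPSC amplitude 25 ms after
    stimulation at +40 mV.  In mode ``minstim_all_sweeps`` the average runs
    over successes and failures alike.
    """

    ampa_component: float
    nmda_component: float
    ratio: float
    averaging_mode: str


def ampa_nmda_ratio(
    sweeps_hyper: SweepSet,
    sweeps_depol: SweepSet,
    mode: str = "minstim_all_sweeps",
    params: DetectionParams | None = None,
) -> AmpaNmdaRatio:
    """Average the sweeps first, then measure components on the averages.

    Measurements on the averaged traces are unsmoothed: averaging already
    suppresses the trial noise the peak smoothing exists for, and an
    unsmoothed peak window cleanly excludes the stimulus artifact.
    """
    from dataclasses import replace

    if mode not in ("compound", "minstim_all_sweeps"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    params = replace(params or DetectionParams(), peak_smoothing_ms=0.0)

    def _averaged(sweeps: SweepSet) -> SweepSet:
        return replace(
            sweeps,
            data=sweeps.data.mean(axis=0, keepdims=True),
            order_index=np.array([0]),
            timestamp_s=np.array([0.0]),
        )

    avg_h = _averaged(sweeps_hyper)
    avg_d = _averaged(sweeps_depol)
    amps, _ = _peaks(avg_h, params, direction=-1)
    ampa = float(abs(amps[0]))
    nmda = float(_read_amplitude(avg_d, params, params.nmda_read_time)[0])
    if nmda <= 0:
        raise ValueError(
            f"averaged 25-ms amplitude at +40 mV is {nmda:.3g} pA <= 0; "
            "the AMPA/NMDA ratio is undefined"
        )
    return AmpaNmdaRatio(
        ampa_component=ampa, nmda_component=nmda, ratio=ampa / nmda,
        averaging_mode=mode,
    )


# ---------------------------------------------------------------------------
# Group summaries


@dataclass
class GroupSummary:
    """Mean +/- SE (parametric) or median [25th 75th] with min/max."""

    n: int
    parametric: bool
    mean: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    median: float | None = None
    q25: float | None = None
    q75: float | None = None
    minimum: float | None = None
    maximum: float | None = None

    def __str__(self) -> str:
        if self.parametric:
            se = "n/a" if self.se is None else f"{self.se:.3g}"
            return f"mean {self.mean:.4g} +/- SE {se} (n={self.n})"
        return (
            f"median {self.median:.4g} [{self.q25:.4g} {self.q75:.4g}] "
            f"(min {self.minimum:.4g}, max {self.maximum:.4g}, n={self.n})"
        )


def summarize_groups(values, parametric: bool = True, ci_level: float = 0.95) -> GroupSummary:
    """Summarize per-experiment values in the standard reporting format.

    Percentiles use linear interpolation between order statistics
    (numpy's default quantile convention).  A single value yields a mean
    with no SE.  Inferential tests are delegated, not computed here.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = arr.size
    if parametric:
        mean = float(arr.mean())
        if n < 2:
            return GroupSummary(n=n, parametric=True, mean=mean, se=None)
        se = float(arr.std(ddof=1) / math.sqrt(n))
        tcrit = stats.t.ppf(0.5 + ci_level / 2, n - 1)
        return GroupSummary(
            n=n, parametric=True, mean=mean, se=se,
            ci_low=mean - tcrit * se, ci_high=mean + tcrit * se,
        )
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return GroupSummary(
        n=n, parametric=False, median=float(med), q25=float(q25), q75=float(q75),
        minimum=float(arr.min()), maximum=float(arr.max()),
    )


def group_silent_fraction(
    rf_hyper_values, rf_depol_values, method: str = "group_mean_rf"
) -> float:
    """Group-level silent fraction.

    ``group_mean_rf`` applies the estimator to the group-mean failure
    rates; ``mean_per_experiment`` averages the per-experiment estimates.
    Both are legitimate aggregations and reports show both.
    """
    rf_h = np.asarray(list(rf_hyper_values), dtype=float)
    rf_d = np.asarray(list(rf_depol_values), dtype=float)
    if method == "group_mean_rf":
        return silent_fraction_estimate(float(rf_h.mean()), float(rf_d.mean()))
    if method == "mean_per_experiment":
        vals = [silent_fraction_estimate(h, d) for h, d in zip(rf_h, rf_d)]
        return float(np.mean(vals))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Model / Results objects


@dataclass
class QuantalSummary:
    """Per-experiment quantal payload: failure rates at both potentials,
    quantal contents, silent fraction, and potencies."""

    experiment_id: str
    rf_hyper: FailureRateEstimate
    rf_depol: FailureRateEstimate
    m_hyper: float
    m_depol: float
    silent_fraction: float
    silent_fraction_flag: str
    potency_hyper: float | None
    potency_depol: float | None

    def to_row(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "n_hyper": self.rf_hyper.n_events,
            "n_depol": self.rf_depol.n_events,
            "rf_hyper": self.rf_hyper.rf,
            "rf_hyper_ci_low": self.rf_hyper.ci_low,
            "rf_hyper_ci_high": self.rf_hyper.ci_high,
            "rf_depol": self.rf_depol.rf,
            "rf_depol_ci_low": self.rf_depol.ci_low,
            "rf_depol_ci_high": self.rf_depol.ci_high,
            "m_hyper": self.m_hyper,
            "m_depol": self.m_depol,
            "silent_fraction": self.silent_fraction,
            "silent_fraction_flag": self.silent_fraction_flag,
            "potency_hyper_pa": self.potency_hyper,
            "potency_depol_pa": self.potency_depol,
        }

    def summary(self) -> str:
        lines = [
            f"Quantal summary — experiment {self.experiment_id or '(unnamed)'}",
            f"  rf  -60 mV : {self.rf_hyper.rf:.3f} "
            f"[{self.rf_hyper.ci_low:.3f}, {self.rf_hyper.ci_high:.3f}] "
            f"({self.rf_hyper.n_failures}/{self.rf_hyper.n_events})",
            f"  rf  +40 mV : {self.rf_depol.rf:.3f} "
            f"[{self.rf_depol.ci_low:.3f}, {self.rf_depol.ci_high:.3f}] "
            f"({self.rf_depol.n_failures}/{self.rf_depol.n_events})",
            f"  m   -60 mV : {self.m_hyper:.3f}",
            f"  m   +40 mV : {self.m_depol:.3f}",
            f"  silent fraction : {self.silent_fraction:.3f}"
            + (f"  [{self.silent_fraction_flag}]" if self.silent_fraction_flag else ""),
        ]
        if self.potency_hyper is not None:
            lines.append(f"  potency -60 mV : {self.potency_hyper:.2f} pA")
        if self.potency_depol is not None:
            lines.append(f"  potency +40 mV : {self.potency_depol:.2f} pA")
        return "\n".join(lines)


class QuantalExperimentModel:
    """Poisson quantal model of one minimal-stimulation experiment.

    Built from the event tables at the two holding potentials;
    :meth:`fit` computes failure rates, mean quantal contents, the silent
    fraction, and the potencies, returning a :class:`QuantalSummary`.

    Use :meth:`from_sweeps` to go directly from raw sweep sets through
    detection (and optionally QC).
    """

    def __init__(
        self,
        events_hyper: EventTable,
        events_depol: EventTable,
        experiment_id: str = "",
    ):
        self.events_hyper = events_hyper
        self.events_depol = events_depol
        self.experiment_id = experiment_id or events_hyper.experiment_id

    @classmethod
    def from_sweeps(
        cls,
        sweeps_hyper: SweepSet,
        sweeps_depol: SweepSet,
        params: DetectionParams | None = None,
        qc: bool = True,
    ) -> "QuantalExperimentModel":
        from .detection import classify_failures, qc_experiment

        params = params or DetectionParams()
        noise_h = estimate_noise(sweeps_hyper, params)
        noise_d = estimate_noise(sweeps_depol, params)
        ev_h = classify_failures(sweeps_hyper, params, noise_h)
        ev_d = classify_failures(sweeps_depol, params, noise_d)
        if qc:
            (ev_h, ev_d), verdict = qc_experiment(
                [ev_h, ev_d], params, [noise_h, noise_d]
            )
            if verdict.status == "excluded":
                raise ValueError(
                    f"experiment excluded by QC: {'; '.join(verdict.reasons)}"
                )
        return cls(ev_h, ev_d, experiment_id=sweeps_hyper.experiment_id)

    def fit(self, ci_level: float = 0.95) -> QuantalSummary:
        rf_h = estimate_failure_rate(self.events_hyper, ci_level)
        rf_d = estimate_failure_rate(self.events_depol, ci_level)
        m_h = mean_quantal_content(rf_h.rf) if rf_h.rf > 0 else float("nan")
        m_d = mean_quantal_content(rf_d.rf) if rf_d.rf > 0 else float("nan")
        flag = ""
        if 0 < rf_h.rf <= 1 and 0 < rf_d.rf < 1:
            s = silent_fraction_estimate(rf_h.rf, rf_d.rf)
            if s < 0:
                flag = "negative (sampling noise: rf_-60 < rf_+40)"
        else:
            s = float("nan")
            flag = "undefined (failure rate at a boundary)"

        def _maybe_potency(events: EventTable) -> float | None:
            try:
                return compute_potency(events)
            except ValueError:
                return None

        return QuantalSummary(
            experiment_id=self.experiment_id,
            rf_hyper=rf_h,
            rf_depol=rf_d,
            m_hyper=m_h,
            m_depol=m_d,
            silent_fraction=s,
            silent_fraction_flag=flag,
            potency_hyper=_maybe_potency(self.events_hyper),
            potency_depol=_maybe_potency(self.events_depol),
        )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack per-experiment :class:`QuantalSummary` objects into a table."""
    return pd.DataFrame([s.to_row() for s in summaries])
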