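"""Somatic Ca2+-imaging analysis: dF/F, transient detection, classification.

Per-ROI fluorescence time series (two-photon imaging at 40 or 80 Hz) are
converted to relative fluorescence change dF/F0 = (F(t) - F0)/F0, where F0
is the mean of the lowest 20% of the ROI intensity values of the whole
recording.  The signal is smoothed with an exponentially weighted filter
(time constant 35 ms) and excursions whose amplitude exceeds 3x the SD of
the baseline noise are counted as Ca2+ transients.  Neurons are classified
from the transient rate:

* hyperactive (HN): more than 4 transients/min over a >=4 min observation,
* normal (NN):      between 0 and 4 transients/min,
* silent (SN):      strictly no transients over an extended (>=15 min)
                    observation; wild-type neurons with at most one
                    transient over 15-20 min also count as silent,
* a rate of exactly 4/min is reported as "unclassified".

An AP->Ca2+ calibration fits transient amplitude against the number of
action potentials for events with 1-4 APs (trains faster than 20 Hz)
followed by a quiet interval of at least 100 ms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "TransientSet",
    "NeuronClass",
    "ApCaFit",
    "InsufficientObservationError",
    "DegenerateDesignError",
    "compute_dff",
    "smooth_exponential",
    "estimate_baseline_sd",
    "detect_transients",
    "classify_neuron",
    "fit_ap_ca_linearity",
    "analyze_trace",
]


class InsufficientObservationError(ValueError):
    """The observation period is too short for the attempted classification."""


class DegenerateDesignError(ValueError):
    """The regression design is rank deficient (e.g. all AP counts equal)."""


@dataclass
class FluorescenceTrace:
    """Raw per-ROI fluorescence series (arbitrary units)."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class DffTrace:
    """Relative fluorescence change (dimensionless) with its baseline F0."""

    samples: np.ndarray
    sampling_rate: float
    f0: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class TransientSet:
    """Detected Ca2+ transients over an observation window."""

    onset_times: np.ndarray      # s, strictly increasing
    peak_amplitudes: np.ndarray  # dF/F
    observation_duration: float  # s

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.onset_times.size > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ValueError("onset times must be strictly increasing")
        if not self.observation_duration > 0:
            raise ValueError("observation_duration must be > 0")

    @property
    def count(self) -> int:
        return int(self.onset_times.size)

    @property
    def rate_per_min(self) -> float:
        return self.count / (self.observation_duration / 60.0)


@dataclass(frozen=True)
class NeuronClass:
    label: str      # hyperactive | normal | silent | unclassified
    genotype: str   # WT | Tg


@dataclass(frozen=True)
class ApCaFit:
    """Linear AP-count -> Ca2+ amplitude calibration."""

    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int


def compute_dff(trace: FluorescenceTrace) -> DffTrace:
    """dF/F0 with F0 = mean of the lowest 20% of the samples.

    Raises if the baseline is non-physical (F0 <= 0, e.g. dark or negative
    fluorescence) or the trace is too short for the lowest-20% set.
    """
    f = trace.samples
    n = f.size
    if n < 5:
        raise ValueError(f"need at least 5 samples to form the lowest-20% baseline, got {n}")
    m = math.ceil(0.2 * n)
    f0 = float(np.partition(f, m - 1)[:m].mean())
    if f0 <= 0:
        raise ValueError(f"non-physical baseline F0 = {f0:g} (must be > 0)")
    return DffTrace((f - f0) / f0, trace.sampling_rate, f0)


def smooth_exponential(dff: DffTrace, tau_ms: float = 35.0) -> DffTrace:
    """Exponentially weighted (first-order recursive) smoothing.

    y[n] = a x[n] + (1 - a) y[n-1] with a = 1 - exp(-dt/tau) and y[0] = x[0];
    the filter has unit DC gain, so a constant trace is a fixed point.
    """
    if not tau_ms > 0:
        raise ValueError(f"tau_ms must be > 0, got {tau_ms}")
    x = dff.samples
    if x.size == 0:
        return DffTrace(x.copy(), dff.sampling_rate, dff.f0)
    dt = 1.0 / dff.sampling_rate
    a = 1.0 - math.exp(-dt / (tau_ms / 1000.0))
    y, _ = signal.lfilter([a], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * x[0]])
    return DffTrace(y, dff.sampling_rate, dff.f0)


def estimate_baseline_sd(dff: DffTrace) -> float:
    """Robust baseline-noise SD from first differences.

    1.4826 x MAD of the first differences, divided by sqrt(2): calibrated to
    the sample SD for white Gaussian noise and insensitive to sparse, slow
    transients, which contribute only a handful of large differences.
    """
    x = dff.samples
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    mad = float(np.median(np.abs(d - np.median(d))))
    return 1.4826 * mad / math.sqrt(2.0)


def detect_transients(
    dff: DffTrace,
    noise_sd: float,
    merge_window_ms: float = 50.0,
) -> TransientSet:
    """Threshold-crossing transient detection at 3x the baseline-noise SD.

    Amplitudes are excursions above the trace's baseline, taken as the
    median (the lowest-20% F0 convention leaves the quiescent dF/F level
    slightly above zero, by about 1.4 noise SDs, so an absolute threshold
    would sit too close to the noise floor).  Contiguous baseline-relative
    segments above 3*noise_sd each contribute one event at the first
    crossing, with amplitude equal to the segment maximum; segments
    separated by less than `merge_window_ms` are merged.  With noise_sd = 0
    every positive excursion is an event (degenerate but well defined).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    x = dff.samples
    if x.size:
        x = x - np.median(x)
    fs = dff.sampling_rate
    duration = x.size / fs
    above = x > 3.0 * noise_sd
    if not above.any():
        return TransientSet(np.empty(0), np.empty(0), duration)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [x.size]])
    gap = max(1, int(round(merge_window_ms / 1000.0 * fs)))
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - m_ends[-1] < gap:
            m_ends[-1] = e
        else:
            m_starts.append(s)
            m_ends.append(e)
    onsets = np.array(m_starts) / fs
    amps = np.array([x[s:e].max() for s, e in zip(m_starts, m_ends)])
    return TransientSet(onsets, amps, duration)


#: rate threshold (transients/min) separating hyperactive from normal
HYPERACTIVE_RATE = 4.0
#: minimum observation (s) for a hyperactive/normal decision (4 min)
MIN_ACTIVE_OBS_S = 240.0
#: minimum observation (s) for a silent decision (15 min)
MIN_SILENT_OBS_S = 900.0


def classify_neuron(transients: TransientSet, genotype: str) -> NeuronClass:
    """Activity class from the transient rate.

    Tg: rate > 4/min -> hyperactive; 0 < rate < 4 -> normal (>=4 min
    observation); zero transients over >=15 min -> silent; rate exactly
    4/min -> unclassified.  WT: at most one transient over a >=15 min
    observation -> silent; otherwise the same rate rules apply.
    """
    if genotype not in ("WT", "Tg"):
        raise ValueError(f"unknown genotype {genotype!r}; expected 'WT' or 'Tg'")
    d = transients.observation_duration
    c = transients.count
    r = transients.rate_per_min

    if genotype == "WT" and d >= MIN_SILENT_OBS_S and c <= 1:
        return NeuronClass("silent", genotype)
    if c == 0:
        if d < MIN_SILENT_OBS_S:
            raise InsufficientObservationError(
                f"silent classification needs >= {MIN_SILENT_OBS_S:.0f} s of "
                f"observation, got {d:.0f} s with no transients"
            )
        return NeuronClass("silent", genotype)
    if d < MIN_ACTIVE_OBS_S:
        raise InsufficientObservationError(
            f"rate classification needs >= {MIN_ACTIVE_OBS_S:.0f} s of observation, got {d:.0f} s"
        )
    if r > HYPERACTIVE_RATE:
        return NeuronClass("hyperactive", genotype)
    if r == HYPERACTIVE_RATE:
        return NeuronClass("unclassified", genotype)
    return NeuronClass("normal", genotype)


def fit_ap_ca_linearity(pairs: pd.DataFrame) -> ApCaFit:
    """OLS fit of Ca2+ transient amplitude on AP count.

    `pairs` needs columns ``ap_count`` and ``amplitude``; optional columns
    ``train_rate_hz`` and ``quiet_ms`` enable the inclusion filter: events
    with 1-4 APs, within-train rate above 20 Hz (single APs are always
    eligible), and a trailing quiet interval of at least 100 ms.  Excluded
    events are counted, not dropped silently.
    """
    required = {"ap_count", "amplitude"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing column(s) {sorted(missing)}")
    ap = pairs["ap_count"].to_numpy(dtype=float)
    amp = pairs["amplitude"].to_numpy(dtype=float)
    mask = (ap >= 1) & (ap <= 4)
    if "train_rate_hz" in pairs.columns:
        rate = pairs["train_rate_hz"].to_numpy(dtype=float)
        mask &= (ap == 1) | (rate > 20.0)
    if "quiet_ms" in pairs.columns:
        mask &= pairs["quiet_ms"].to_numpy(dtype=float) >= 100.0
    ap_u, amp_u = ap[mask], amp[mask]
    if np.unique(ap_u).size < 2:
        raise DegenerateDesignError(
            "AP-Ca2+ calibration needs at least two distinct AP counts after filtering"
        )
    X = np.column_stack([ap_u, np.ones_like(ap_u)])
    (slope, intercept), ssr_arr, *_ = np.linalg.lstsq(X, amp_u, rcond=None)
    fitted = X @ np.array([slope, intercept])
    ssr = float(np.sum((amp_u - fitted) ** 2))
    sst = float(np.sum((amp_u - amp_u.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return ApCaFit(float(slope), float(intercept), r2, int(mask.sum()), int((~mask).sum()))


def analyze_trace(
    trace: FluorescenceTrace,
    tau_ms: float = 35.0,
    noise_sd: float | None = None,
    merge_window_ms: float = 250.0,
) -> tuple[DffTrace, TransientSet, float]:
    """Convenience chain: dF/F -> noise SD -> smoothing -> detection.

    The baseline-noise SD is estimated on the raw dF/F trace (where the
    first-difference estimator is calibrated for white noise) and detection
    runs on the smoothed trace against 3x that SD; an explicit `noise_sd`
    overrides the estimate (useful for noiseless synthetic traces).  The
    default merge window is matched to the ~500 ms indicator decay: a
    transient hovers near threshold for ~100 ms on its way down, and the
    noise-driven re-crossings there must merge into one event.
    Returns (smoothed dF/F, transients, noise SD used).
    """
    dff = compute_dff(trace)
    sd = estimate_baseline_sd(dff) if noise_sd is None else noise_sd
    smoothed = smooth_exponential(dff, tau_ms=tau_ms)
    transients = detect_transients(smoothed, sd, merge_window_ms=merge_window_ms)
    return smoothed, transients, sd
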