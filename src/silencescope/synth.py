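"""Synthetic recordings with known ground truth for every analysis stage.

Emulates the study's four data families:

* somatic Ca2+ fluorescence traces (40/80 Hz) with class-specific transient
  rates (hyperactive, normal, silent, WT) and additive Gaussian noise,
* whole-cell voltage-clamp current traces (20 kHz) as Poisson trains of
  alpha-function PSCs with group-specific rates and lognormal amplitudes
  plus ~5 pA measurement noise,
* right-skewed per-region presynaptic-neuron count tables from rabies
  tracing, calibrated so the group-level mean totals default to the study
  scale (WT ~721, silent transgenic neurons ~85),
* dendritic spine-density tables with a per-mouse random effect plus
  per-neuron dendritic lengths.

Event times are Poisson in count; given the count, times are uniform
subject to a minimum gap (exact order-statistics construction), so that a
noiseless trace passed through the matching analysis stage recovers the
ground truth exactly.

All randomness flows from a single root seed with per-record derived
streams, so adding records does not perturb earlier ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcium import FluorescenceTrace
from .deconv import AlphaKernel, CurrentTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GROUPS",
    "CA_CLASSES",
    "REGIONS",
    "gen_ca_trace",
    "gen_ap_ca_pairs",
    "gen_vc_trace",
    "gen_connectivity_counts",
    "gen_spine_table",
]

GROUPS = ("WT", "Tg-SN", "Tg-NN", "Tg-HN")
CA_CLASSES = ("HN", "NN", "SN", "WT-silent")
REGIONS = ("M2", "M1", "S1", "FRA", "S2", "ORB", "INS", "ECT", "other")

#: default Ca2+ transient rates per class, events/min (inside each class band)
CA_RATES_PER_MIN = {"HN": 8.0, "NN": 2.0, "SN": 0.0, "WT-silent": 0.05}

#: default spontaneous PSC rates, Hz; excitatory input collapses in Tg-SN
VC_RATES_HZ = {
    "EPSC": {"WT": 5.0, "Tg-SN": 0.5, "Tg-NN": 2.5, "Tg-HN": 5.0},
    "IPSC": {"WT": 4.0, "Tg-SN": 0.4, "Tg-NN": 2.0, "Tg-HN": 4.0},
}

#: unitary-PSC kernel shapes; IPSCs have smaller k and longer tau than EPSCs
VC_KERNELS = {"EPSC": AlphaKernel(2.0, 0.003), "IPSC": AlphaKernel(1.5, 0.008)}

#: presynaptic-count calibration: mean total and coefficient of variation
CONNECTIVITY_MEAN = {"WT": 721.0, "Tg-SN": 85.0, "Tg-NN": 550.0, "Tg-HN": 600.0}
CONNECTIVITY_CV = {"WT": 180.0 / 721.0, "Tg-SN": 28.0 / 85.0, "Tg-NN": 0.3, "Tg-HN": 0.3}

#: relative weight of each cortical region among presynaptic neurons
REGION_WEIGHTS = {
    "M2": 0.42, "M1": 0.18, "S1": 0.12, "FRA": 0.08, "S2": 0.07,
    "ORB": 0.05, "INS": 0.04, "ECT": 0.02, "other": 0.02,
}

#: spine densities (spines/um) and dendritic lengths (um): all Tg reduced vs WT
SPINE_DENSITY_MEAN = {"WT": 0.45, "Tg-SN": 0.25, "Tg-NN": 0.38, "Tg-HN": 0.40}
DENDRITE_LENGTH_MEAN = {"WT": 3200.0, "Tg-SN": 2300.0, "Tg-NN": 2600.0, "Tg-HN": 2700.0}


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs mirroring the recording conditions.

    Defaults: two-photon imaging at 40 Hz, voltage clamp sampled at 20 kHz
    with ~5 pA measurement noise, Ca2+ noise 0.02 dF/F (SNR 10 for a
    single-AP transient of 0.2 dF/F).
    """

    seed: int = 0
    duration_s: float = 300.0
    fs_ca: float = 40.0
    fs_vc: float = 20_000.0
    noise_sd_vc: float = 5.0
    ca_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("fs_ca", "fs_vc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("duration_s",):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("noise_sd_vc", "ca_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def rng(self, *stream: int) -> np.random.Generator:
        """Derived random stream; distinct `stream` keys are independent."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=stream))


@dataclass
class GroundTruth:
    """The truth record real recordings lack: every generated event."""

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    ap_counts: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        if self.event_times.size > 1 and not np.all(np.diff(self.event_times) > 0):
            raise ValueError("ground-truth event times must be strictly increasing")
        if np.any(self.event_amplitudes <= 0):
            raise ValueError("ground-truth amplitudes must be > 0")

    def __len__(self) -> int:
        return int(self.event_times.size)


def _min_gap_times(
    rng: np.random.Generator, rate_hz: float, duration_s: float, min_gap_s: float
) -> np.ndarray:
    """Poisson-count event times, uniform given the count with a minimum gap.

    Draw n ~ Poisson(rate*T); place n points as sorted uniforms on
    [0, T - (n-1) g] and add i*g to the i-th order statistic.  The count is
    exactly Poisson and gaps are >= g by construction.
    """
    if rate_hz < 0:
        raise ValueError(f"rate must be >= 0, got {rate_hz}")
    n = int(rng.poisson(rate_hz * duration_s))
    while n > 1 and (n - 1) * min_gap_s >= duration_s:
        n -= 1  # density cap: cannot fit more events at this gap
    if n == 0:
        return np.empty(0)
    free = duration_s - (n - 1) * min_gap_s
    x = np.sort(rng.uniform(0.0, free, n))
    return x + min_gap_s * np.arange(n)


def gen_ca_trace(
    cls: str,
    cfg: SimConfig,
    rate_per_min: float | None = None,
    amp_per_ap: float = 0.2,
    decay_tau_s: float = 0.5,
    min_gap_s: float = 1.5,
    f_base: float = 100.0,
    stream: int = 0,
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Synthetic fluorescence trace for one neuron of activity class `cls`.

    Transients have an instantaneous rise and single-exponential decay
    (default tau 500 ms, a standard synthetic-indicator model), scaled by a
    1-4 AP count at `amp_per_ap` dF/F per AP, on a baseline `f_base` with
    additive Gaussian noise of SD ``cfg.ca_noise_sd * f_base``.  The default
    1.5-s minimum gap guarantees that a 4-AP transient decays below a
    3 x 0.02 dF/F detection threshold before the next event, so noiseless
    traces round-trip exactly through detection.
    """
    if cls not in CA_CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {CA_CLASSES}")
    rate = CA_RATES_PER_MIN[cls] if rate_per_min is None else rate_per_min
    if rate < 0:
        raise ValueError(f"rate_per_min must be >= 0, got {rate}")
    T = cfg.duration_s
    if cls in ("HN", "NN") and T < 60:
        raise ValueError(f"duration_s must be >= 60 s for class {cls}, got {T:g}")
    if cls in ("SN", "WT-silent") and T < 900:
        raise ValueError(f"duration_s must be >= 900 s for class {cls}, got {T:g}")

    rng = cfg.rng(0, stream)
    times = _min_gap_times(rng, rate / 60.0, T, min_gap_s)
    n_ev = times.size
    ap = rng.integers(1, 5, n_ev)
    amps = amp_per_ap * ap

    n = int(round(T * cfg.fs_ca))
    t = np.arange(n) / cfg.fs_ca
    sig = np.zeros(n)
    for t0, a in zip(times, amps):
        i0 = int(math.ceil(t0 * cfg.fs_ca))
        if i0 < n:
            sig[i0:] += a * np.exp(-(t[i0:] - t0) / decay_tau_s)
    f = f_base * (1.0 + sig)
    if cfg.ca_noise_sd > 0:
        f = f + rng.normal(0.0, cfg.ca_noise_sd * f_base, n)
    truth = GroundTruth(times, amps, ap, cls)
    return FluorescenceTrace(f, cfg.fs_ca), truth


def gen_ap_ca_pairs(
    n_events: int,
    slope: float,
    cfg: SimConfig,
    noise_sd: float = 0.05,
    intercept: float = 0.0,
    stream: int = 0,
) -> pd.DataFrame:
    """Paired AP-count / Ca2+-amplitude calibration events.

    Amplitudes are slope x AP count (+ intercept) plus Gaussian noise; all
    AP counts 1-4 are represented, within-train rates exceed 20 Hz and every
    event has a trailing quiet interval >= 100 ms, so the whole table passes
    the calibration inclusion filter.
    """
    if n_events < 4:
        raise ValueError(f"n_events must be >= 4 so all AP counts appear, got {n_events}")
    if not slope > 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    rng = cfg.rng(1, stream)
    ap = np.concatenate([np.arange(1, 5), rng.integers(1, 5, n_events - 4)])
    rng.shuffle(ap)
    amp = intercept + slope * ap
    if noise_sd > 0:
        amp = amp + rng.normal(0.0, noise_sd, n_events)
    train_rate = rng.uniform(25.0, 80.0, n_events)
    quiet = rng.uniform(120.0, 500.0, n_events)
    t = np.cumsum(rng.uniform(0.8, 2.0, n_events))
    return pd.DataFrame(
        {
            "event_time_s": t,
            "ap_count": ap.astype(int),
            "amplitude": amp,
            "train_rate_hz": train_rate,
            "quiet_ms": quiet,
        }
    )


def gen_vc_trace(
    group: str,
    ctype: str,
    cfg: SimConfig,
    rate_hz: float | None = None,
    amp_median_pA: float = 20.0,
    amp_sigma: float = 0.4,
    kernel: AlphaKernel | None = None,
    min_gap_s: float | None = None,
    stream: int = 0,
) -> tuple[CurrentTrace, GroundTruth]:
    """Synthetic voltage-clamp trace: Poisson alpha-PSC train plus noise.

    Events are emitted sign-positive with lognormal peak amplitudes
    (median `amp_median_pA`); the physiological polarity is recoverable
    from `ctype`.  Default rates order the groups Tg-SN << Tg-NN < WT ~
    Tg-HN for both current types.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if ctype not in VC_RATES_HZ:
        raise ValueError(f"unknown current type {ctype!r}; expected EPSC or IPSC")
    rate = VC_RATES_HZ[ctype][group] if rate_hz is None else rate_hz
    if rate < 0:
        raise ValueError(f"rate_hz must be >= 0, got {rate}")
    ker = VC_KERNELS[ctype] if kernel is None else kernel
    gap = 5.0 * ker.peak_time if min_gap_s is None else min_gap_s

    rng = cfg.rng(2, stream)
    T = cfg.duration_s
    # keep events clear of the trace end: a kernel truncated at the edge has
    # no peak to anchor on, so edge events would break exact round trips
    margin = min(2.0 * ker.duration(tol=1e-3), 0.25 * T)
    times = _min_gap_times(rng, rate, T - margin, gap)
    n_ev = times.size
    amps = np.exp(rng.normal(math.log(amp_median_pA), amp_sigma, n_ev))

    n = int(round(T * cfg.fs_vc))
    y = np.zeros(n)
    ku = ker.sample(cfg.fs_vc)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * cfg.fs_vc))
        if i0 < n:
            seg = ku[: n - i0]
            y[i0 : i0 + seg.size] += a * seg
    if cfg.noise_sd_vc > 0:
        y = y + rng.normal(0.0, cfg.noise_sd_vc, n)
    trace = CurrentTrace(y, cfg.fs_vc, ctype, None, group)
    return trace, GroundTruth(times, amps, None, group)


def gen_connectivity_counts(
    group: str,
    n_starters: int,
    cfg: SimConfig,
    mean_total: float | None = None,
    cv: float | None = None,
    ipsi_fraction: float = 0.8,
    stream: int = 0,
) -> pd.DataFrame:
    """Per-region presynaptic-neuron counts for `n_starters` starter neurons.

    Each starter's total is lognormal with arithmetic mean `mean_total`
    (group defaults calibrated to the study scale) and coefficient of
    variation `cv`; cv = 0 gives exactly the rounded mean.  The total is
    split multinomially across regions x hemispheres with an ipsilateral
    majority.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if n_starters < 1:
        raise ValueError(f"n_starters must be >= 1, got {n_starters}")
    mu = CONNECTIVITY_MEAN[group] if mean_total is None else mean_total
    c = CONNECTIVITY_CV[group] if cv is None else cv
    if mu < 0 or c < 0:
        raise ValueError("mean_total and cv must be >= 0")
    rng = cfg.rng(3, stream)
    s = math.sqrt(math.log(1.0 + c * c))
    w = np.array([REGION_WEIGHTS[r] for r in REGIONS])
    p = np.concatenate([w * ipsi_fraction, w * (1.0 - ipsi_fraction)])
    p = p / p.sum()
    rows = []
    for i in range(n_starters):
        total = int(round(mu * math.exp(rng.normal(-s * s / 2.0, s)))) if s > 0 else int(round(mu))
        cell = rng.multinomial(total, p)
        for j, region in enumerate(REGIONS):
            rows.append((f"{group}-{i + 1}", group, region, "ipsi", int(cell[j])))
            rows.append((f"{group}-{i + 1}", group, region, "contra", int(cell[j + len(REGIONS)])))
    return pd.DataFrame(rows, columns=["starter_id", "group", "region", "hemisphere", "count"])


def gen_spine_table(
    group: str,
    n_mice: int,
    neurons_per_mouse: int,
    segments_per_neuron: int,
    cfg: SimConfig,
    density_mean: float | None = None,
    mouse_sd: float = 0.03,
    segment_sd: float = 0.08,
    length_mean: float | None = None,
    length_sd: float = 300.0,
    stream: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spine-density segments and per-neuron dendritic lengths for one group.

    Per-segment density = group mean + mouse-level Gaussian random effect
    (SD `mouse_sd`) + segment noise (SD `segment_sd`), for apical and basal
    compartments.  Returns (segments, neurons): segments has one row per
    dendritic segment, neurons one row per neuron with its total dendritic
    length (group means reduced in all transgenic groups).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    for name, v in (
        ("n_mice", n_mice),
        ("neurons_per_mouse", neurons_per_mouse),
        ("segments_per_neuron", segments_per_neuron),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    dmu = SPINE_DENSITY_MEAN[group] if density_mean is None else density_mean
    lmu = DENDRITE_LENGTH_MEAN[group] if length_mean is None else length_mean
    rng = cfg.rng(4, stream)
    seg_rows, neuron_rows = [], []
    for m in range(n_mice):
        mouse = f"{group}-m{m + 1}"
        m_eff = rng.normal(0.0, mouse_sd) if mouse_sd > 0 else 0.0
        for nrn in range(neurons_per_mouse):
            neuron = f"{mouse}-n{nrn + 1}"
            length = lmu + (rng.normal(0.0, length_sd) if length_sd > 0 else 0.0)
            densities = []
            for comp in ("apical", "basal"):
                for s in range(segments_per_neuron):
                    d = dmu + m_eff + (rng.normal(0.0, segment_sd) if segment_sd > 0 else 0.0)
                    densities.append(d)
                    seg_rows.append((mouse, neuron, group, comp, s + 1, d))
            neuron_rows.append(
                (mouse, neuron, group, length, int(round(max(length, 0.0) * np.mean(densities))))
            )
    segments = pd.DataFrame(
        seg_rows, columns=["mouse", "neuron", "group", "compartment", "segment", "density"]
    )
    neurons = pd.DataFrame(
        neuron_rows, columns=["mouse", "neuron", "group", "dendritic_length_um", "total_spines"]
    )
    return segments, neurons
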