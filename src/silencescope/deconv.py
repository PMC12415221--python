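"""Parametric deconvolution of voltage-clamp current traces into unitary PSCs.

Spontaneous excitatory and inhibitory postsynaptic currents (EPSCs at a
holding potential of -80 mV, IPSCs at +10 mV) are modelled as a sum of
unitary alpha-function events

    u(t) = t**(k - 1) * exp(-t / tau),        k > 1, tau > 0,

placed at a predefined candidate set of onsets (anchored so kernel peaks
coincide with local maxima of the current trace).  Event amplitudes are
estimated by constrained least squares: nonnegative least squares followed
by iterative pruning of amplitudes below a noise floor (default 5 pA) and
refitting of the survivors, which yields a sparse event set whose surviving
amplitudes all exceed the floor.  Kernel shape (k, tau) is fitted per neuron
and per current type by minimising the post-fit residual over a bounded grid
with local refinement.

Amplitude convention: kernels are normalised to unit peak, so a fitted
amplitude is the event's peak current in pA.  Traces are analysed
sign-positive; the physiological polarity (inward EPSCs are negative
deflections at -80 mV) is metadata.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, signal, special

__all__ = [
    "AlphaKernel",
    "CurrentTrace",
    "EventSet",
    "SynapticSummary",
    "DeconvResult",
    "candidate_threshold",
    "find_candidate_times",
    "fit_amplitudes",
    "fit_kernel_params",
    "summarize_events",
    "deconvolve_neuron",
]

#: holding potentials (mV) consistent with each current type
HOLDING_MV = {"EPSC": -80.0, "IPSC": 10.0}


@dataclass(frozen=True)
class AlphaKernel:
    """Unitary PSC shape u(t) = t**(k-1) exp(-t/tau), normalised to unit peak.

    Parameters
    ----------
    k : float
        Dimensionless shape power, must exceed 1 (so the kernel rises from 0).
    tau : float
        Time constant in seconds.
    """

    k: float
    tau: float

    def __post_init__(self) -> None:
        if not self.k > 1:
            raise ValueError(f"kernel power k must be > 1, got {self.k}")
        if not self.tau > 0:
            raise ValueError(f"kernel tau must be > 0, got {self.tau}")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum, (k - 1) * tau, in seconds."""
        return (self.k - 1.0) * self.tau

    @property
    def unit_charge(self) -> float:
        """Integral of the unit-peak kernel (pA*s of charge per pA of peak).

        integral u dt = Gamma(k) tau**k; peak value ((k-1)tau)**(k-1) e**-(k-1).
        """
        k, tau = self.k, self.tau
        log_integral = special.gammaln(k) + k * math.log(tau)
        log_peak = (k - 1.0) * math.log((k - 1.0) * tau) - (k - 1.0)
        return math.exp(log_integral - log_peak)

    def duration(self, tol: float = 1e-5) -> float:
        """Time at which the unit-peak kernel has decayed below `tol`."""
        tp = self.peak_time
        # solve (t/tp)**(k-1) exp(-(t-tp)/tau) = tol by fixed point on t
        t = tp + self.tau * (-math.log(tol))
        for _ in range(8):
            t = tp + self.tau * ((self.k - 1.0) * math.log(t / tp) - math.log(tol))
        return t

    def sample(self, fs: float, tol: float = 1e-5, max_samples: int = 2_000_000) -> np.ndarray:
        """Unit-peak kernel sampled at `fs` Hz, truncated once decayed below `tol`."""
        n = min(max_samples, max(2, int(math.ceil(self.duration(tol) * fs))))
        t = np.arange(n) / fs
        tp = self.peak_time
        with np.errstate(divide="ignore"):
            logu = (self.k - 1.0) * np.log(t / tp) - (t - tp) / self.tau
        u = np.exp(logu)
        u[0] = 0.0
        return u


@dataclass
class CurrentTrace:
    """Whole-cell voltage-clamp current trace.

    samples are in pA; analysis operates on a sign-positive version of the
    trace.  If `holding_mV` is supplied it must match the current type
    (EPSC at -80 mV, IPSC at +10 mV).
    """

    samples: np.ndarray
    sampling_rate: float = 20_000.0
    ctype: str = "EPSC"
    holding_mV: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.ctype not in HOLDING_MV:
            raise ValueError(f"unknown current type {self.ctype!r}; expected EPSC or IPSC")
        if self.holding_mV is not None and self.holding_mV != HOLDING_MV[self.ctype]:
            raise ValueError(
                f"holding potential {self.holding_mV} mV inconsistent with "
                f"{self.ctype} (expected {HOLDING_MV[self.ctype]} mV)"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def rectified(self) -> "CurrentTrace":
        """Baseline-subtracted, sign-positive copy (events deflect upward)."""
        y = self.samples - np.median(self.samples)
        if -y.min() > y.max():
            y = -y
        return CurrentTrace(y, self.sampling_rate, self.ctype, None, self.group)


@dataclass
class EventSet:
    """Detected unitary events: kernel onset times (s) and peak amplitudes (pA)."""

    times: np.ndarray
    amplitudes: np.ndarray
    residual_rms: float
    floor: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SynapticSummary:
    """Per-neuron summary of the deconvolved synaptic input."""

    rate: float                       # events / s
    total_charge: float               # pA*s
    mean_amplitude: float             # pA (nan when no events)
    amplitudes_sorted: np.ndarray     # ascending peak amplitudes
    cumulative_fractions: np.ndarray  # cumulative fraction of events, ends at 1
    normalized_charge: float | None = None  # total_charge / reference (e.g. WT mean)


@dataclass
class DeconvResult:
    """All intermediates of a per-neuron deconvolution, for inspection."""

    events: EventSet
    summary: SynapticSummary
    kernel: AlphaKernel
    candidate_times: np.ndarray
    trace: CurrentTrace  # rectified trace the fit was run on


def _smoothing_weights(kernel: AlphaKernel, fs: float) -> np.ndarray:
    """Area-normalised kernel-shaped smoothing weights (a matched filter).

    Smoothing with the kernel's own shape is the minimum-variance way to
    locate events of that shape in white noise; a flat moving average leaves
    enough anchoring jitter to bias the kernel-shape fit noticeably.
    """
    w = kernel.sample(fs, tol=1e-3)
    return w / w.sum()


def _smoothed(trace: CurrentTrace, kernel: AlphaKernel) -> np.ndarray:
    """Kernel-matched smoothing of the trace (same-length output)."""
    y = trace.samples
    w = _smoothing_weights(kernel, trace.sampling_rate)
    if w.size <= 1 or y.size == 0:
        return y
    return signal.fftconvolve(y, w[::-1], mode="same")


def candidate_threshold(
    trace: CurrentTrace, kernel: AlphaKernel, floor_pA: float = 5.0
) -> float:
    """Height threshold for candidate maxima: max(floor/2, 4x smoothed-noise SD).

    The robust SD of the smoothed trace (1.4826 x MAD of differences at a
    lag beyond the filter support, / sqrt(2)) keeps per-noise-wiggle
    candidates rare while staying below the smoothed peak of any event at
    the amplitude floor; the floored constrained least squares still does
    the pruning.
    """
    ys = _smoothed(trace, kernel)
    # differences at a lag beyond the filter support: nearby smoothed
    # samples share their window, so short-lag differences would cancel
    # the very noise being estimated
    lag = _smoothing_weights(kernel, trace.sampling_rate).size
    if ys.size <= lag:
        return floor_pA / 2.0
    d = ys[lag:] - ys[:-lag]
    sd = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)
    return max(floor_pA / 2.0, 4.0 * sd)


def find_candidate_times(
    trace: CurrentTrace,
    kernel: AlphaKernel,
    min_height: float | None = None,
) -> np.ndarray:
    """Candidate event onsets: local maxima of the kernel-smoothed trace.

    The trace is smoothed with the kernel's own shape (a matched filter,
    the minimum-variance anchor for events of that shape in white noise);
    every local maximum above `min_height` (also required as prominence)
    is mapped back to the kernel onset via the deterministic argmax shift
    the filtering induces.  Onsets falling before the trace start are
    dropped.  For noisy traces pass `min_height` from
    :func:`candidate_threshold`.
    """
    y = trace.samples
    if y.size == 0:
        return np.empty(0)
    fs = trace.sampling_rate
    ys = _smoothed(trace, kernel)
    # floor the height at a relative epsilon: FFT-based smoothing leaves
    # ~1e-16-scale ripples on flat stretches that are not real maxima
    eps = 1e-9 * float(np.max(np.abs(ys))) if ys.size else 0.0
    h = eps if min_height is None else max(min_height, eps)
    # the prominence requirement suppresses noise wiggles riding on the
    # decaying tail of a large event, which clear an absolute height alone
    peaks, _ = signal.find_peaks(ys, height=h, prominence=h)
    # matched filtering shifts the kernel's argmax by a deterministic,
    # shape-dependent amount; subtract that shift instead of re-anchoring
    # on the raw trace, whose noisy argmax would jitter the onsets
    ku = kernel.sample(fs)
    w = _smoothing_weights(kernel, fs)
    if w.size > 1:
        pad = np.concatenate([np.zeros(w.size), ku, np.zeros(w.size)])
        ks = signal.fftconvolve(pad, w[::-1], mode="same")
        shift = int(np.argmax(ks)) - w.size - int(np.argmax(ku))
    else:
        shift = 0
    onsets = (peaks - shift) / fs - kernel.peak_time
    return onsets[onsets >= 0.0]


def _column_spans(n: int, fs: float, ker: np.ndarray, onsets: np.ndarray):
    """Start indices and truncated kernel columns for each onset."""
    starts = np.round(onsets * fs).astype(int)
    cols = []
    for s in starts:
        seg = ker[: n - s]
        cols.append(seg)
    return starts, cols


def _gram_nnls(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve min_x>=0  x'Gx - 2 b'x via a Cholesky factor of G."""
    m = b.size
    if m == 0:
        return np.empty(0)
    jitter = 1e-12 * (np.trace(G) / m + 1.0)
    for _ in range(6):
        try:
            L = np.linalg.cholesky(G + jitter * np.eye(m))
            break
        except np.linalg.LinAlgError:
            jitter *= 1e3
    else:  # pragma: no cover - pathological Gram matrix
        raise np.linalg.LinAlgError("Gram matrix could not be factorised")
    c = linalg.solve_triangular(L, b, lower=True)
    x, _ = optimize.nnls(L.T, c)
    return x


def fit_amplitudes(
    trace: CurrentTrace,
    kernel: AlphaKernel,
    candidate_times: np.ndarray,
    floor_pA: float = 5.0,
) -> EventSet:
    """Constrained least-squares amplitudes at the candidate onsets.

    Minimises ||y - sum_i a_i u(t - t_i)||^2 with the sparse constraint
    a_i in {0} U [floor, inf): nonnegative least squares, then iteratively
    zero every amplitude below the floor and refit the survivors until all
    surviving amplitudes are at or above the floor.
    """
    if floor_pA < 0:
        raise ValueError(f"floor_pA must be >= 0, got {floor_pA}")
    y = trace.samples
    n = y.size
    fs = trace.sampling_rate
    cand = np.sort(np.asarray(candidate_times, dtype=float))
    # collapse candidates that round to the same sample
    idx = np.round(cand * fs).astype(int)
    if idx.size:
        keep = np.concatenate([[True], np.diff(idx) > 0])
        cand, idx = cand[keep], idx[keep]
    inside = idx < n - 1
    if not inside.all():
        warnings.warn("dropping candidate onsets beyond the trace end", stacklevel=2)
        cand, idx = cand[inside], idx[inside]
    m = cand.size
    if m == 0:
        rms = float(np.sqrt(np.mean(y**2))) if n else 0.0
        return EventSet(np.empty(0), np.empty(0), rms, floor_pA)

    ker = kernel.sample(fs)
    starts, cols = _column_spans(n, fs, ker, cand)
    klen = ker.size

    # b_i = <y, col_i>;  G_ij = <col_i, col_j>, banded in the sorted onsets
    b = np.array([y[s : s + c.size] @ c for s, c in zip(starts, cols)])
    G = np.zeros((m, m))
    for i in range(m):
        ci, si = cols[i], starts[i]
        G[i, i] = ci @ ci
        for j in range(i + 1, m):
            sj = starts[j]
            lag = sj - si
            if lag >= klen or lag >= ci.size:
                break
            ov = min(ci.size - lag, cols[j].size)
            G[i, j] = G[j, i] = ci[lag : lag + ov] @ cols[j][:ov]

    active = np.arange(m)
    amps = np.zeros(m)
    while active.size:
        x = _gram_nnls(G[np.ix_(active, active)], b[active])
        low = x < floor_pA if floor_pA > 0 else x <= 0.0
        if not low.any():
            amps[active] = x
            break
        active = active[~low]

    surv = amps > 0 if floor_pA == 0 else amps >= floor_pA
    times = cand[surv]
    a_out = amps[surv]

    resid = y.copy()
    for t0, a, s, c in zip(cand, amps, starts, cols):
        if a > 0:
            resid[s : s + c.size] -= a * c
    rms = float(np.sqrt(np.mean(resid**2)))
    return EventSet(times, a_out, rms, floor_pA)


def _total_ssr(
    traces: list[CurrentTrace], kernel: AlphaKernel, floor_pA: float
) -> float:
    ssr = 0.0
    for tr in traces:
        h = candidate_threshold(tr, kernel, floor_pA)
        cand = find_candidate_times(tr, kernel, min_height=h)
        ev = fit_amplitudes(tr, kernel, cand, floor_pA)
        ssr += ev.residual_rms**2 * tr.samples.size
    return ssr


def fit_kernel_params(
    traces: list[CurrentTrace] | CurrentTrace,
    ctype: str | None = None,
    floor_pA: float = 5.0,
    k_bounds: tuple[float, float] = (1.1, 6.0),
    tau_bounds: tuple[float, float] = (0.5e-3, 50e-3),
    grid_shape: tuple[int, int] = (6, 7),
    refine: bool = True,
) -> AlphaKernel:
    """Kernel shape (k, tau) minimising the post-fit residual over the traces.

    A bounded grid (k linear in `k_bounds`, tau logarithmic in `tau_bounds`)
    is evaluated first, then the best point is refined with Nelder-Mead.
    Fitted per neuron and per current type; all traces must share a type.
    """
    if isinstance(traces, CurrentTrace):
        traces = [traces]
    if not traces:
        raise ValueError("at least one trace is required to fit a kernel")
    ctypes = {tr.ctype for tr in traces}
    if len(ctypes) > 1:
        raise ValueError(f"traces mix current types {sorted(ctypes)}")
    if ctype is not None and ctypes != {ctype}:
        raise ValueError(f"traces have ctype {ctypes.pop()!r}, expected {ctype!r}")
    if all(np.ptp(tr.samples) == 0 for tr in traces):
        raise ValueError("flat traces: kernel shape is unidentifiable")

    lo = np.log

    def objective(p: np.ndarray) -> float:
        k, ltau = p
        if not (k_bounds[0] <= k <= k_bounds[1]) or not (
            lo(tau_bounds[0]) <= ltau <= lo(tau_bounds[1])
        ):
            return np.inf
        return _total_ssr(traces, AlphaKernel(k, math.exp(ltau)), floor_pA)

    ks = np.linspace(k_bounds[0], k_bounds[1], grid_shape[0])
    taus = np.geomspace(tau_bounds[0], tau_bounds[1], grid_shape[1])
    best, best_ssr = None, np.inf
    for k in ks:
        for tau in taus:
            ssr = objective(np.array([k, lo(tau)]))
            if ssr < best_ssr:
                best, best_ssr = (k, tau), ssr
    if best is None:  # pragma: no cover
        raise ValueError("kernel grid search failed")
    if refine:
        # local grid around the coarse best: the residual valley is narrow,
        # so Nelder-Mead needs a start inside it and a small initial simplex
        for _ in range(2):
            kf = np.unique(np.clip(best[0] * np.array([0.85, 0.93, 1.0, 1.08, 1.18]), *k_bounds))
            tf = np.unique(np.clip(best[1] * np.array([0.85, 0.93, 1.0, 1.08, 1.18]), *tau_bounds))
            for k in kf:
                for tau in tf:
                    ssr = objective(np.array([k, lo(tau)]))
                    if ssr < best_ssr:
                        best, best_ssr = (float(k), float(tau)), ssr
        x0 = np.array([best[0], lo(best[1])])
        simplex = np.array([x0, x0 + [0.02 * best[0], 0.0], x0 + [0.0, 0.02]])
        res = optimize.minimize(
            objective,
            x0=x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-4,
                "fatol": best_ssr * 1e-8 + 1e-15,
                "maxfev": 200,
                "initial_simplex": simplex,
            },
        )
        if np.isfinite(res.fun) and res.fun <= best_ssr:
            best = (float(res.x[0]), float(math.exp(res.x[1])))
    return AlphaKernel(*best)


def summarize_events(
    events: EventSet,
    kernel: AlphaKernel,
    duration_s: float,
    reference_charge: float | None = None,
) -> SynapticSummary:
    """Rate, total charge, and cumulative amplitude distribution of an event set.

    total_charge = sum of amplitudes x unit kernel charge.  An empty event
    set is a valid silent-neuron output (rate 0, charge 0).  If
    `reference_charge` (e.g. the WT group mean) is given, `normalized_charge`
    is total_charge divided by it.
    """
    if not duration_s > 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    amps = np.sort(events.amplitudes)
    n = amps.size
    rate = n / duration_s
    total_charge = float(amps.sum() * kernel.unit_charge)
    mean_amp = float(amps.mean()) if n else float("nan")
    cum = np.arange(1, n + 1) / n if n else np.empty(0)
    norm = total_charge / reference_charge if reference_charge else None
    return SynapticSummary(rate, total_charge, mean_amp, amps, cum, norm)


def deconvolve_neuron(
    raw: CurrentTrace,
    kernel: AlphaKernel | None = None,
    floor_pA: float = 5.0,
    reference_charge: float | None = None,
) -> DeconvResult:
    """Full per-neuron pipeline: rectify, fit kernel, detect, fit, summarise.

    If `kernel` is given (e.g. fitted once per current type on calibration
    traces) the per-neuron kernel fit is skipped.
    """
    tr = raw.rectified()
    if kernel is None:
        kernel = fit_kernel_params([tr], floor_pA=floor_pA)
    cand = find_candidate_times(tr, kernel, min_height=candidate_threshold(tr, kernel, floor_pA))
    events = fit_amplitudes(tr, kernel, cand, floor_pA)
    summary = summarize_events(events, kernel, tr.duration, reference_charge)
    return DeconvResult(events, summary, kernel, cand, tr)
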