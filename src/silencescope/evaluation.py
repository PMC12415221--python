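"""Validation suite: quantitative checks of every analysis stage.

Each function simulates data with :mod:`silencescope.synth`, runs the
corresponding analysis stage, and returns a dict of measured quantities
(biases, error rates, recovery errors, calibration levels).  They are used
both by the test suite and by ``scripts/acceptance.py``.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import optimize

from . import calcium, connectivity, deconv, stats, synth

__all__ = [
    "exhaustive_best_subset",
    "run_oracle_equivalence",
    "run_deconv_recovery",
    "run_kernel_recovery",
    "run_classification",
    "run_anova_calibration",
    "run_lmm_calibration",
    "run_cohort_power",
    "run_epsc_ordering",
]


# ---------------------------------------------------------------------------
# brute-force constrained-LSQ oracle

def exhaustive_best_subset(
    trace: deconv.CurrentTrace,
    kernel: deconv.AlphaKernel,
    candidate_times: np.ndarray,
    floor_pA: float = 5.0,
) -> float:
    """Globally optimal SSR of the sparse floored least-squares problem.

    Enumerates every support subset of the candidates and solves the
    bound-constrained least squares (amplitudes >= floor on the support)
    with ``scipy.optimize.lsq_linear``; returns the minimum residual sum of
    squares.  Exponential in the candidate count — a reference for small
    instances only, independent of the prune-and-refit path it checks.
    """
    y = trace.samples
    fs = trace.sampling_rate
    ker = kernel.sample(fs)
    cand = np.sort(np.asarray(candidate_times, dtype=float))
    m = cand.size
    if m > 12:
        raise ValueError(f"exhaustive oracle limited to <= 12 candidates, got {m}")
    n = y.size
    A = np.zeros((n, m))
    for j, t0 in enumerate(cand):
        s = int(round(t0 * fs))
        seg = ker[: n - s]
        A[s : s + seg.size, j] = seg
    best = float(np.sum(y**2))  # empty support
    for r in range(1, m + 1):
        for supp in itertools.combinations(range(m), r):
            As = A[:, list(supp)]
            res = optimize.lsq_linear(As, y, bounds=(floor_pA, np.inf), method="bvls")
            ssr = float(np.sum((As @ res.x - y) ** 2))
            if ssr < best:
                best = ssr
    return best


def run_oracle_equivalence(
    seed: int, n_traces: int = 100, floor_pA: float = 5.0
) -> dict:
    """Prune-and-refit vs exhaustive best-subset on short few-event traces.

    Generates `n_traces` 0.25-s traces (20 kHz, 3 pA noise, 2-6 true events
    of 8-40 pA); candidates are capped at the 6 highest local maxima so the
    2**m enumeration stays exact.  Reports the fraction of traces whose
    prune-and-refit SSR is within 1% of the exhaustive optimum and the
    worst SSR ratio.
    """
    kernel = synth.VC_KERNELS["EPSC"]
    rng = np.random.default_rng(seed)
    ratios = []
    for i in range(n_traces):
        cfg = synth.SimConfig(seed=int(rng.integers(2**31)), duration_s=0.25,
                              noise_sd_vc=3.0)
        n_ev = int(rng.integers(2, 7))
        rate = n_ev / cfg.duration_s
        trace, _ = synth.gen_vc_trace(
            "WT", "EPSC", cfg, rate_hz=rate, amp_median_pA=18.0, amp_sigma=0.35
        )
        cand = deconv.find_candidate_times(
            trace, kernel, min_height=deconv.candidate_threshold(trace, kernel, floor_pA)
        )
        if cand.size > 6:
            # keep the 6 largest smoothed peaks
            y = trace.samples
            heights = [y[int(round(t * cfg.fs_vc)) : int(round(t * cfg.fs_vc)) + 80].max()
                       for t in cand]
            cand = np.sort(cand[np.argsort(heights)[-6:]])
        ev = deconv.fit_amplitudes(trace, kernel, cand, floor_pA)
        ssr = ev.residual_rms**2 * trace.samples.size
        best = exhaustive_best_subset(trace, kernel, cand, floor_pA)
        ratios.append(ssr / best if best > 0 else 1.0)
    ratios = np.asarray(ratios)
    return {
        "n": n_traces,
        "fraction_within_1pct": float(np.mean(ratios <= 1.01)),
        "max_ssr_ratio": float(ratios.max()),
    }


# ---------------------------------------------------------------------------
# deconvolution recovery

def _match_events(true_t, true_a, est_t, est_a, tol_s=0.005):
    """Greedy nearest-time matching of estimated to true events."""
    used = np.zeros(est_t.size, dtype=bool)
    pairs = []
    for t, a in zip(true_t, true_a):
        if est_t.size == 0:
            break
        d = np.abs(est_t - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            pairs.append((a, est_a[j]))
    return pairs


def run_deconv_recovery(
    seed: int,
    n_per_group: int = 50,
    duration_s: float = 8.0,
    n_noise_traces: int = 50,
) -> dict:
    """Event-rate / charge bias, amplitude RMSE, and false-positive rate.

    Simulates `n_per_group` EPSC traces per experimental group at 5 pA
    noise, deconvolves with a kernel fitted once on separate calibration
    traces, and compares pooled estimates with the generator's ground
    truth.  False positives are measured on pure-noise traces.
    """
    cal_cfg = synth.SimConfig(seed=seed, duration_s=3.0)
    cal = [synth.gen_vc_trace("WT", "EPSC", cal_cfg, stream=900 + i)[0] for i in range(2)]
    kernel = deconv.fit_kernel_params([tr.rectified() for tr in cal])

    out = {"kernel_k": kernel.k, "kernel_tau_ms": kernel.tau * 1e3}
    biases_rate, biases_charge = {}, {}
    sq_err, n_matched = 0.0, 0
    for g in synth.GROUPS:
        true_rate = true_charge = est_rate = est_charge = 0.0
        for i in range(n_per_group):
            cfg = synth.SimConfig(seed=seed, duration_s=duration_s)
            trace, truth = synth.gen_vc_trace(g, "EPSC", cfg, stream=i + 1000 * (1 + synth.GROUPS.index(g)))
            res = deconv.deconvolve_neuron(trace, kernel=kernel)
            true_rate += len(truth) / duration_s
            est_rate += res.summary.rate
            true_charge += truth.event_amplitudes.sum() * kernel.unit_charge
            est_charge += res.summary.total_charge
            for a_true, a_est in _match_events(
                truth.event_times, truth.event_amplitudes,
                res.events.times, res.events.amplitudes,
            ):
                sq_err += (a_true - a_est) ** 2
                n_matched += 1
        biases_rate[g] = (est_rate - true_rate) / true_rate if true_rate else 0.0
        biases_charge[g] = (est_charge - true_charge) / true_charge if true_charge else 0.0

    fp_events = 0.0
    for i in range(n_noise_traces):
        cfg = synth.SimConfig(seed=seed, duration_s=duration_s)
        trace, _ = synth.gen_vc_trace("WT", "EPSC", cfg, rate_hz=0.0, stream=5000 + i)
        res = deconv.deconvolve_neuron(trace, kernel=kernel)
        fp_events += len(res.events)
    out.update(
        {
            "n_per_group": n_per_group,
            "rate_bias": biases_rate,
            "charge_bias": biases_charge,
            "max_abs_rate_bias": float(max(abs(v) for v in biases_rate.values())),
            "max_abs_charge_bias": float(max(abs(v) for v in biases_charge.values())),
            "amplitude_rmse_pA": float(math.sqrt(sq_err / n_matched)) if n_matched else float("nan"),
            "false_positive_rate_hz": float(fp_events / (n_noise_traces * duration_s)),
        }
    )
    return out


def run_kernel_recovery(seed: int, duration_s: float = 4.0, n_traces: int = 3) -> dict:
    """Kernel (k, tau) recovery, noiseless and at 5 pA noise, for both types.

    Also checks that kernels fitted to EPSC- vs IPSC-generated sets
    preserve the physiological ordering (IPSCs: smaller k, longer tau).
    """
    out = {}
    fitted = {}
    for ctype in ("EPSC", "IPSC"):
        truth = synth.VC_KERNELS[ctype]
        for label, noise in (("noiseless", 0.0), ("noise5pA", 5.0)):
            cfg = synth.SimConfig(seed=seed, duration_s=duration_s, noise_sd_vc=noise)
            traces = [
                synth.gen_vc_trace("WT", ctype, cfg, rate_hz=4.0, stream=i)[0].rectified()
                for i in range(n_traces)
            ]
            est = deconv.fit_kernel_params(traces, ctype=ctype)
            out[f"{ctype}_{label}_k_err"] = abs(est.k - truth.k) / truth.k
            out[f"{ctype}_{label}_tau_err"] = abs(est.tau - truth.tau) / truth.tau
            fitted[(ctype, label)] = est
    for label in ("noiseless", "noise5pA"):
        e, i = fitted[("EPSC", label)], fitted[("IPSC", label)]
        out[f"ordering_preserved_{label}"] = bool(i.k < e.k and i.tau > e.tau)
    return out


# ---------------------------------------------------------------------------
# calcium classification

_COHORT_CLASSES = ("HN", "NN", "SN", "WT-silent")


def _truth_label(truth: synth.GroundTruth, duration: float, genotype: str) -> str:
    ts = calcium.TransientSet(
        truth.event_times,
        np.maximum(truth.event_amplitudes, 1e-12),
        duration,
    )
    return calcium.classify_neuron(ts, genotype).label


def run_classification(seed: int, n_neurons: int = 50, noiseless: bool = False) -> dict:
    """Label accuracy on a mixed 50-neuron cohort.

    The reference label is obtained by applying the classification rules to
    the generator's true event times, so the check isolates detection +
    classification from Poisson sampling of the rates.  Noiseless traces
    are detected against a nominal noise SD (the estimator would return 0).
    """
    rng = np.random.default_rng(seed)
    classes = [
        _COHORT_CLASSES[i % len(_COHORT_CLASSES)] for i in range(n_neurons)
    ]
    rng.shuffle(classes)
    correct = 0
    rate4_label = calcium.classify_neuron(
        calcium.TransientSet(np.arange(24) * 15.0 + 1.0, np.full(24, 0.5), 360.0), "Tg"
    ).label
    for i, cls in enumerate(classes):
        duration = 300.0 if cls in ("HN", "NN") else 960.0
        cfg = synth.SimConfig(
            seed=seed, duration_s=duration, ca_noise_sd=0.0 if noiseless else 0.02
        )
        trace, truth = synth.gen_ca_trace(cls, cfg, stream=i)
        genotype = "WT" if cls == "WT-silent" else "Tg"
        if noiseless:
            _, transients, _ = calcium.analyze_trace(trace, noise_sd=0.02)
        else:
            _, transients, _ = calcium.analyze_trace(trace)
        label = calcium.classify_neuron(transients, genotype).label
        if label == _truth_label(truth, trace.duration, genotype):
            correct += 1
    return {
        "n": n_neurons,
        "accuracy": correct / n_neurons,
        "rate_exactly_4_label": rate4_label,
    }


# ---------------------------------------------------------------------------
# statistics calibration

def run_anova_calibration(
    seed: int, n_sims: int = 10_000, n_groups: int = 4, n_per_group: int = 8
) -> dict:
    """Type-I error of the one-way ANOVA under the global null."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    rejections = 0
    for _ in range(n_sims):
        df = pd.DataFrame({"value": rng.normal(size=groups.size), "group": groups})
        if stats.anova_oneway(df).p < 0.05:
            rejections += 1
    return {"n": n_sims, "type1_error": rejections / n_sims}


def run_lmm_calibration(
    seed: int,
    n_sims: int = 500,
    n_groups: int = 4,
    mice_per_group: int = 5,
    segments_per_mouse: int = 6,
    mouse_sd: float = 0.1,
    segment_sd: float = 0.08,
) -> dict:
    """Type-I error of the mixed-model group test: strong mouse effect, no group effect."""
    rng = np.random.default_rng(seed)
    groups = [f"g{i}" for i in range(n_groups)]
    rej = 0
    for _ in range(n_sims):
        rows = []
        for g in groups:
            for m in range(mice_per_group):
                mouse = f"{g}-m{m}"
                eff = rng.normal(0.0, mouse_sd)
                vals = 0.4 + eff + rng.normal(0.0, segment_sd, segments_per_mouse)
                rows += [(mouse, g, v) for v in vals]
        df = pd.DataFrame(rows, columns=["mouse", "group", "density"])
        if stats.lmm_spine_density(df).p < 0.05:
            rej += 1
    return {"n": n_sims, "type1_error": rej / n_sims}


# ---------------------------------------------------------------------------
# end-to-end cohort properties

def run_cohort_power(seed: int, n_cohorts: int = 100, alpha: float = 0.01) -> dict:
    """Connectivity ANOVA power at the study's sample sizes.

    For each simulated cohort (6/5/6/6 starters, group means 721/85/550/600)
    checks that the ANOVA on log-transformed totals rejects at `alpha` and
    that the Tg-SN vs WT contrast has the smallest pairwise p-value.
    """
    n_starters = {"WT": 6, "Tg-SN": 5, "Tg-NN": 6, "Tg-HN": 6}
    hits = 0
    for c in range(n_cohorts):
        cfg = synth.SimConfig(seed=seed, duration_s=1.0)
        counts = pd.concat(
            [
                synth.gen_connectivity_counts(g, n, cfg, stream=c * 10 + j)
                for j, (g, n) in enumerate(n_starters.items())
            ],
            ignore_index=True,
        )
        fit = connectivity.compare_groups(connectivity.total_per_starter(counts))
        pw = fit.pairwise
        key = pw.apply(lambda r: frozenset((r["group1"], r["group2"])), axis=1)
        p_snwt = float(pw.loc[key == frozenset(("Tg-SN", "WT")), "p"].iloc[0])
        if fit.p < alpha and p_snwt <= pw["p"].min() + 1e-15:
            hits += 1
    return {"n": n_cohorts, "fraction_reject_and_snwt_smallest": hits / n_cohorts}


def run_epsc_ordering(
    seed: int, n_per_group: int = 6, duration_s: float = 8.0
) -> dict:
    """Group ordering of deconvolved excitatory rate and charge.

    Checks the study's qualitative pattern Tg-SN << Tg-NN < WT ~ Tg-HN on
    group-mean EPSC event rate and total charge estimated from synthetic
    traces ("<<" as less than half, "~" as within 25%).
    """
    cal_cfg = synth.SimConfig(seed=seed, duration_s=3.0)
    cal = [synth.gen_vc_trace("WT", "EPSC", cal_cfg, stream=900 + i)[0] for i in range(2)]
    kernel = deconv.fit_kernel_params([tr.rectified() for tr in cal])
    rates, charges = {}, {}
    for j, g in enumerate(synth.GROUPS):
        rs, cs = [], []
        for i in range(n_per_group):
            cfg = synth.SimConfig(seed=seed, duration_s=duration_s)
            trace, _ = synth.gen_vc_trace(g, "EPSC", cfg, stream=100 * j + i)
            res = deconv.deconvolve_neuron(trace, kernel=kernel)
            rs.append(res.summary.rate)
            cs.append(res.summary.total_charge)
        rates[g] = float(np.mean(rs))
        charges[g] = float(np.mean(cs))

    def ordered(d: dict) -> bool:
        return (
            d["Tg-SN"] < 0.5 * d["Tg-NN"]
            and d["Tg-NN"] < d["WT"]
            and abs(d["WT"] - d["Tg-HN"]) <= 0.25 * d["WT"]
        )

    return {
        "n_per_group": n_per_group,
        "mean_rate_hz": rates,
        "mean_total_charge": charges,
        "rate_ordering_ok": bool(ordered(rates)),
        "charge_ordering_ok": bool(ordered(charges)),
    }
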