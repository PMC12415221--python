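"""Unit and property tests for the alpha-kernel PSC deconvolution."""
import math

import numpy as np
import pytest
from scipy import integrate

from silencescope import deconv, synth
from silencescope.deconv import AlphaKernel, CurrentTrace

FS = 20_000.0
EPSC = synth.VC_KERNELS["EPSC"]


def alpha_trace(events, kernel=EPSC, duration=1.0, fs=FS, noise_sd=0.0, seed=0):
    """Trace as an explicit sum of unit-peak alpha kernels."""
    n = int(duration * fs)
    y = np.zeros(n)
    ku = kernel.sample(fs)
    for t0, a in events:
        i0 = int(round(t0 * fs))
        seg = ku[: n - i0]
        y[i0 : i0 + seg.size] += a * seg
    if noise_sd:
        y += np.random.default_rng(seed).normal(0, noise_sd, n)
    return CurrentTrace(y, fs, "EPSC")


class TestAlphaKernel:
    def test_peak_time_and_unit_peak(self):
        k = AlphaKernel(2.0, 0.003)
        u = k.sample(FS)
        assert u.argmax() / FS == pytest.approx(k.peak_time, abs=1.0 / FS)
        assert u.max() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k,tau", [(2.0, 0.003), (1.5, 0.008), (3.7, 0.0012)])
    def test_unit_charge_matches_numerical_integral(self, k, tau):
        ker = AlphaKernel(k, tau)
        u = ker.sample(FS, tol=1e-9)
        num = integrate.trapezoid(u, dx=1.0 / FS)
        assert ker.unit_charge == pytest.approx(num, rel=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AlphaKernel(1.0, 0.003)
        with pytest.raises(ValueError):
            AlphaKernel(2.0, 0.0)

    def test_holding_consistency(self):
        with pytest.raises(ValueError, match="holding"):
            CurrentTrace(np.zeros(10), FS, "EPSC", holding_mV=10.0)
        CurrentTrace(np.zeros(10), FS, "IPSC", holding_mV=10.0)  # consistent


class TestCandidates:
    def test_single_event_one_candidate(self):
        tr = alpha_trace([(0.1, 30.0)])
        cand = deconv.find_candidate_times(tr, EPSC)
        assert cand.size == 1
        assert cand[0] == pytest.approx(0.1, abs=1.0 / FS)

    def test_monotone_trace_has_no_candidates(self):
        tr = CurrentTrace(np.linspace(0, 50, 1000), FS, "EPSC")
        assert deconv.find_candidate_times(tr, EPSC).size == 0

    def test_two_events_five_tau_apart(self):
        dt = 5 * EPSC.tau
        tr = alpha_trace([(0.1, 30.0), (0.1 + dt, 25.0)])
        cand = deconv.find_candidate_times(tr, EPSC)
        assert cand.size == 2
        # the second anchor may sit a few samples early on the first event's
        # decaying tail; the amplitude fit is insensitive at this offset
        np.testing.assert_allclose(cand, [0.1, 0.1 + dt], atol=4.0 / FS)

    def test_empty_trace(self):
        tr = CurrentTrace(np.empty(0), FS, "EPSC")
        assert deconv.find_candidate_times(tr, EPSC).size == 0


class TestFitAmplitudes:
    def test_exact_amplitude_recovery(self):
        tr = alpha_trace([(0.1, 30.0)])
        ev = deconv.fit_amplitudes(tr, EPSC, np.array([0.1]))
        assert len(ev) == 1
        assert ev.amplitudes[0] == pytest.approx(30.0, abs=0.1)

    def test_below_floor_event_dropped(self):
        tr = alpha_trace([(0.1, 3.0)])
        ev = deconv.fit_amplitudes(tr, EPSC, np.array([0.1]), floor_pA=5.0)
        assert len(ev) == 0

    def test_onset_beyond_trace_warns_and_drops(self):
        tr = alpha_trace([(0.1, 30.0)], duration=0.5)
        with pytest.warns(UserWarning, match="beyond"):
            ev = deconv.fit_amplitudes(tr, EPSC, np.array([0.1, 0.9]))
        assert len(ev) == 1

    def test_floor_invariant_on_noisy_traces(self):
        for seed in range(5):
            cfg = synth.SimConfig(seed=seed, duration_s=2.0)
            tr, _ = synth.gen_vc_trace("WT", "EPSC", cfg)
            res = deconv.deconvolve_neuron(tr, kernel=EPSC)
            assert np.all(res.events.amplitudes >= res.events.floor)

    def test_amplitudes_are_least_squares_on_support(self, rng):
        """Random perturbations on the surviving support never reduce the SSR."""
        cfg = synth.SimConfig(seed=3, duration_s=2.0)
        tr, _ = synth.gen_vc_trace("WT", "EPSC", cfg)
        trr = tr.rectified()
        res = deconv.deconvolve_neuron(tr, kernel=EPSC)
        y = trr.samples
        ku = EPSC.sample(FS)

        def ssr(amps):
            r = y.copy()
            for t0, a in zip(res.events.times, amps):
                i0 = int(round(t0 * FS))
                seg = ku[: y.size - i0]
                r[i0 : i0 + seg.size] -= a * seg
            return float(np.sum(r**2))

        base = ssr(res.events.amplitudes)
        for _ in range(10):
            pert = res.events.amplitudes + rng.normal(0, 0.5, len(res.events))
            assert ssr(pert) >= base - 1e-6 * base


class TestKernelFit:
    def test_grid_only_matches_exhaustive_grid(self):
        cfg = synth.SimConfig(seed=9, duration_s=1.5, noise_sd_vc=0.0)
        tr = synth.gen_vc_trace("WT", "EPSC", cfg, rate_hz=4.0)[0].rectified()
        got = deconv.fit_kernel_params([tr], refine=False, grid_shape=(4, 4))
        # independent oracle: evaluate the same grid exhaustively
        ks = np.linspace(1.1, 6.0, 4)
        taus = np.geomspace(0.5e-3, 50e-3, 4)
        best, best_ssr = None, np.inf
        for k in ks:
            for tau in taus:
                ssr = deconv._total_ssr([tr], AlphaKernel(k, tau), 5.0)
                if ssr < best_ssr:
                    best, best_ssr = (k, tau), ssr
        assert (got.k, got.tau) == pytest.approx(best)

    def test_flat_trace_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            deconv.fit_kernel_params([CurrentTrace(np.zeros(1000), FS, "EPSC")])

    def test_mixed_ctypes_rejected(self):
        a = CurrentTrace(np.ones(100), FS, "EPSC")
        b = CurrentTrace(np.ones(100), FS, "IPSC")
        with pytest.raises(ValueError, match="mix"):
            deconv.fit_kernel_params([a, b])


class TestSummaries:
    def test_empty_event_set_is_valid_silent_output(self):
        ev = deconv.EventSet(np.empty(0), np.empty(0), 1.0, 5.0)
        s = deconv.summarize_events(ev, EPSC, 10.0)
        assert s.rate == 0.0 and s.total_charge == 0.0

    def test_charge_against_trapezoidal_integration(self):
        times = 0.5 + np.arange(10) * 0.9
        ev = deconv.EventSet(times, np.full(10, 20.0), 0.0, 5.0)
        s = deconv.summarize_events(ev, EPSC, 10.0)
        assert s.rate == pytest.approx(1.0)
        tr = alpha_trace([(t, 20.0) for t in times], duration=10.0)
        num = integrate.trapezoid(tr.samples, dx=1.0 / FS)
        assert s.total_charge == pytest.approx(num, rel=1e-3)

    def test_normalized_charge_self_reference_is_one(self):
        ev = deconv.EventSet(np.array([0.1]), np.array([20.0]), 0.0, 5.0)
        s = deconv.summarize_events(ev, EPSC, 1.0)
        s2 = deconv.summarize_events(ev, EPSC, 1.0, reference_charge=s.total_charge)
        assert s2.normalized_charge == pytest.approx(1.0)

    def test_cumulative_distribution_ends_at_one(self):
        ev = deconv.EventSet(np.array([0.1, 0.2, 0.5]), np.array([30.0, 10.0, 20.0]), 0.0, 5.0)
        s = deconv.summarize_events(ev, EPSC, 1.0)
        assert np.all(np.diff(s.amplitudes_sorted) >= 0)
        assert s.cumulative_fractions[-1] == 1.0


class TestEndToEnd:
    def test_noiseless_round_trip(self):
        cfg = synth.SimConfig(seed=17, duration_s=4.0, noise_sd_vc=0.0)
        tr, truth = synth.gen_vc_trace("WT", "EPSC", cfg)
        res = deconv.deconvolve_neuron(tr, kernel=EPSC)
        assert len(res.events) == len(truth)
        np.testing.assert_allclose(res.events.amplitudes, truth.event_amplitudes, rtol=0.01)

    def test_silent_group_below_wt_in_paired_draws(self):
        lows, highs = [], []
        for i in range(10):
            cfg = synth.SimConfig(seed=40 + i, duration_s=4.0)
            sn, _ = synth.gen_vc_trace("Tg-SN", "EPSC", cfg, stream=0)
            wt, _ = synth.gen_vc_trace("WT", "EPSC", cfg, stream=1)
            r_sn = deconv.deconvolve_neuron(sn, kernel=EPSC)
            r_wt = deconv.deconvolve_neuron(wt, kernel=EPSC)
            lows.append(r_sn.summary.rate)
            highs.append(r_wt.summary.rate)
        assert all(lo < hi for lo, hi in zip(lows, highs))

    def test_polarity_rectification(self):
        cfg = synth.SimConfig(seed=2, duration_s=1.0)
        tr, _ = synth.gen_vc_trace("WT", "EPSC", cfg)
        inward = CurrentTrace(-tr.samples - 12.0, FS, "EPSC")  # inward + offset
        res_pos = deconv.deconvolve_neuron(tr, kernel=EPSC)
        res_neg = deconv.deconvolve_neuron(inward, kernel=EPSC)
        assert len(res_pos.events) == len(res_neg.events)
        np.testing.assert_allclose(
            res_pos.events.amplitudes, res_neg.events.amplitudes, rtol=1e-6
        )
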