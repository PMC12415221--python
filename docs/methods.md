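# Methods

silencescope reimplements, on synthetic data with known ground truth, the
quantitative analysis chain used to characterise silent, normal and
hyperactive cortical neurons in an amyloidosis mouse model: somatic Ca2+
imaging analysis and activity classification, parametric deconvolution of
spontaneous postsynaptic currents, and the group statistics applied to
presynaptic-connectivity counts, dendritic morphology and synaptic input.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Calcium-imaging analysis

Raw per-ROI fluorescence F(t) (40 or 80 Hz) is converted to
dF/F0 = (F − F0)/F0 with F0 the mean of the lowest 20% of the samples of
the whole recording. The signal is smoothed with a first-order exponential
filter, y[n] = a·x[n] + (1 − a)·y[n−1], a = 1 − exp(−dt/tau), tau = 35 ms,
initialised at the first sample (unit DC gain). Transients are
threshold-crossing excursions exceeding 3x the baseline-noise SD, one event
per supra-threshold segment with amplitude equal to the segment maximum.

Three choices here are ours:

* **Noise estimator.** The baseline SD is 1.4826 x the median absolute
  deviation of the first differences, divided by sqrt(2) — exactly
  calibrated for white Gaussian noise and nearly blind to sparse, slow
  transients. It is estimated on the *raw* dF/F trace. Estimating it on
  the smoothed trace instead couples two errors (the smoothed-noise SD is
  ~0.6x the raw SD at 40 Hz, and first differences of correlated noise
  undershoot further), which would place the effective threshold ~1.3
  raw-noise SDs above baseline and produce hundreds of false transients per
  15-minute recording — silent neurons would be undetectable. Detection
  itself runs on the smoothed trace against 3x the raw-noise SD.
* **Baseline reference.** Because F0 is the mean of the *lowest* 20% of
  samples, the quiescent dF/F level sits ~1.4 noise SDs above zero.
  Detection therefore measures excursions above the trace median, not
  above absolute zero.
* **Re-crossing merge.** A transient with a 500-ms decay hovers near the
  threshold for ~100 ms on its way down, and noise there splits one event
  into several crossings. `detect_transients` merges crossings closer than
  its `merge_window_ms` (default 50 ms, appropriate for generic use);
  the recommended chain `analyze_trace` uses 250 ms, matched to the
  indicator decay.

Classification from the transient rate: for transgenic neurons, more than
4/min over at least 4 min is hyperactive, between 0 and 4/min normal, no
transients over at least 15 min silent; wild-type neurons with at most one
transient over at least 15 min are silent. A rate of exactly 4/min falls
between the defining inequalities and is reported as `unclassified` rather
than silently assigned. Observations too short for the attempted label
raise an error instead of guessing.

The AP–Ca2+ calibration regresses transient amplitude on the number of
action potentials for events with 1–4 APs (trains faster than 20 Hz;
single APs always eligible) followed by at least 100 ms of quiet; excluded
events are counted. Fewer than two distinct AP counts is a degenerate
design and raises.

## PSC deconvolution

A sign-positive current trace is modelled as a sum of unitary alpha
functions u(t) = t^(k−1) e^(−t/tau), normalised to unit peak so that each
event's amplitude is its peak current in pA. The peak occurs at
(k−1)·tau, and the charge per unit peak amplitude is
Gamma(k)·tau^k · e^(k−1) / ((k−1)·tau)^(k−1).

**Candidates.** Event onsets are anchored to local maxima of the trace
after smoothing with the kernel's own (area-normalised) shape — a matched
filter, the minimum-variance locator of a known waveform in white noise.
The deterministic argmax shift the filtering induces is subtracted, so a
noiseless event maps back to its onset exactly. Two filters are applied to
the maxima: a height/prominence threshold of max(floor/2, 4x the robust SD
of the smoothed trace), which keeps per-noise-wiggle candidates rare while
passing any event near the amplitude floor, and the prominence requirement
suppresses wiggles riding on the decay tail of large events. An earlier
implementation that anchored on moving-average peaks and then refined to
the raw-trace maximum left enough noise-driven onset jitter to bias the
fitted kernel shape by ~20%; refitting with the true onsets removed the
bias entirely, which is why the matched filter was adopted.

**Amplitudes.** Given candidates, amplitudes minimise the squared residual
subject to the sparse constraint a_i in {0} U [floor, inf), floor = 5 pA
(the measurement-noise scale): nonnegative least squares on the candidate
Gram matrix (banded, built from truncated kernel columns; solved through a
Cholesky factor), then every amplitude below the floor is zeroed and the
survivors refit, iterating until all survivors clear the floor. The
non-convex exact problem is NP-hard in general; on traces with at most six
candidates the prune-and-refit solution is checked against exhaustive
best-subset bound-constrained least squares and matches its residual to
within 1%.

**Kernel shape.** (k, tau) are fitted per neuron and per current type by
minimising the total post-fit residual: a coarse grid (k in [1.1, 6], tau
in [0.5, 50] ms, 6x7 points), a local 5x5 grid around the best point, and
Nelder–Mead started there with a small (2%) initial simplex — plain
Nelder–Mead from the coarse grid stalls in side basins of the narrow
residual valley. Excitatory kernels default to (k = 2, tau = 3 ms) and
inhibitory to (k = 1.5, tau = 8 ms): smaller power and longer time
constant for IPSCs.

**Summaries.** Per neuron: event rate, total charge (sum of amplitudes x
unit charge), mean amplitude, the cumulative amplitude distribution, and
charge normalised to a supplied reference (e.g. the WT group mean). An
empty event set is a valid silent-neuron output. EPSCs are recorded at
−80 mV (inward, negative) and IPSCs at +10 mV; traces are rectified to
positive before analysis and the polarity convention lives in metadata.

## Group statistics

Presynaptic-neuron counts are right-skewed; they are transformed as
log10(x + 0.5) (the offset avoids the singularity at zero) and summarised
as offset geometric means, 10^mean(log10(x+0.5)) − 0.5, with SEM on the
log scale. Morphological and electrophysiological measures are analysed
untransformed.

The neuron-type effect is tested with one-way fixed-effects ANOVA computed
from the classical sums-of-squares decomposition (identical to the linear
model F-test; verified against scipy and statsmodels in the tests),
followed by pairwise contrasts on the pooled residual variance with
two-sided t tests — uncorrected by default, mirroring coefficient-test
post hocs; a Holm correction is available.

Spine densities have several segments per mouse, so the neuron-type effect
is tested with a random-intercept linear mixed model (density ~ type +
(1 | mouse), REML, statsmodels MixedLM) and a marginal Wald F-test.
Because the default gradient optimizer can stall short of the zero-variance
boundary, the model is also fitted with Powell's method and the higher
REML likelihood kept. The denominator degrees of freedom default to the
containment choice n_mice − n_groups, appropriate for a factor that varies
between mice: in null simulations with a strong mouse effect (4 groups x 5
mice x 6 segments) the residual convention n_obs − n_fixed rejected at
0.094 instead of 0.05, while the containment choice stays at its nominal
level (for balanced designs it is numerically identical to the exact
ANOVA on mouse means). The residual convention remains available as
`df_method="residual"`.

## Synthetic data generator

The generator emulates the study's four data families with known ground
truth; its defaults are the study conditions wherever those are stated,
and a calibrated choice otherwise.

* **Ca2+ traces** (40 Hz default): transients with instantaneous rise and
  500-ms single-exponential decay (a standard synthetic indicator model),
  amplitude 0.2 dF/F per AP with 1–4 APs per event, additive white noise
  0.02 dF/F (SNR 10 for a single AP). Class rates: hyperactive 8/min,
  normal 2/min, silent 0, quiet wild type 0.05/min — placed safely inside
  each class's defining band.
* **Voltage-clamp traces** (20 kHz, 5 pA noise): Poisson alpha-PSC trains
  with lognormal peak amplitudes (median 20 pA, sigma 0.4). Excitatory
  rates 5 / 0.5 / 2.5 / 5 Hz and inhibitory 4 / 0.4 / 2 / 4 Hz for
  WT / Tg-SN / Tg-NN / Tg-HN, reproducing the qualitative ordering
  Tg-SN << Tg-NN < WT ~ Tg-HN of the study's group summaries (per-group
  numeric rates are plotted there, not printed).
* **Connectivity tables**: per-starter totals lognormal with arithmetic
  means 721 (WT), 85 (Tg-SN), 550 (Tg-NN), 600 (Tg-HN) and CVs from the
  printed WT and Tg-SN mean ± SD; totals split multinomially over nine
  cortical regions x hemisphere with an 80% ipsilateral share.
* **Spine tables**: per-segment density = group mean (0.45 / 0.25 / 0.38 /
  0.40 spines/um) + mouse random effect (SD 0.03) + segment noise
  (SD 0.08); per-neuron dendritic lengths with all transgenic means
  reduced versus WT.

Event times are Poisson in count; given the count, times are placed as
uniform order statistics subject to a minimum gap (1.5 s for Ca2+ traces —
the time a 4-AP transient needs to decay below a 3 x 0.02 dF/F threshold —
and 5x the kernel peak time for PSC trains) and an end margin of twice the
kernel's support, so the count keeps its Poisson distribution while
noiseless traces round-trip exactly through the matching analysis stage.
All randomness derives from one root seed through per-record spawned
streams, so adding records never perturbs earlier ones.

What the generator does *not* emulate: photobleaching drift, movement
artefacts and neuropil contamination in imaging; series-resistance
filtering, dendritic cable distortion of PSC shapes, amplitude–kinetics
correlations, and bursty (non-Poisson) event statistics in voltage clamp;
atlas-registration noise in the count tables. Passing tests therefore
demonstrate the correctness and calibration of the analysis chain under
the stated model, not robustness to every artefact of real recordings.

## Validation scale

The validation suite (`silencescope.evaluation`, run by the tests and by
`scripts/acceptance.py`) uses problem sizes chosen to keep every check
sharp but affordable: 100 short (0.25 s) traces for the exhaustive-oracle
comparison, 50 neurons per group with 8-s traces for recovery (kernel
fitted once per current type on separate calibration traces and reused —
per-neuron refits add cost but nothing to the recovery question), 3 x 4-s
trace sets per kernel fit, 50-neuron classification cohorts, 10^4 ANOVA
and 2 x 10^3 mixed-model null simulations, and 100 connectivity cohorts at
the study's sample sizes (6/5/6/6 starters).

## Known limitations

* The kernel-shape fit retains a small (<~10%) noise-driven bias for broad
  inhibitory kernels at 5 pA noise and short recordings; it shrinks with
  recording length.
* Candidate onsets are frozen after detection (no subsample refinement),
  so amplitude estimates absorb sub-sample misalignment, visible only as
  a slight residual inflation.
* The exhaustive best-subset oracle is exponential in the candidate count
  and only usable on short traces (<= 12 candidates).
* `validate_inputs` checks schemas and invariants, not units: a density
  table in spines/mm would pass validation and produce nonsense.
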