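"""Compare presynaptic connectivity across neuron types.

Simulates rabies-tracing count tables at the study's sample sizes (6 WT,
5 silent, 6 normal, 6 hyperactive starter neurons), summarises them as
offset geometric means, and tests the neuron-type effect with ANOVA on
log10(count + 0.5) totals plus pairwise contrasts.
"""
import pandas as pd

from silencescope import connectivity, stats, synth

cfg = synth.SimConfig(seed=5, duration_s=1.0)
counts = pd.concat(
    [
        synth.gen_connectivity_counts(g, n, cfg, stream=i)
        for i, (g, n) in enumerate((("WT", 6), ("Tg-SN", 5), ("Tg-NN", 6), ("Tg-HN", 6)))
    ],
    ignore_index=True,
)
totals = connectivity.total_per_starter(counts)
print(stats.geometric_mean_summary(totals, value="total", group="group").round(3))

fit = connectivity.compare_groups(totals)
print(f"\nANOVA on log10(total + 0.5): F({fit.df_between}, {fit.df_within}) = "
      f"{fit.F:.2f}, p = {fit.p:.2e}")
print(fit.pairwise.round(4))

# The silent-neuron group (mean calibrated to ~85 presynaptic cells vs ~721
# for WT) should drive a strong type effect, with Tg-SN vs WT the smallest
# pairwise p-value.
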