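"""Mixed-model analysis of dendritic spine density.

Simulates per-segment spine densities for all four groups (six mice each,
apical + basal segments, with a per-mouse random effect) and tests the
neuron-type effect with a random-intercept linear mixed model, mirroring
how clustered morphology data should be analysed.
"""
import pandas as pd

from silencescope import stats, synth

cfg = synth.SimConfig(seed=3, duration_s=1.0)
segments = pd.concat(
    [synth.gen_spine_table(g, 6, 1, 6, cfg, stream=i)[0] for i, g in enumerate(synth.GROUPS)],
    ignore_index=True,
)

for comp in ("apical", "basal"):
    sub = segments[segments["compartment"] == comp]
    res = stats.lmm_spine_density(sub)
    print(
        f"{comp:6s}: F({res.df_num}, {res.df_den}) = {res.F:.2f}, p = {res.p:.2e}   "
        f"mouse var {res.mouse_var:.4f}, residual var {res.residual_var:.4f}"
    )

# The group means (WT 0.45, Tg-SN 0.25, Tg-NN 0.38, Tg-HN 0.40 spines/um)
# should produce a clear neuron-type effect while the mouse random effect
# absorbs the per-animal shifts that would otherwise inflate the test.
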