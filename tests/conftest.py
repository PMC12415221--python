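import numpy as np
import pandas as pd
import pytest

from silencescope import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def grouped_df(rng):
    """Small 4-group table of normal measurements with a real group effect."""
    rows = []
    for g, mu in (("WT", 1.0), ("Tg-SN", 0.2), ("Tg-NN", 0.8), ("Tg-HN", 0.9)):
        for v in rng.normal(mu, 0.15, 6):
            rows.append((g, v))
    return pd.DataFrame(rows, columns=["group", "value"])


@pytest.fixture()
def count_table():
    cfg = synth.SimConfig(seed=7, duration_s=1.0)
    return pd.concat(
        [
            synth.gen_connectivity_counts(g, n, cfg, stream=i)
            for i, (g, n) in enumerate(
                (("WT", 6), ("Tg-SN", 5), ("Tg-NN", 6), ("Tg-HN", 6))
            )
        ],
        ignore_index=True,
    )


@pytest.fixture()
def spine_table():
    cfg = synth.SimConfig(seed=11, duration_s=1.0)
    segs = pd.concat(
        [synth.gen_spine_table(g, 5, 1, 6, cfg, stream=i)[0] for i, g in enumerate(synth.GROUPS)],
        ignore_index=True,
    )
    return segs
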