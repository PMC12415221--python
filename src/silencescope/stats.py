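"""Group-level statistics: count transforms, ANOVA, contrasts, mixed models.

Count data (presynaptic-neuron counts) are log10(x + 0.5) transformed
before analysis (the 0.5 offset avoids the singularity at zero) and
summarised as offset geometric means.  Group effects are tested with
one-way fixed-effects ANOVA computed from the classical sums-of-squares
decomposition of the linear model, followed by uncorrected pairwise
coefficient contrasts on the pooled residual variance (a Holm correction is
available but off by default).  Spine densities, with several dendritic
segments per mouse, are tested with a linear mixed model (random intercept
per mouse, REML, marginal Wald F-test for the neuron-type effect), fitted
with statsmodels MixedLM.  Morphological and electrophysiological measures
are analysed untransformed; only counts get the log transform.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "LmmResult",
    "log_count_transform",
    "inverse_log_count_transform",
    "geometric_mean_summary",
    "anova_oneway",
    "posthoc_pairwise",
    "lmm_spine_density",
]

LOG_OFFSET = 0.5


def log_count_transform(counts, offset: float = LOG_OFFSET) -> np.ndarray:
    """log10(x + offset), elementwise; rejects negative counts."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be >= 0")
    return np.log10(x + offset)


def inverse_log_count_transform(y, offset: float = LOG_OFFSET) -> np.ndarray:
    """Exact inverse of the offset log transform: 10**y - offset."""
    return np.power(10.0, np.asarray(y, dtype=float)) - offset


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA for a group effect."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    group_sizes: dict
    mse: float  # pooled within-group variance (residual mean square)
    pairwise: pd.DataFrame | None = None


@dataclass
class LmmResult:
    """Marginal Wald F-test for a fixed effect in a random-intercept LMM."""

    F: float
    df_num: int
    df_den: int
    p: float
    fixed_effects: dict
    mouse_var: float     # random-intercept variance
    residual_var: float
    df_method: str
    converged: bool


def _check_grouped(df: pd.DataFrame, value: str, group: str) -> None:
    if value not in df.columns or group not in df.columns:
        raise ValueError(f"table needs columns {value!r} and {group!r}")
    sizes = df.groupby(group, observed=True)[value].size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"every group needs >= 2 observations; too small: {small}")


def geometric_mean_summary(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    offset: float = LOG_OFFSET,
) -> pd.DataFrame:
    """Per-group geometric mean (with offset) and SEM on the log10 scale.

    The mean and SEM are computed on log10(x + offset); the geometric mean
    is back-transformed as 10**mean - offset.
    """
    if df.empty:
        raise ValueError("empty table")
    if value not in df.columns or group not in df.columns:
        raise ValueError(f"table needs columns {value!r} and {group!r}")
    if np.any(df[value].to_numpy(dtype=float) + offset <= 0):
        raise ValueError(f"all values must exceed -offset = {-offset}")
    rows = []
    for g, sub in df.groupby(group, observed=True, sort=True):
        ly = np.log10(sub[value].to_numpy(dtype=float) + offset)
        n = ly.size
        mean = float(ly.mean())
        sem = float(ly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append((g, n, mean, sem, 10.0**mean - offset))
    return pd.DataFrame(rows, columns=[group, "n", "log10_mean", "log10_sem", "geometric_mean"])


def anova_oneway(df: pd.DataFrame, value: str = "value", group: str = "group") -> AnovaResult:
    """One-way fixed-effects ANOVA via the sums-of-squares decomposition.

    F = (SSB/df_between) / (SSW/df_within); identical to the linear-model
    F-test of the group factor.  If the between-group sum of squares is
    exactly zero (all group means equal), F = 0 and p = 1.
    """
    _check_grouped(df, value, group)
    groups = {g: sub[value].to_numpy(dtype=float) for g, sub in df.groupby(group, observed=True)}
    n = sum(v.size for v in groups.values())
    g = len(groups)
    grand = sum(v.sum() for v in groups.values()) / n
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    dfb, dfw = g - 1, n - g
    mse = ssw / dfw
    if ssb == 0.0:
        F, p = 0.0, 1.0
    elif ssw == 0.0:
        F, p = float("inf"), 0.0
    else:
        F = (ssb / dfb) / mse
        p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(
        F=float(F),
        df_between=dfb,
        df_within=dfw,
        p=p,
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_sizes={k: int(v.size) for k, v in groups.items()},
        mse=float(mse),
    )


def posthoc_pairwise(
    df: pd.DataFrame,
    fit: AnovaResult,
    value: str = "value",
    group: str = "group",
    pairs: list[tuple[str, str]] | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Pairwise group contrasts on the pooled residual variance.

    For each pair, the contrast estimate is the difference of group means,
    its t statistic uses the ANOVA residual mean square on the residual df,
    and p-values are two-sided.  No multiplicity correction by default
    (mirroring coefficient-test post hocs); ``correction="holm"`` applies a
    Holm step-down adjustment.
    """
    means, sizes = fit.group_means, fit.group_sizes
    if pairs is None:
        pairs = list(itertools.combinations(sorted(means), 2))
    rows = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in means:
                raise ValueError(f"group {g!r} not present in the fit")
        est = means[g1] - means[g2]
        if g1 == g2:
            rows.append((g1, g2, 0.0, 0.0, 1.0))
            continue
        se = math.sqrt(fit.mse * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        t = est / se if se > 0 else math.copysign(math.inf, est) if est else 0.0
        p = float(2.0 * sps.t.sf(abs(t), fit.df_within)) if math.isfinite(t) else 0.0
        rows.append((g1, g2, est, t, p))
    out = pd.DataFrame(rows, columns=["group1", "group2", "estimate", "t", "p"])
    if correction == "holm":
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def lmm_spine_density(
    df: pd.DataFrame,
    value: str = "density",
    group: str = "group",
    mouse: str = "mouse",
    df_method: str = "between",
) -> LmmResult:
    """Random-intercept mixed model: value ~ group + (1 | mouse), REML.

    Returns the marginal Wald F-test for the group (neuron-type) effect.
    ``df_method`` selects the denominator degrees of freedom: "between"
    (n_mice - n_groups, the containment-style default; the group factor
    varies between mice, and null simulations show the residual convention
    is anticonservative here) or "residual" (n_obs - n_fixed, the
    convention behind printed dfs like F(3, 129) in some toolboxes).
    """
    import statsmodels.formula.api as smf

    for col in (value, group, mouse):
        if col not in df.columns:
            raise ValueError(f"table needs column {col!r}")
    mice = df.groupby(mouse, observed=True)[group].nunique()
    if len(mice) < 2:
        raise ValueError("random intercept unidentifiable with a single mouse")
    if (mice > 1).any():
        bad = mice[mice > 1].index.tolist()
        raise ValueError(f"mouse assigned to multiple groups: {bad}")
    if df_method not in ("residual", "between"):
        raise ValueError(f"unknown df_method {df_method!r}")

    data = df[[value, group, mouse]].rename(
        columns={value: "_y", group: "_g", mouse: "_m"}
    )
    model = smf.mixedlm("_y ~ C(_g)", data, groups=data["_m"])
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # a zero mouse variance legitimately sits on the REML boundary,
        # where the default gradient optimizer can stall short of it;
        # Powell reaches it, so keep whichever attains the higher REML
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
        try:
            alt = model.fit(reml=True, method="powell")
            if np.isfinite(alt.llf) and alt.llf > res.llf + 1e-10:
                res = alt
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            pass
    names = list(res.fe_params.index)
    idx = [i for i, nm in enumerate(names) if nm.startswith("C(_g)")]
    q = len(idx)
    beta = res.fe_params.to_numpy()[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    W = float(beta @ np.linalg.solve(cov, beta))
    F = W / q
    n_obs = len(data)
    n_fixed = len(names)
    n_mice = data["_m"].nunique()
    n_groups = data["_g"].nunique()
    df_den = n_obs - n_fixed if df_method == "residual" else n_mice - n_groups
    if df_den < 1:
        raise ValueError("not enough degrees of freedom for the group F-test")
    p = float(sps.f.sf(F, q, df_den))
    return LmmResult(
        F=F,
        df_num=q,
        df_den=int(df_den),
        p=p,
        fixed_effects={nm: float(v) for nm, v in res.fe_params.items()},
        mouse_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        df_method=df_method,
        converged=bool(res.converged),
    )
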