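"""Fitness-proxy phenotypes and the habitat-interaction ANCOVA.

Two traits are derived from raw measurements of juvenile fish:

- the relative condition factor ``K``, the ratio of observed weight to the
  weight predicted by the pooled log–log length–weight regression;
- a standardized length index, the z-score of total length within each
  habitat × sampling-date stratum, a growth proxy robust to heterochronous
  sampling.

``ancova_interaction`` fits ``y ~ group * x`` by OLS and reports per-group
slopes plus the F-test of the interaction, the construction reused for every
genotype–environment interaction analysis in the package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


def condition_factor(lengths, weights) -> np.ndarray:
    """Relative condition factor K per individual.

    Fits ``log w = a + b log L`` by OLS over all individuals, then
    ``K_i = w_i / exp(a + b log L_i)``.  By construction the geometric mean
    of K is 1.
    """
    L = np.asarray(lengths, dtype=float)
    W = np.asarray(weights, dtype=float)
    if len(L) != len(W):
        raise ValueError("lengths and weights differ in length")
    if len(L) < 3:
        raise ValueError("need at least 3 individuals for the length-weight fit")
    if (L <= 0).any() or (W <= 0).any():
        raise ValueError("lengths and weights must be positive")
    b, a = np.polyfit(np.log(L), np.log(W), 1)
    predicted = np.exp(a + b * np.log(L))
    return W / predicted


def standardized_length(lengths, habitat, date) -> np.ndarray:
    """Z-score of total length within each habitat × sampling-date stratum.

    Singleton strata (or strata with zero variance) yield NaN with a logged
    warning.
    """
    L = np.asarray(lengths, dtype=float)
    df = pd.DataFrame({"L": L, "habitat": list(habitat), "date": list(date)})
    z = np.full(len(df), np.nan)
    for (h, d), idx in df.groupby(["habitat", "date"]).groups.items():
        vals = L[np.asarray(idx)]
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            logger.warning("stratum (%s, %s) has <2 individuals or zero variance; "
                           "standardized length set to NaN", h, d)
            continue
        z[np.asarray(idx)] = (vals - vals.mean()) / vals.std(ddof=1)
    return z


@dataclass
class AncovaFit:
    """Per-group regression lines and interaction test from an ANCOVA."""

    slopes: dict
    intercepts: dict
    r_squared: float
    model_p: float
    interaction_p: float
    df_resid: float
    nobs: int


def ancova_interaction(y, x, group) -> AncovaFit:
    """OLS ANCOVA ``y ~ group * x`` with per-group slopes.

    ``model_p`` is the overall F-test; ``interaction_p`` the F-test of the
    group × covariate interaction (full vs. additive model).  Rows with NaN
    in any variable are dropped.  A rank-deficient design (e.g. constant
    covariate) raises a ValueError naming the degenerate term.
    """
    df = pd.DataFrame({"y": np.asarray(y, float),
                       "x": np.asarray(x, float),
                       "g": list(group)}).dropna()
    if df["g"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(df["x"].to_numpy()) == 0:
        raise ValueError("covariate x is constant (rank-deficient design)")
    for g, sub in df.groupby("g"):
        if np.ptp(sub["x"].to_numpy()) == 0:
            raise ValueError(f"covariate x is constant within group {g!r}")
    n_params = 2 * df["g"].nunique()
    if len(df) <= n_params:
        raise ValueError("fewer observations than parameters")
    full = smf.ols("y ~ C(g) * x", data=df).fit()
    reduced = smf.ols("y ~ C(g) + x", data=df).fit()
    comparison = sm.stats.anova_lm(reduced, full)
    interaction_p = float(comparison["Pr(>F)"].iloc[1])
    groups = sorted(df["g"].unique())
    base = groups[0]
    slopes = {base: full.params["x"]}
    intercepts = {base: full.params["Intercept"]}
    for g in groups[1:]:
        slopes[g] = full.params["x"] + full.params.get(f"C(g)[T.{g}]:x", 0.0)
        intercepts[g] = full.params["Intercept"] + full.params.get(f"C(g)[T.{g}]", 0.0)
    return AncovaFit(
        slopes={k: float(v) for k, v in slopes.items()},
        intercepts={k: float(v) for k, v in intercepts.items()},
        r_squared=float(full.rsquared),
        model_p=float(full.f_pvalue),
        interaction_p=interaction_p,
        df_resid=float(full.df_resid),
        nobs=int(full.nobs),
    )
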