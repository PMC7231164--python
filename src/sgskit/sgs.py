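"""The single-generation selection (SGS) test.

Two samples of the same generation are drawn from one panmictic gene pool.
At a biallelic locus the observed allele-frequency difference
``Δp = |p1 − p2|`` is compared to a Monte-Carlo null that accounts for two
variance sources: uncertainty about the true pool frequency (a Beta
posterior built from the pooled counts) and binomial sampling noise in each
sample.  Each null draw takes ``p* ~ Beta(x_pool + a, n_pool − x_pool + b)``
followed by independent binomial draws of the two sample counts, and the
P-value is the (add-one corrected) fraction of null Δp* at least as large as
the observed Δp.

A small exact counterpart (:func:`sgs_exact_tail`) integrates the Beta layer
analytically — the joint null of the two sample counts is a correlated
beta-binomial — and is used to validate the Monte-Carlo estimator at small
sample sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln

from .genotypes import GenotypeMatrix, LocusStats, allele_frequencies

DEFAULT_PRIOR = (1.0, 1.0)
_TIE_EPS = 1e-12


@dataclass
class SGSLocusResult:
    """Per-locus outcome of the SGS test."""

    locus: object
    p1: float
    p2: float
    delta_p: float
    p_value: float
    n_iter: int
    monomorphic: bool = False
    p_base: float = np.nan
    ci_lo: float = np.nan
    ci_hi: float = np.nan


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sgs_null_draws(
    x_pool: int,
    n_pool: int,
    n1_alleles: int,
    n2_alleles: int,
    n_iter: int = 10_000,
    seed=None,
    prior: tuple[float, float] = DEFAULT_PRIOR,
) -> np.ndarray:
    """Draw ``n_iter`` values of Δp* from the sampling-only null.

    The pool-frequency layer uses the conjugate posterior
    ``Beta(x_pool + a, n_pool − x_pool + b)``; the sampling layer draws the
    two sample allele counts binomially at the shared ``p*``.
    """
    if n_pool <= 0:
        raise ValueError("n_pool must be positive")
    if not 0 <= x_pool <= n_pool:
        raise ValueError("x_pool must lie in [0, n_pool]")
    if min(n1_alleles, n2_alleles) < 2:
        raise ValueError("each sample needs at least 2 alleles")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    a, b = prior
    rng = _rng(seed)
    p_star = rng.beta(x_pool + a, n_pool - x_pool + b, size=n_iter)
    x1 = rng.binomial(n1_alleles, p_star)
    x2 = rng.binomial(n2_alleles, p_star)
    return np.abs(x1 / n1_alleles - x2 / n2_alleles)


def sgs_test_locus(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    n_iter: int = 10_000,
    seed=None,
    prior: tuple[float, float] = DEFAULT_PRIOR,
    locus=None,
) -> SGSLocusResult:
    """SGS test for one locus from the two samples' allele counts.

    ``x_i``/``n_i`` are reference-allele count and total called alleles in
    sample *i*.  The null pool frequency is estimated from the two samples
    pooled.  P-values use the add-one estimator
    ``(1 + #{Δp* ≥ Δp_obs}) / (n_iter + 1)`` with ties counted as extreme, so
    a reported P is never zero.
    """
    x_pool, n_pool = x1 + x2, n1 + n2
    if n_pool == 0:
        raise ValueError("no called alleles at locus")
    p1, p2 = x1 / n1, x2 / n2
    delta = abs(p1 - p2)
    if x_pool == 0 or x_pool == n_pool:
        return SGSLocusResult(locus, p1, p2, 0.0, 1.0, n_iter, monomorphic=True)
    draws = sgs_null_draws(x_pool, n_pool, n1, n2, n_iter, seed, prior)
    k = int((draws >= delta - _TIE_EPS).sum())
    p_value = (1 + k) / (n_iter + 1)
    return SGSLocusResult(locus, p1, p2, delta, p_value, n_iter)


# ---------------------------------------------------------------------------
# Exact (small-n) counterpart
# ---------------------------------------------------------------------------

def sgs_joint_null_pmf(
    x_pool: int,
    n_pool: int,
    n1: int,
    n2: int,
    prior: tuple[float, float] = DEFAULT_PRIOR,
) -> np.ndarray:
    """Exact joint null pmf of the two sample counts, shape (n1+1, n2+1).

    Integrating the Beta layer gives
    ``P(x1, x2) = C(n1,x1) C(n2,x2) B(A+x1+x2, B+n1+n2−x1−x2) / B(A, B)``
    with ``A = x_pool + a`` and ``B = n_pool − x_pool + b``.
    """
    a, b = prior
    A, B = x_pool + a, n_pool - x_pool + b
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    logc = (gammaln(n1 + 1) - gammaln(i + 1) - gammaln(n1 - i + 1)
            + gammaln(n2 + 1) - gammaln(j + 1) - gammaln(n2 - j + 1))
    logp = logc + betaln(A + i + j, B + (n1 - i) + (n2 - j)) - betaln(A, B)
    pmf = np.exp(logp)
    return pmf / pmf.sum()


def sgs_exact_tail(
    x_pool: int,
    n_pool: int,
    n1: int,
    n2: int,
    delta_obs: float,
    prior: tuple[float, float] = DEFAULT_PRIOR,
) -> float:
    """Exact null probability ``P(Δp* ≥ delta_obs)`` by full enumeration."""
    pmf = sgs_joint_null_pmf(x_pool, n_pool, n1, n2, prior)
    i = np.arange(n1 + 1)[:, None] / n1
    j = np.arange(n2 + 1)[None, :] / n2
    return float(pmf[np.abs(i - j) >= delta_obs - _TIE_EPS].sum())


# ---------------------------------------------------------------------------
# Baseline credibility interval and outlier classification
# ---------------------------------------------------------------------------

def baseline_credibility_interval(
    x_base: int,
    n_base: int,
    level: float = 0.90,
    prior: tuple[float, float] = DEFAULT_PRIOR,
) -> tuple[float, float]:
    """Equal-tailed Beta-posterior interval for the baseline allele frequency."""
    if not 0 <= x_base <= n_base or n_base < 1:
        raise ValueError("invalid baseline counts")
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    a, b = prior
    lo_q = (1 - level) / 2
    dist = stats.beta(x_base + a, n_base - x_base + b)
    return float(dist.ppf(lo_q)), float(dist.ppf(1 - lo_q))


def sgs_scan(
    G: GenotypeMatrix,
    group_a: str,
    group_b: str,
    baseline: str | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    prior: tuple[float, float] = DEFAULT_PRIOR,
    ci_level: float = 0.90,
) -> pd.DataFrame:
    """Run the SGS test at every locus of ``G`` between two groups.

    Each locus uses an RNG substream derived from ``(seed, locus index)``, so
    results do not depend on scan order.  If ``baseline`` is given, the
    baseline frequency and its credibility interval are included per locus.
    """
    st = allele_frequencies(G, [g for g in (group_a, group_b, baseline) if g])
    rows = []
    for i, locus in enumerate(G.loci):
        x1, n1 = int(st.x[group_a][i]), int(st.n[group_a][i])
        x2, n2 = int(st.x[group_b][i]), int(st.n[group_b][i])
        if n1 < 2 or n2 < 2:
            raise ValueError(f"locus {locus!r} has <2 called alleles in a group")
        rng = np.random.default_rng([seed, i])
        res = sgs_test_locus(x1, n1, x2, n2, n_iter, rng, prior, locus=locus)
        row = {
            "locus": locus,
            "p_a": res.p1,
            "p_b": res.p2,
            "delta_p": res.delta_p,
            "p_value": res.p_value,
            "monomorphic": res.monomorphic,
        }
        if baseline is not None:
            xb, nb = int(st.x[baseline][i]), int(st.n[baseline][i])
            row["p_base"] = xb / nb if nb else np.nan
            if nb:
                lo, hi = baseline_credibility_interval(xb, nb, ci_level, prior)
            else:
                lo = hi = np.nan
            row["ci_lo"], row["ci_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def outlier_set(scan: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Loci with SGS P-value below ``threshold``."""
    return scan[scan["p_value"] < threshold].reset_index(drop=True)


def classify_outliers_vs_baseline(scan: pd.DataFrame) -> pd.DataFrame:
    """Descriptive flags relating each locus to the baseline sample.

    Requires a scan run with a baseline group.  Flags per locus:

    - ``baseline_intermediate`` — baseline frequency lies between the two
      post-selection group frequencies;
    - ``outside_ci`` — at least one group frequency falls outside the
      baseline credibility interval;
    - ``major_up_a`` / ``major_up_b`` — the baseline major allele increased
      in frequency in group A / B relative to the baseline.
    """
    if "p_base" not in scan.columns:
        raise ValueError("scan lacks baseline columns; rerun with baseline group")
    p_base = scan["p_base"].to_numpy(float)
    p_a = scan["p_a"].to_numpy(float)
    p_b = scan["p_b"].to_numpy(float)
    lo = scan["ci_lo"].to_numpy(float)
    hi = scan["ci_hi"].to_numpy(float)
    intermediate = (np.minimum(p_a, p_b) <= p_base) & (p_base <= np.maximum(p_a, p_b))
    outside = (p_a < lo) | (p_a > hi) | (p_b < lo) | (p_b > hi)
    # orient to the baseline major allele
    sign = np.where(p_base >= 0.5, 1.0, -1.0)
    major_up_a = sign * (p_a - p_base) > 0
    major_up_b = sign * (p_b - p_base) > 0
    return pd.DataFrame({
        "locus": scan["locus"],
        "baseline_intermediate": intermediate,
        "outside_ci": outside,
        "major_up_a": major_up_a,
        "major_up_b": major_up_b,
    })
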