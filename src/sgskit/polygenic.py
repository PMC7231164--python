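"""Polygenic scores over outlier loci and genotype–environment association.

At each outlier locus the allele at higher frequency in one habitat's
survivors is that habitat's "favored" allele; the two favored alleles are
complementary, so the two per-individual scores (counts of favored alleles
over a locus set) sum to twice the number of loci when no calls are
missing.  Missing calls contribute zero to both scores (no imputation by
default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, LocusStats, allele_frequencies
from .phenotypes import AncovaFit, ancova_interaction

logger = logging.getLogger(__name__)


def orient_alleles(stats_: LocusStats, group_a: str, group_b: str) -> pd.DataFrame:
    """Assign each locus its group-A-favored allele.

    The A-favored allele is the one at higher frequency in group A than in
    group B; ties default to the reference allele with a flag.  Loci with no
    called alleles in either group are excluded (logged).
    """
    p_a = stats_.p(group_a)
    p_b = stats_.p(group_b)
    usable = ~(np.isnan(p_a) | np.isnan(p_b))
    n_drop = int((~usable).sum())
    if n_drop:
        logger.warning("%d loci lack calls in a group and were excluded from orientation",
                       n_drop)
    diff = p_a[usable] - p_b[usable]
    return pd.DataFrame({
        "locus": stats_.loci[usable],
        "a_favored_allele": np.where(diff >= 0, "ref", "alt"),
        "tie": diff == 0,
    })


@dataclass
class ScoreSet:
    """Per-individual counts of habitat-favored alleles over a locus set."""

    table: pd.DataFrame          # individual, score_a, score_b, n_missing
    loci: np.ndarray

    @property
    def score_a(self) -> np.ndarray:
        return self.table["score_a"].to_numpy()

    @property
    def score_b(self) -> np.ndarray:
        return self.table["score_b"].to_numpy()


def polygenic_scores(G: GenotypeMatrix, orientation: pd.DataFrame,
                     locus_set) -> ScoreSet:
    """Sum favored-allele counts over ``locus_set`` for every individual.

    Missing calls contribute 0 to both scores, so with complete data
    ``score_a + score_b == 2 × |locus_set|`` exactly.
    """
    locus_set = list(locus_set)
    if not locus_set:
        raise ValueError("empty locus set")
    orient = orientation.set_index("locus")["a_favored_allele"]
    unknown = [l for l in locus_set if l not in orient.index]
    if unknown:
        raise KeyError(f"loci missing from orientation: {unknown[:5]}")
    sub = G.subset_loci(locus_set)
    calls = sub.calls.astype(np.int64)
    missing = calls == MISSING
    ref_fav = (orient.loc[locus_set] == "ref").to_numpy()[None, :]
    contrib_a = np.where(ref_fav, calls, 2 - calls)
    contrib_b = np.where(ref_fav, 2 - calls, calls)
    contrib_a = np.where(missing, 0, contrib_a)
    contrib_b = np.where(missing, 0, contrib_b)
    table = pd.DataFrame({
        "individual": sub.individuals,
        "score_a": contrib_a.sum(axis=1),
        "score_b": contrib_b.sum(axis=1),
        "n_missing": missing.sum(axis=1),
    })
    return ScoreSet(table, np.array(locus_set, dtype=object))


@dataclass
class SweepResult:
    """Outcome of the nominal-threshold sweep."""

    table: pd.DataFrame          # threshold, n_loci, r2, model_p, interaction_p
    best_threshold: float
    best_r2: float
    score: str


def threshold_sweep(
    scan: pd.DataFrame,
    G: GenotypeMatrix,
    trait,
    habitat,
    thresholds,
    score: str = "a",
    group_a: str | None = None,
    group_b: str | None = None,
) -> SweepResult:
    """Trait ANCOVA across nested outlier sets at decreasing P-value cutoffs.

    For each threshold ``t``, loci with SGS P < t are selected, per-individual
    polygenic scores computed (orientation from the contrast between
    ``group_a`` and ``group_b``, which default to the two habitat labels),
    and ``trait ~ habitat × score`` fitted; the threshold maximizing R² is
    reported.  ``trait`` and ``habitat`` are aligned with ``G.individuals``;
    individuals with NaN trait or habitat are dropped.
    """
    thresholds = sorted(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if score not in ("a", "b"):
        raise ValueError("score must be 'a' or 'b'")
    habitat = np.asarray(list(habitat), dtype=object)
    trait = np.asarray(trait, dtype=float)
    hab_names = [h for h in pd.unique(habitat) if not pd.isna(h)]
    if group_a is None or group_b is None:
        if len(hab_names) != 2:
            raise ValueError("could not infer the two habitat groups; pass group_a/group_b")
        group_a, group_b = hab_names
    orientation = orient_alleles(allele_frequencies(G, [group_a, group_b]),
                                 group_a, group_b)
    use = ~pd.isna(trait) & pd.Series(habitat).isin([group_a, group_b]).to_numpy()
    rows = []
    for t in thresholds:
        loci = scan.loc[scan["p_value"] < t, "locus"]
        loci = [l for l in loci if l in set(orientation["locus"])]
        if len(loci) == 0:
            rows.append({"threshold": t, "n_loci": 0, "r2": np.nan,
                         "model_p": np.nan, "interaction_p": np.nan})
            continue
        ss = polygenic_scores(G, orientation, loci)
        sc = ss.score_a if score == "a" else ss.score_b
        fit = ancova_interaction(trait[use], sc[use], habitat[use])
        rows.append({"threshold": t, "n_loci": len(loci), "r2": fit.r_squared,
                     "model_p": fit.model_p, "interaction_p": fit.interaction_p})
    table = pd.DataFrame(rows)
    if table["r2"].notna().any():
        best = table.loc[table["r2"].idxmax()]
        best_t, best_r2 = float(best["threshold"]), float(best["r2"])
    else:
        best_t, best_r2 = np.nan, np.nan
    return SweepResult(table, best_t, best_r2, score)


@dataclass
class GWAResult:
    """Per-SNP association table with the tag-aware Bonferroni threshold."""

    table: pd.DataFrame
    bonferroni_threshold: float
    n_effective_tests: int
    model: str


def gwa_linear(G: GenotypeMatrix, y, E=None, model: str = "simple",
               alpha: float = 0.05) -> GWAResult:
    """Per-SNP OLS association under one of three models.

    ``simple``: y ~ g; ``covariate``: y ~ g + E; ``interaction``:
    y ~ g + E + g×E.  The reported P is the SNP term for the first two and
    the interaction term for the third.  The genome-wide threshold is
    ``alpha`` divided by the number of distinct RAD-tags among tested loci
    (within-tag linkage treated as one effective test); without tag ids each
    locus is its own tag.
    """
    if model not in ("simple", "covariate", "interaction"):
        raise ValueError(f"unknown model {model!r}")
    y = np.asarray(y, float)
    if model != "simple":
        if E is None:
            raise ValueError("E required for covariate/interaction models")
        E = np.asarray(E, float)
        if set(np.unique(E[~np.isnan(E)])) - {0.0, 1.0}:
            raise ValueError("E must be binary 0/1")
    rows = []
    tested_tags = set()
    tags = G.tags if G.tags is not None else G.loci
    for j, locus in enumerate(G.loci):
        g = G.calls[:, j].astype(float)
        g[g == MISSING] = np.nan
        if model == "simple":
            cols = [g]
        elif model == "covariate":
            cols = [g, E]
        else:
            cols = [g, E, g * E]
        X = np.column_stack([np.ones_like(y)] + cols)
        ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
        Xo, yo = X[ok], y[ok]
        if len(np.unique(Xo[:, 1])) < 2:
            continue  # monomorphic among tested individuals
        if np.linalg.matrix_rank(Xo) < Xo.shape[1] or len(yo) <= Xo.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
        resid = yo - Xo @ beta
        dof = len(yo) - Xo.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(Xo.T @ Xo)
        idx = 1 if model in ("simple", "covariate") else 3
        se = np.sqrt(cov[idx, idx])
        tstat = beta[idx] / se
        p = 2 * stats.t.sf(abs(tstat), dof)
        tested_tags.add(tags[j])
        rows.append({"locus": locus, "beta": beta[idx], "se": se,
                     "t": tstat, "p_value": p, "n": len(yo)})
    n_eff = max(len(tested_tags), 1)
    return GWAResult(pd.DataFrame(rows), alpha / n_eff, n_eff, model)


@dataclass
class AssociationFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def independent_association(scores, trait, score_ids=None,
                            discovery_ids=None) -> AssociationFit:
    """Simple OLS of a trait on a polygenic score in an independent sample.

    If both id sets are given, any overlap between the scored individuals
    and the outlier-discovery individuals is an error — the association is
    only an independent validation when the two samples are disjoint.
    """
    if score_ids is not None and discovery_ids is not None:
        overlap = set(score_ids) & set(discovery_ids)
        if overlap:
            raise ValueError(f"individuals used for discovery appear in the "
                             f"validation sample: {sorted(overlap)[:5]}")
    x = np.asarray(scores, float)
    y = np.asarray(trait, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("polygenic score is constant; slope undefined")
    res = stats.linregress(x, y)
    return AssociationFit(float(res.slope), float(res.intercept),
                          float(res.rvalue ** 2), float(res.pvalue), len(x))
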