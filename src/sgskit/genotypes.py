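"""Genotype matrices: loading, QC filtering, allele frequencies, F_ST and PCA.

The central container is :class:`GenotypeMatrix`, an individuals × loci matrix
of reference-allele copy counts (0/1/2, -1 for missing) together with a group
label per individual (a pre-selection baseline sample plus post-selection
samples from different environments) and, optionally, per-call allele read
depths used by the allele-balance filter.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a grouped cohort.

    Parameters
    ----------
    calls
        ``(n_individuals, n_loci)`` integer array of reference-allele copy
        counts; ``-1`` marks a missing call.
    individuals, loci
        Ordered unique identifiers.
    groups
        One label per individual (e.g. ``larvae``, ``brackish``, ``marine``).
    tags
        Optional tag-of-origin (RAD-tag) id per locus; loci sharing a tag are
        treated as a single effective test in Bonferroni corrections.
    allele_depths
        Optional ``(n_individuals, n_loci, 2)`` array of (ref, alt) read
        depths.
    """

    calls: np.ndarray
    individuals: np.ndarray
    loci: np.ndarray
    groups: np.ndarray
    tags: np.ndarray | None = None
    allele_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.loci = np.asarray(self.loci, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-dimensional")
        n_ind, n_loc = self.calls.shape
        if len(self.individuals) != n_ind or len(self.groups) != n_ind:
            raise ValueError("individual/group labels do not match calls shape")
        if len(self.loci) != n_loc:
            raise ValueError("locus ids do not match calls shape")
        if len(set(self.loci)) != n_loc:
            raise ValueError("locus ids must be unique")
        if len(set(self.individuals)) != n_ind:
            raise ValueError("individual ids must be unique")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("calls must be 0, 1, 2 or missing (-1)")
        if self.tags is not None:
            self.tags = np.asarray(self.tags, dtype=object)
            if len(self.tags) != n_loc:
                raise ValueError("tags do not match number of loci")
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths)
            if self.allele_depths.shape != (n_ind, n_loc, 2):
                raise ValueError("allele_depths must have shape (n_ind, n_loci, 2)")

    # -- basic introspection ------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_mask(self, group: str) -> np.ndarray:
        mask = self.groups == group
        if not mask.any():
            raise ValueError(f"no individuals in group {group!r}")
        return mask

    # -- subsetting ----------------------------------------------------------
    def subset_loci(self, loci: Sequence | np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to ``loci`` (ids or boolean mask)."""
        loci = np.asarray(loci)
        if loci.dtype == bool:
            idx = np.flatnonzero(loci)
        else:
            pos = {l: i for i, l in enumerate(self.loci)}
            try:
                idx = np.array([pos[l] for l in loci], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown locus {e.args[0]!r}") from None
        return replace(
            self,
            calls=self.calls[:, idx],
            loci=self.loci[idx],
            tags=None if self.tags is None else self.tags[idx],
            allele_depths=None if self.allele_depths is None else self.allele_depths[:, idx],
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(self.individuals, mask)
        return replace(
            self,
            calls=self.calls[mask],
            individuals=self.individuals[mask],
            groups=self.groups[mask],
            allele_depths=None if self.allele_depths is None else self.allele_depths[mask],
        )


@dataclass
class LocusStats:
    """Per-locus reference-allele counts by group and pooled.

    ``x[g]`` is the reference-allele count, ``n[g]`` the number of called
    alleles (2 × non-missing individuals) in group ``g``; key ``"pooled"``
    holds the totals.
    """

    loci: np.ndarray
    x: dict[str, np.ndarray]
    n: dict[str, np.ndarray]

    def p(self, group: str) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n[group] > 0, self.x[group] / self.n[group], np.nan)

    def to_frame(self) -> pd.DataFrame:
        out = {"locus": self.loci}
        for g in self.x:
            out[f"x_{g}"] = self.x[g]
            out[f"n_{g}"] = self.n[g]
            out[f"p_{g}"] = self.p(g)
        return pd.DataFrame(out)


@dataclass
class FilterReport:
    """Outcome of one locus filter: what was tested, what was removed."""

    name: str
    tested: np.ndarray
    removed: np.ndarray
    table: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return len(self.tested)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_tsv(self, path) -> None:
        if self.table is not None:
            self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_group_map(group_map) -> dict:
    if isinstance(group_map, (str, Path)):
        df = pd.read_csv(group_map, sep="\t", header=None,
                         names=["individual", "group"], comment="#", dtype=str)
        return dict(zip(df["individual"], df["group"]))
    return dict(group_map)


def load_genotypes(path, format: str = "vcf", group_map=None) -> GenotypeMatrix:
    """Load genotype calls from a VCF or a delimited 0/1/2 matrix.

    VCF records are decoded as copies of the REF allele; multiallelic records
    are skipped (with a logged count).  ``group_map`` maps every individual id
    to its group label (dict, or path to a two-column TSV); an individual in
    the map that is absent from the data is a hard error, as is a data
    individual missing from the map.
    """
    if group_map is None:
        raise ValueError("group_map is required")
    gmap = _read_group_map(group_map)
    if format == "vcf":
        G = _load_vcf(path)
    elif format == "matrix":
        G = _load_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    ids = set(G.individuals)
    unknown = sorted(set(gmap) - ids)
    if unknown:
        raise ValueError(f"group map names individuals absent from data: {unknown[:5]}")
    missing = sorted(ids - set(gmap))
    if missing:
        raise ValueError(f"individuals without a group label: {missing[:5]}")
    G.groups = np.array([gmap[i] for i in G.individuals], dtype=object)
    return G


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = np.array(vcf.samples, dtype=object)
    calls, loci, tags, depths = [], [], [], []
    n_skipped = 0
    ad_in_header = "##FORMAT=<ID=AD" in vcf.raw_header
    have_ad = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types)
        # cyvcf2: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        col = np.select([gt == 0, gt == 1, gt == 3], [2, 1, 0], default=MISSING)
        calls.append(col.astype(np.int8))
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        tags.append(var.INFO.get("TAG"))
        ad = var.format("AD") if ad_in_header else None
        if ad is not None:
            have_ad = True
            ad = np.asarray(ad)[:, :2].astype(np.int64)
            ad[ad < 0] = 0
            depths.append(ad)
        else:
            depths.append(np.zeros((len(individuals), 2), dtype=np.int64))
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    if not calls:
        raise ValueError("no biallelic records in VCF")
    tag_arr = np.array(tags, dtype=object) if any(t is not None for t in tags) else None
    return GenotypeMatrix(
        calls=np.column_stack(calls),
        individuals=individuals,
        loci=np.array(loci, dtype=object),
        groups=np.array(["unassigned"] * len(individuals), dtype=object),
        tags=tag_arr,
        allele_depths=np.stack(depths, axis=1) if have_ad else None,
    )


def _load_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    calls = df.to_numpy(dtype=float)
    out = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(
        calls=out,
        individuals=df.index.to_numpy(dtype=object),
        loci=df.columns.to_numpy(dtype=object),
        groups=np.array(["unassigned"] * len(df), dtype=object),
    )


def write_matrix(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.calls.astype(float), index=G.individuals, columns=G.loci)
    df[df < 0] = np.nan
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix, groups: Iterable[str] | None = None) -> LocusStats:
    """Per-group and pooled reference-allele counts; missing calls excluded."""
    groups = list(groups) if groups is not None else G.group_names
    x: dict[str, np.ndarray] = {}
    n: dict[str, np.ndarray] = {}
    for g in groups:
        mask = G.group_mask(g)
        sub = G.calls[mask]
        called = sub != MISSING
        x[g] = np.where(called, sub, 0).sum(axis=0).astype(np.int64)
        n[g] = 2 * called.sum(axis=0).astype(np.int64)
    x["pooled"] = np.sum([x[g] for g in groups], axis=0)
    n["pooled"] = np.sum([n[g] for g in groups], axis=0)
    return LocusStats(loci=G.loci.copy(), x=x, n=n)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE test P-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (conditional on allele counts, Levene/Haldane
    distribution).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_ref = 2 * n_hom_ref + n_het
    n_rare = min(n_ref, 2 * n - n_ref)
    if n_rare == 0:
        return 1.0
    obs_het = n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(h) ∝ n! 2^h / (h! n_AA(h)! n_aa(h)!) with n_AA, n_aa the homozygote
    # counts implied by h given the fixed allele counts.
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1))
    logp -= logsumexp(logp)
    p = np.exp(logp)
    p_obs = p[hets == obs_het]
    if len(p_obs) == 0:  # inconsistent counts cannot occur for valid input
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_loci(
    G: GenotypeMatrix,
    max_missing_frac: float = 0.10,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-3,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Missingness / MAF / HWE locus filter.

    Retains loci with missingness ≤ ``max_missing_frac`` within *every* group,
    pooled minor allele frequency ≥ ``maf_min``, and HWE exact-test
    P ≥ ``hwe_alpha`` within every group.
    """
    for thr in (max_missing_frac, maf_min):
        if not 0 <= thr <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    groups = G.group_names
    n_loc = G.n_loci
    keep = np.ones(n_loc, dtype=bool)
    miss_frac = np.zeros((len(groups), n_loc))
    hwe_p = np.ones((len(groups), n_loc))
    for gi, g in enumerate(groups):
        sub = G.calls[G.group_mask(g)]
        if sub.shape[0] == 0:
            raise ValueError(f"group {g!r} has no individuals")
        miss_frac[gi] = (sub == MISSING).mean(axis=0)
        for j in range(n_loc):
            col = sub[:, j]
            col = col[col != MISSING]
            hwe_p[gi, j] = hwe_exact_pvalue(
                int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
            )
    keep &= (miss_frac <= max_missing_frac + 1e-12).all(axis=0)
    stats_ = allele_frequencies(G, groups)
    with np.errstate(invalid="ignore"):
        p_pool = stats_.p("pooled")
    maf = np.fmin(p_pool, 1 - p_pool)
    keep &= np.nan_to_num(maf, nan=0.0) >= maf_min
    keep &= (hwe_p >= hwe_alpha).all(axis=0)
    table = pd.DataFrame({
        "locus": G.loci,
        "max_group_missing": miss_frac.max(axis=0),
        "pooled_maf": maf,
        "min_group_hwe_p": hwe_p.min(axis=0),
        "retained": keep,
    })
    report = FilterReport("missing_maf_hwe", G.loci.copy(), G.loci[~keep], table)
    return G.subset_loci(keep), report


def allele_balance_filter(
    G: GenotypeMatrix, alpha: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with systematic read-depth bias against one allele.

    For each locus the allele with the lowest total read count across
    individuals is identified; each heterozygote contributes the ratio of
    that allele's depth to total depth, and a one-sided one-sample t-test
    checks whether the mean ratio falls below the unbiased expectation 0.5.
    Loci with fewer than two usable heterozygotes pass with a warning.
    """
    if G.allele_depths is None:
        raise ValueError("allele_depths required for the allele-balance filter")
    n_loc = G.n_loci
    pvals = np.ones(n_loc)
    means = np.full(n_loc, np.nan)
    n_het = np.zeros(n_loc, dtype=int)
    warnings: list[str] = []
    for j in range(n_loc):
        het = G.calls[:, j] == 1
        d = G.allele_depths[het, j, :].astype(float)
        tot = d.sum(axis=1)
        usable = tot > 0
        n_skip = int((~usable).sum())
        if n_skip:
            warnings.append(f"{G.loci[j]}: {n_skip} heterozygote(s) without depths skipped")
        d = d[usable]
        tot = tot[usable]
        n_het[j] = len(tot)
        if len(tot) < 2:
            if het.any():
                warnings.append(f"{G.loci[j]}: <2 usable heterozygotes, passed untested")
            continue
        # allele with the lowest overall read count at this locus
        col_tot = G.allele_depths[:, j, :].sum(axis=0)
        low = int(np.argmin(col_tot))
        ratios = d[:, low] / tot
        means[j] = ratios.mean()
        sd = ratios.std(ddof=1)
        if sd == 0:
            pvals[j] = 0.0 if means[j] < 0.5 else (0.5 if means[j] == 0.5 else 1.0)
        else:
            pvals[j] = stats.ttest_1samp(ratios, 0.5, alternative="less").pvalue
    keep = pvals >= alpha
    table = pd.DataFrame({
        "locus": G.loci,
        "n_heterozygotes": n_het,
        "mean_low_allele_ratio": means,
        "p_value": pvals,
        "retained": keep,
    })
    for w in warnings:
        logger.warning(w)
    report = FilterReport("allele_balance", G.loci.copy(), G.loci[~keep], table, warnings)
    return G.subset_loci(keep), report


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def pairwise_fst(G: GenotypeMatrix, group_pair: tuple[str, str]) -> float:
    """Multi-locus Weir & Cockerham (1984) θ between two groups.

    Ratio-of-sums estimator over loci; may be slightly negative near zero
    differentiation.  Returns NaN (with a warning) if every locus is
    monomorphic across both groups.
    """
    g1, g2 = group_pair
    if g1 == g2:
        G.group_mask(g1)          # still validate the group exists
        return 0.0                # degenerate self-comparison: no differentiation
    masks = [G.group_mask(g1), G.group_mask(g2)]
    r = 2
    a_sum = b_sum = c_sum = 0.0
    any_informative = False
    for j in range(G.n_loci):
        n_i, p_i, h_i = [], [], []
        ok = True
        for m in masks:
            col = G.calls[m, j]
            col = col[col != MISSING]
            if len(col) == 0:
                ok = False
                break
            n_i.append(len(col))
            p_i.append(col.sum() / (2 * len(col)))
            h_i.append((col == 1).mean())
        if not ok:
            continue
        n_i = np.array(n_i, float)
        p_i = np.array(p_i, float)
        h_i = np.array(h_i, float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        pbar = (n_i * p_i).sum() / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
        any_informative = True
    denom = a_sum + b_sum + c_sum
    if not any_informative or denom == 0:
        logger.warning("F_ST undefined: no polymorphic loci between %s and %s", g1, g2)
        return float("nan")
    return a_sum / denom


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coords: pd.DataFrame          # individuals × PCs
    loadings: np.ndarray          # PCs × loci
    explained_variance_ratio: np.ndarray
    loci: np.ndarray


def pca_coordinates(
    G: GenotypeMatrix,
    locus_subset: Sequence | None = None,
    scale: bool = True,
    n_components: int = 10,
) -> PCAResult:
    """PCA of the genotype matrix (missing calls mean-imputed per locus).

    Coordinates are deterministic up to axis sign, which is fixed so that the
    loading sum of each component is non-negative.
    """
    sub = G if locus_subset is None else G.subset_loci(locus_subset)
    X = sub.calls.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("locus with no called genotypes in PCA subset")
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X = X - col_mean
    sd = X.std(axis=0, ddof=0)
    polymorphic = sd > 0
    if not polymorphic.any():
        raise ValueError("all loci monomorphic in PCA subset")
    if scale:
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, int((S > 1e-10 * S[0]).sum()) if S[0] > 0 else 1)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    flip = Vt.sum(axis=1) < 0
    Vt[flip] *= -1
    U[:, flip] *= -1
    coords = U * S
    var = S ** 2
    total_var = (X ** 2).sum()
    evr = var / total_var if total_var > 0 else np.zeros_like(var)
    df = pd.DataFrame(coords, index=sub.individuals,
                      columns=[f"PC{i+1}" for i in range(k)])
    return PCAResult(coords=df, loadings=Vt, explained_variance_ratio=evr,
                     loci=sub.loci.copy())
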