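"""Synthetic cohorts with planted within-generation selection.

The generator emulates the statistical design the analysis stack assumes: a
panmictic larval baseline sample plus two juvenile samples that survived one
round of viability selection in contrasting habitats (brackish vs marine).
A configurable subset of loci is under antagonistic selection (habitat A's
selection coefficient is sign-flipped in habitat B); those loci also carry
additive, environment-dependent effects on two correlated fitness-proxy
traits (growth and condition), so the full pipeline — scan, orientation,
polygenic scores, threshold sweep, survival surfaces — can be validated
against known truth.

Selection on survivors is applied as the exact post-selection genotype
distribution (Hardy–Weinberg proportions reweighted by viability fitness,
the infinite-settler-pool limit; with multiplicative fitness across unlinked
loci this factorizes per locus).  The finite-population machinery lives in
:mod:`sgskit.simulate`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .simulate import post_selection_genotype_probs

BASELINE = "larvae"
GROUP_A = "brackish"
GROUP_B = "marine"

#: Trait architecture targeting the empirically observed R² regime:
#: condition driven by brackish-favored alleles (~9% of variance in
#: interaction with habitat), growth by marine-favored alleles (~4%), and a
#: larval growth rate (measured on larvae only) sharing the marine-score
#: architecture (~21%).
DEFAULT_TRAIT_SPEC: dict = {
    "condition": {"r2": 0.087, "score": GROUP_A},
    "growth": {"r2": 0.0385, "score": GROUP_B},
    "larval_growth": {"r2": 0.214, "score": GROUP_B},
}


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for recovery benchmarks."""

    selected_loci: list
    s_brackish: list          # selection coefficient on the ref allele, group A
    s_marine: list            # same, group B
    brackish_allele: list     # 'ref' or 'alt' per selected locus
    baseline_freqs: list      # ref-allele frequency per locus (all loci)
    trait_slopes: dict        # trait -> slope magnitude b
    trait_spec: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: CohortTruth


def _tag_ids(n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """Partition loci into RAD-tags of 1-3 SNPs (most tags carry 1-2)."""
    tags = []
    t = 0
    while len(tags) < n_loci:
        size = rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2])
        tags.extend([f"tag{t}"] * size)
        t += 1
    return np.array(tags[:n_loci], dtype=object)


def generate_cohort(
    n_larvae: int = 44,
    n_juv_a: int = 106,
    n_juv_b: int = 106,
    n_loci: int = 5020,
    n_selected: int = 20,
    s_range: tuple[float, float] = (0.5, 0.5),
    maf_range: tuple[float, float] = (0.05, 0.95),
    selected_maf_range: tuple[float, float] = (0.25, 0.75),
    trait_spec: dict | None = None,
    seed: int = 0,
    antagonism: str = "antagonistic",
    missing_rate: float = 0.0,
) -> Cohort:
    """Generate a genotype matrix, phenotype table and ground truth.

    Baseline ref-allele frequencies are uniform on ``maf_range``
    (``selected_maf_range`` for the planted loci, intermediate by default
    since antagonistic selection maintains segregating variation); larvae are
    Hardy–Weinberg draws, juveniles are post-selection draws at the planted
    loci with per-locus |s| uniform on ``s_range`` (sign of the favored
    allele randomized).  ``antagonism='antagonistic'`` flips the sign of s
    between habitats; ``'conditional'`` sets s to zero in habitat B.
    Traits are environment-dependent linear combinations of planted
    genotypes plus unit Gaussian noise, and lengths/weights are
    back-transformed so the condition factor and standardized length recover
    the planted structure.
    """
    if n_selected > n_loci:
        raise ValueError("n_selected cannot exceed n_loci")
    if antagonism not in ("antagonistic", "conditional"):
        raise ValueError("antagonism must be 'antagonistic' or 'conditional'")
    spec = DEFAULT_TRAIT_SPEC if trait_spec is None else trait_spec
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(*maf_range, size=n_loci)
    selected_idx = rng.choice(n_loci, size=n_selected, replace=False)
    # antagonistic viability selection behaves like balancing selection and
    # keeps the selected alleles segregating at intermediate frequency
    freqs[selected_idx] = rng.uniform(*selected_maf_range, size=n_selected)
    s_mag = rng.uniform(*s_range, size=n_selected)
    sign = rng.choice([-1.0, 1.0], size=n_selected)   # +1: ref allele brackish-favored
    s_a = sign * s_mag
    s_b = -s_a if antagonism == "antagonistic" else np.zeros(n_selected)

    n_total = n_larvae + n_juv_a + n_juv_b
    groups = np.array([BASELINE] * n_larvae + [GROUP_A] * n_juv_a + [GROUP_B] * n_juv_b,
                      dtype=object)
    calls = rng.binomial(2, freqs, size=(n_total, n_loci)).astype(np.int8)
    sl_a = slice(n_larvae, n_larvae + n_juv_a)
    sl_b = slice(n_larvae + n_juv_a, n_total)
    for k, j in enumerate(selected_idx):
        p = freqs[j]
        calls[sl_a, j] = rng.choice(3, size=n_juv_a,
                                    p=post_selection_genotype_probs(p, s_a[k]))
        calls[sl_b, j] = rng.choice(3, size=n_juv_b,
                                    p=post_selection_genotype_probs(p, s_b[k]))

    # Genetic value on the brackish-allele scale: weight per planted locus
    # proportional to |s|, dose of the brackish-favored allele, centered.
    dose = calls[:, selected_idx].astype(float)
    brackish_dose = np.where(sign > 0, dose, 2 - dose)
    p_brack = np.where(sign > 0, freqs[selected_idx], 1 - freqs[selected_idx])
    g_brackish = ((brackish_dose - 2 * p_brack) * s_mag).sum(axis=1)
    var_g = float((s_mag ** 2 * 2 * p_brack * (1 - p_brack)).sum())

    loci = np.array([f"snp{j}" for j in range(n_loci)], dtype=object)
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls[miss] = MISSING

    G = GenotypeMatrix(calls=calls,
                       individuals=np.array([f"ind{i}" for i in range(n_total)],
                                            dtype=object),
                       loci=loci, groups=groups, tags=_tag_ids(n_loci, rng))

    phen = _phenotypes(groups, g_brackish, var_g, spec, rng)
    truth = CohortTruth(
        selected_loci=[loci[j] for j in selected_idx],
        s_brackish=s_a.tolist(),
        s_marine=s_b.tolist(),
        brackish_allele=["ref" if sg > 0 else "alt" for sg in sign],
        baseline_freqs=freqs.tolist(),
        trait_slopes={t: _slope(spec[t]["r2"], var_g) for t in spec},
        trait_spec=spec,
        seed=seed,
    )
    return Cohort(G, phen, truth)


def _slope(r2: float, var_g: float) -> float:
    if var_g <= 0:
        return 0.0
    return float(np.sqrt(r2 / (1 - r2) / var_g))


def _phenotypes(groups, g_brackish, var_g, spec, rng) -> pd.DataFrame:
    """Trait values, lengths/weights and sampling dates per individual."""
    n = len(groups)
    traits: dict[str, np.ndarray] = {}
    for trait, ts in spec.items():
        b = _slope(ts["r2"], var_g)
        g = g_brackish if ts["score"] == GROUP_A else -g_brackish
        slope = np.zeros(n)
        if trait == "larval_growth":
            slope[groups == BASELINE] = b
        else:
            slope[groups == GROUP_A] = b
            slope[groups == GROUP_B] = -b
        traits[trait] = slope * g + rng.normal(0, 1, size=n)

    date = np.empty(n, dtype=object)
    mean_len = np.empty(n)
    for grp, dates, means in (
        (BASELINE, ["2013-04-01"], [12.0]),
        (GROUP_A, ["2013-07-15", "2013-09-15"], [115.0, 130.0]),
        (GROUP_B, ["2013-07-20", "2013-09-20"], [95.0, 108.0]),
    ):
        idx = np.flatnonzero(groups == grp)
        pick = rng.integers(len(dates), size=len(idx))
        date[idx] = np.array(dates, dtype=object)[pick]
        mean_len[idx] = np.array(means)[pick]
    is_larva = groups == BASELINE
    sigma_len = np.where(is_larva, 1.0, 8.0)
    length = mean_len + sigma_len * np.where(is_larva, rng.normal(0, 1, n),
                                             traits["growth"])
    length = np.maximum(length, 1.0)
    # common allometry with a multiplicative condition residual (~8% spread)
    log_w = np.log(1.4e-5) + 3.0 * np.log(length) + 0.08 * np.where(
        is_larva, rng.normal(0, 1, n), traits["condition"])
    weight = np.exp(log_w)
    lg = np.where(is_larva, 1.84 + 0.37 * traits["larval_growth"], np.nan)
    return pd.DataFrame({
        "individual": [f"ind{i}" for i in range(n)],
        "group": groups,
        "date": date,
        "total_length_mm": length,
        "eviscerated_weight_g": weight,
        "larval_growth_um_day": lg,
        "growth_trait": traits["growth"],
        "condition_trait": traits["condition"],
    })


def generate_read_depths(
    G: GenotypeMatrix,
    mean_depth: float = 20.0,
    bias_loci=(),
    bias_strength: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Attach simulated (ref, alt) read depths to a genotype matrix.

    Total depth per called genotype is Poisson(``mean_depth``).
    Heterozygote reads split binomially with ref probability 0.5, except at
    ``bias_loci`` where the split shifts by ``bias_strength`` in favor of the
    locus's major allele — the systematic under-reading of the rarer allele
    (a mapping/assembly artifact) that the allele-balance filter is designed
    to catch.  Homozygotes put all reads on their single allele; missing
    calls get zero depth.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    n_ind, n_loc = G.calls.shape
    total = rng.poisson(mean_depth, size=(n_ind, n_loc))
    total[G.calls == MISSING] = 0
    called = G.calls != MISSING
    with np.errstate(invalid="ignore"):
        freq_ref = np.where(called, G.calls, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1)
    p_ref = np.full(n_loc, 0.5)
    bias_set = set(bias_loci)
    for j, locus in enumerate(G.loci):
        if locus in bias_set:
            p_ref[j] = 0.5 + (bias_strength if freq_ref[j] >= 0.5 else -bias_strength)
    ref = np.zeros_like(total)
    het = G.calls == 1
    ref[het] = rng.binomial(total[het], np.broadcast_to(p_ref, (n_ind, n_loc))[het])
    ref[G.calls == 2] = total[G.calls == 2]
    depths = np.stack([ref, total - ref], axis=2)
    return replace(G, allele_depths=depths)


# ---------------------------------------------------------------------------
# Writers (plain-text interchange)
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF (GT, and AD when present)."""
    gt_map = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    has_ad = G.allele_depths is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=TAG,Number=1,Type=String,Description="RAD tag of origin">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.individuals)) + "\n")
        fmt = "GT:AD" if has_ad else "GT"
        for j, locus in enumerate(G.loci):
            info = f"TAG={G.tags[j]}" if G.tags is not None else "."
            fields = []
            for i in range(G.n_individuals):
                gt = gt_map[int(G.calls[i, j])]
                if has_ad:
                    r, a = G.allele_depths[i, j]
                    fields.append(f"{gt}:{int(r)},{int(a)}")
                else:
                    fields.append(gt)
            fh.write(f"1\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t{info}\t{fmt}\t"
                     + "\t".join(fields) + "\n")


def write_group_map(G: GenotypeMatrix, path) -> None:
    pd.DataFrame({"individual": G.individuals, "group": G.groups}).to_csv(
        path, sep="\t", index=False, header=False)


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index=False)
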