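"""Config-driven end-to-end run: filter → scan → scores → sweep → surfaces.

All stage outputs are pure functions of (inputs, config, seed); re-running
with the same configuration reproduces byte-identical tables.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotypes as gio
from . import polygenic as pg
from . import sgs
from . import surface as surf
from .phenotypes import condition_factor, standardized_length

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = [1e-4, 1e-3, 7.5e-3, 1e-2]


@dataclass
class RunConfig:
    genotypes: str
    groups: str
    format: str = "vcf"
    baseline: str = "larvae"
    group_a: str = "brackish"
    group_b: str = "marine"
    phenotypes: str | None = None
    max_missing_frac: float = 0.10
    maf_min: float = 0.01
    hwe_alpha: float = 1e-3
    allele_balance_alpha: float = 0.05
    n_iter: int = 10_000
    thresholds: list = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    outlier_threshold: float = 1e-3
    grid_n: int = 100
    seed: int = 1
    outdir: str = "sgs_run"

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("threshold list must be non-empty")
        if any(not 0 < t < 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        for f in (self.genotypes, self.groups, self.phenotypes):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict (also written as JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    G = _stage("load")(gio.load_genotypes)(cfg.genotypes, cfg.format, cfg.groups)
    summary["n_individuals"] = G.n_individuals
    summary["n_loci_input"] = G.n_loci

    G, rep = _stage("filter")(gio.filter_loci)(
        G, cfg.max_missing_frac, cfg.maf_min, cfg.hwe_alpha)
    rep.to_tsv(out / "filter_missing_maf_hwe.tsv")
    summary["n_removed_missing_maf_hwe"] = rep.n_removed
    if G.allele_depths is not None:
        G, rep_ab = _stage("allele_balance")(gio.allele_balance_filter)(
            G, cfg.allele_balance_alpha)
        rep_ab.to_tsv(out / "filter_allele_balance.tsv")
        summary["n_removed_allele_balance"] = rep_ab.n_removed
    summary["n_loci_retained"] = G.n_loci

    summary["fst_a_b"] = _stage("fst")(gio.pairwise_fst)(G, (cfg.group_a, cfg.group_b))
    summary["fst_base_a"] = gio.pairwise_fst(G, (cfg.baseline, cfg.group_a))
    summary["fst_base_b"] = gio.pairwise_fst(G, (cfg.baseline, cfg.group_b))

    scan = _stage("scan")(sgs.sgs_scan)(
        G, cfg.group_a, cfg.group_b, baseline=cfg.baseline,
        n_iter=cfg.n_iter, seed=cfg.seed)
    flags = sgs.classify_outliers_vs_baseline(scan)
    scan.merge(flags, on="locus").to_csv(out / "sgs_scan.tsv", sep="\t", index=False)
    summary["outlier_counts"] = {
        str(t): int((scan["p_value"] < t).sum()) for t in cfg.thresholds}

    outliers = sgs.outlier_set(scan, cfg.outlier_threshold)["locus"].tolist()
    summary["n_outliers"] = len(outliers)

    phen = None
    if cfg.phenotypes is not None:
        phen = pd.read_csv(cfg.phenotypes, sep="\t")
        phen = phen.set_index("individual").loc[G.individuals].reset_index()
        juv = phen["group"].isin([cfg.group_a, cfg.group_b]).to_numpy()
        K = np.full(len(phen), np.nan)
        K[juv] = condition_factor(phen.loc[juv, "total_length_mm"],
                                  phen.loc[juv, "eviscerated_weight_g"])
        z = np.full(len(phen), np.nan)
        z[juv] = standardized_length(phen.loc[juv, "total_length_mm"],
                                     phen.loc[juv, "group"], phen.loc[juv, "date"])
        phen["condition_factor"] = K
        phen["std_length"] = z
        phen.to_csv(out / "phenotypes_derived.tsv", sep="\t", index=False)

        habitat = np.where(juv, phen["group"], None)
        sweep_specs = [("condition_factor", "a"), ("std_length", "b")]
        summary["sweeps"] = {}
        for trait_col, score in sweep_specs:
            sw = _stage("sweep")(pg.threshold_sweep)(
                scan, G, phen[trait_col].to_numpy(), habitat,
                cfg.thresholds, score=score,
                group_a=cfg.group_a, group_b=cfg.group_b)
            sw.table.to_csv(out / f"sweep_{trait_col}.tsv", sep="\t", index=False)
            summary["sweeps"][trait_col] = {
                "best_threshold": sw.best_threshold, "best_r2": sw.best_r2}

    if len(outliers) >= 2:
        pca = _stage("pca")(gio.pca_coordinates)(G, outliers, n_components=2)
        coords = pca.coords.to_numpy()[:, :2]
        pca.coords.to_csv(out / "outlier_pca.tsv", sep="\t")
        base = G.groups == cfg.baseline
        score_tables = {}
        summary["surfaces"] = {}
        for grp in (cfg.group_a, cfg.group_b):
            ss = _stage("surface")(surf.survival_surface)(
                coords[G.groups == grp], coords[base],
                grid_n=cfg.grid_n, habitat=grp)
            scores, _ = surf.project_survival_scores(coords, ss)
            score_tables[grp] = scores
            pd.DataFrame(ss.z, index=ss.x, columns=ss.y).to_csv(
                out / f"surface_{grp}.tsv", sep="\t")
            summary["surfaces"][grp] = {
                "z_integral": ss.z_integral(),
                "baseline_positive_fraction": surf.positive_fraction(
                    scores[base]),
            }
        pd.DataFrame({"individual": G.individuals, "group": G.groups,
                      **{f"survival_score_{g}": s for g, s in score_tables.items()}}
                     ).to_csv(out / "survival_scores.tsv", sep="\t", index=False)

        orientation = pg.orient_alleles(
            gio.allele_frequencies(G, [cfg.group_a, cfg.group_b]),
            cfg.group_a, cfg.group_b)
        usable = [l for l in outliers if l in set(orientation["locus"])]
        if usable:
            ss_scores = pg.polygenic_scores(G, orientation, usable)
            juv_mask = np.isin(G.groups, [cfg.group_a, cfg.group_b])
            fit = surf.survival_tradeoff_ancova(
                {g: score_tables[g][juv_mask] for g in score_tables},
                ss_scores.score_a[juv_mask])
            summary["tradeoff"] = {"slopes": fit.slopes,
                                   "interaction_p": fit.interaction_p,
                                   "r2": fit.r_squared}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
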