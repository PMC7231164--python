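"""Forward simulation of one generation of viability selection.

A finite panmictic population of ``N`` diploids carries a biallelic locus at
frequency ``p``.  Genotype fitnesses are ``ω_AA = 1+s``, ``ω_Aa = 1`` and
``ω_aa = 1−s`` (A = reference allele).  One replicate realizes the standing
frequency by a binomial draw (drift), forms Hardy–Weinberg genotype counts,
then draws sample 1 without selection and sample 2 after viability
selection.  Replicates feed the power comparison of the SGS test against
Fisher's exact test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sgs import DEFAULT_PRIOR, sgs_test_locus

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of one viability-selection scenario.

    ``n1``/``n2`` are diploid sample sizes; ``survival_scheme`` chooses
    between independent Bernoulli survival with probability ``ω_g / max(ω)``
    (default) and weighted sampling of survivors without replacement.
    """

    N: int = 10_000
    n1: int = 100
    n2: int = 100
    p: float = 0.5
    s: float = 0.0
    reps: int = 100
    alpha: float = 0.05
    seed: int = 0
    survival_scheme: str = "bernoulli"
    fisher_alternative: str = "two-sided"
    sgs_n_iter: int = 1_000
    prior: tuple[float, float] = DEFAULT_PRIOR

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if not abs(self.s) < 1:
            raise ValueError("|s| must be < 1 so all fitnesses stay positive")
        if self.N < max(self.n1, self.n2):
            raise ValueError("population smaller than a sample")
        if self.survival_scheme not in ("bernoulli", "weighted"):
            raise ValueError("survival_scheme must be 'bernoulli' or 'weighted'")

    @property
    def fitness(self) -> np.ndarray:
        """Fitness by reference-allele copy number (aa, Aa, AA)."""
        return np.array([1 - self.s, 1.0, 1 + self.s])


def post_selection_genotype_probs(p: float, s: float) -> np.ndarray:
    """Deterministic post-selection genotype distribution (aa, Aa, AA).

    Hardy–Weinberg proportions reweighted by the viability fitnesses; the
    infinite-pool limit of one round of viability selection.
    """
    q = 1 - p
    w = np.array([(1 - s) * q * q, 2 * p * q, (1 + s) * p * p])
    tot = w.sum()
    if tot <= 0:
        raise ValueError("degenerate fitness/frequency combination")
    return w / tot


def expected_post_selection_freq(p: float, s: float) -> float:
    """Expected reference-allele frequency after viability selection."""
    probs = post_selection_genotype_probs(p, s)
    return float(probs[2] + probs[1] / 2)


def simulate_replicate(cfg: SimulationConfig, rng: np.random.Generator):
    """One replicate; returns allele counts ``(x1, n1_alleles, x2, n2_alleles)``.

    Selection acts only on sample 2.  If Bernoulli survival leaves fewer than
    ``n2`` survivors the survivor draw is repeated (logged).
    """
    k = rng.binomial(2 * cfg.N, cfg.p)           # drift: standing allele count
    p_pop = k / (2 * cfg.N)
    q = 1 - p_pop
    geno = rng.multinomial(cfg.N, [q * q, 2 * p_pop * q, p_pop * p_pop])
    dose = np.array([0, 1, 2])

    s1 = rng.multivariate_hypergeometric(geno, cfg.n1)
    x1 = int((s1 * dose).sum())

    w = cfg.fitness
    rel = w / w.max()
    if cfg.survival_scheme == "bernoulli":
        for attempt in range(1000):
            survivors = rng.binomial(geno, rel)
            if survivors.sum() >= cfg.n2:
                break
            logger.info("replicate redraw: %d survivors < n2=%d", survivors.sum(), cfg.n2)
        else:
            raise RuntimeError("could not obtain enough survivors")
        s2 = rng.multivariate_hypergeometric(survivors, cfg.n2)
    else:
        # weighted sampling without replacement (Efraimidis–Spirakis keys)
        genotypes = np.repeat(dose, geno)
        keys = rng.random(cfg.N) ** (1.0 / w[genotypes])
        chosen = genotypes[np.argsort(keys)[-cfg.n2:]]
        s2 = np.bincount(chosen, minlength=3)
    x2 = int((s2 * dose).sum())
    return x1, 2 * cfg.n1, x2, 2 * cfg.n2


def fisher_exact(x1: int, n1: int, x2: int, n2: int,
                 alternative: str = "two-sided") -> float:
    """Fisher's exact test on the 2×2 allele-count table.

    Table is ``[[x1, n1−x1], [x2, n2−x2]]`` with ``n_i`` total alleles.
    An empty margin gives P = 1.
    """
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative=alternative)[1])


@dataclass
class PowerGrid:
    """Power of SGS and Fisher tests over a (p, s) grid."""

    table: pd.DataFrame
    alpha: float
    reps: int

    def cell(self, p: float, s: float) -> pd.Series:
        t = self.table
        return t[(t["p"] == p) & (t["s"] == s)].iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def power_grid(
    p_values,
    s_values,
    cfg_base: SimulationConfig | None = None,
) -> PowerGrid:
    """Estimate rejection rates of both tests across a (p, s) grid.

    Per cell, ``cfg.reps`` replicates are simulated and each is tested with
    the SGS test and Fisher's exact test at level ``cfg.alpha``; power is the
    rejection fraction, reported with its binomial Monte-Carlo SE.
    """
    cfg_base = cfg_base or SimulationConfig()
    p_values = list(p_values)
    s_values = list(s_values)
    if not p_values or not s_values or cfg_base.reps < 1:
        raise ValueError("empty grid or reps < 1")
    rows = []
    for i, p in enumerate(p_values):
        for j, s in enumerate(s_values):
            cfg = replace(cfg_base, p=p, s=s)
            rng = np.random.default_rng([cfg_base.seed, i, j])
            rej_sgs = rej_fisher = 0
            for _ in range(cfg.reps):
                x1, m1, x2, m2 = simulate_replicate(cfg, rng)
                res = sgs_test_locus(x1, m1, x2, m2, cfg.sgs_n_iter, rng, cfg.prior)
                if res.p_value < cfg.alpha:
                    rej_sgs += 1
                if fisher_exact(x1, m1, x2, m2, cfg.fisher_alternative) < cfg.alpha:
                    rej_fisher += 1
            pow_s = rej_sgs / cfg.reps
            pow_f = rej_fisher / cfg.reps
            rows.append({
                "p": p, "s": s,
                "power_sgs": pow_s,
                "power_fisher": pow_f,
                "se_sgs": np.sqrt(pow_s * (1 - pow_s) / cfg.reps),
                "se_fisher": np.sqrt(pow_f * (1 - pow_f) / cfg.reps),
                "reps": cfg.reps,
            })
    return PowerGrid(pd.DataFrame(rows), cfg_base.alpha, cfg_base.reps)
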