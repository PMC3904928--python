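"""Case-control simulation on synthetic haplotype pools.

A haplotype pool is a fixed collection of phased chromosomes for a short
coding region (default 4000 haplotypes, 3 kb).  Sites carry allele
frequencies drawn from a rare-skewed frequency spectrum (by default
proportional to 1/x over allele counts x = 1..n_hap-1, the neutral shape,
which purifying selection only sharpens further toward rare alleles), and
haplotypes are sampled site-independently at those frequencies.  Pools
produced by external forward simulators can be imported through the
rectangular pool file format instead.

Individuals are formed by drawing two haplotypes at random; disease status
follows a linear logistic model

    logit P(D=1) = logit(p0) + sum_l log(OR_l) * e_l,

with baseline probability p0 = 1% for the wild-type genotype.  Four
phenotype scenarios are provided:

* ``Rare`` — a random half of the rare sites (pool MAF < 1%) causal, OR 3;
* ``LowFrequency`` — one random site with pool MAF in [1%, 5%] causal,
  OR 2.5 (falling back to the lowest-MAF site above 5% when none exists);
* ``Common`` — one random site with pool MAF > 5% causal, OR 1.5;
* ``Interaction`` — a random half of the rare sites causal with OR 6 per
  qualifying haplotype, where a haplotype qualifies only when the rare
  minor allele sits on the same haplotype (cis) as the minor allele of a
  common partner site chosen beforehand.

Case/control quotas are filled by rejection sampling, and the study driver
pairs the simulator with the region tests to estimate empirical power and
type-I error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .grouped_test import Partition, maf_partition, permutation_test
from .score_core import GenotypeMatrix, InvalidInputError, prepare_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePool",
    "PhenotypeModelSpec",
    "Replicate",
    "StudyConfig",
    "generate_haplotype_pool",
    "make_model",
    "sample_replicate",
    "run_power_study",
]

RARE_MAF = 0.01
COMMON_MAF = 0.05


@dataclass
class HaplotypePool:
    """Pool of phased haplotypes; every retained site is segregating."""

    haplotypes: np.ndarray  # (n_hap, n_sites) 0/1
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, s = self.haplotypes.shape
        if s != self.positions.shape[0]:
            raise InvalidInputError("positions do not match the haplotype matrix")
        counts = self.haplotypes.sum(axis=0)
        if np.any((counts == 0) | (counts == n)):
            raise InvalidInputError("pool contains non-segregating sites")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def allele_frequency(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    @property
    def pool_maf(self) -> np.ndarray:
        f = self.allele_frequency
        return np.minimum(f, 1.0 - f)

    def minor_haplotypes(self) -> np.ndarray:
        """Haplotypes recoded so 1 marks the pool-minor allele at every site."""
        h = self.haplotypes.copy()
        flip = self.allele_frequency > 0.5
        h[:, flip] = 1 - h[:, flip]
        return h


def generate_haplotype_pool(
    n_hap: int = 4000,
    region_bp: int = 3000,
    target_density: float = 1.0 / 60.0,
    sfs_shape: float = 1.0,
    seed: int = 0,
) -> HaplotypePool:
    """Synthesize a haplotype pool with a rare-skewed frequency spectrum.

    The number of sites is Poisson with mean ``region_bp * target_density``
    (default about 50 sites on 3 kb, a plausible nonsynonymous site count
    for a selected coding region).  Site allele counts x are drawn with
    probability proportional to x**(-sfs_shape) on {1, ..., n_hap-1}
    (``sfs_shape=1`` is the standard neutral spectrum); haplotypes carry the
    allele independently across sites at frequency x/n_hap.  Sites that come
    out non-segregating are dropped.
    """
    if n_hap < 4 or region_bp < 1:
        raise InvalidInputError("need n_hap >= 4 and region_bp >= 1")
    rng = np.random.default_rng(seed)
    n_sites = max(1, int(rng.poisson(region_bp * target_density)))
    x = np.arange(1, n_hap)
    weights = x.astype(float) ** (-sfs_shape)
    weights /= weights.sum()
    counts = rng.choice(x, size=n_sites, p=weights)
    freqs = counts / n_hap
    hap = (rng.random((n_hap, n_sites)) < freqs).astype(np.int8)
    seg = (hap.sum(axis=0) > 0) & (hap.sum(axis=0) < n_hap)
    hap = hap[:, seg]
    positions = np.sort(rng.choice(region_bp, size=hap.shape[1], replace=False))
    return HaplotypePool(haplotypes=hap, positions=positions + 1)


@dataclass
class PhenotypeModelSpec:
    """Causal-site configuration for one phenotype scenario."""

    model: str
    causal_sites: np.ndarray
    odds_ratios: np.ndarray
    baseline_prob: float = 0.01
    interaction_partner: Optional[int] = None

    def __post_init__(self) -> None:
        self.causal_sites = np.asarray(self.causal_sites, dtype=np.int64)
        self.odds_ratios = np.asarray(self.odds_ratios, dtype=float)
        if not 0 < self.baseline_prob < 1:
            raise InvalidInputError("baseline probability must lie in (0, 1)")
        if (self.odds_ratios <= 0).any():
            raise InvalidInputError("odds ratios must be positive")
        if self.causal_sites.shape != self.odds_ratios.shape:
            raise InvalidInputError("need one odds ratio per causal site")

    @classmethod
    def null(cls, baseline_prob: float = 0.01) -> "PhenotypeModelSpec":
        return cls(
            model="Null",
            causal_sites=np.empty(0, dtype=np.int64),
            odds_ratios=np.empty(0),
            baseline_prob=baseline_prob,
        )


def make_model(
    pool: HaplotypePool, model_name: str, seed: int = 0, baseline_prob: float = 0.01
) -> PhenotypeModelSpec:
    """Instantiate one of the phenotype scenarios on a pool.

    ``Rare``: half the rare sites causal at OR 3 (half rounds to nearest,
    ties down).  ``LowFrequency``: one site with MAF in [1%, 5%] at OR 2.5,
    else the lowest-MAF site above 5%.  ``Common``: one site with MAF > 5%
    at OR 1.5.  ``Interaction``: half the rare sites at OR 6 with a common
    partner site fixed at random beforehand.  ``Null``: no causal sites.
    """
    rng = np.random.default_rng(seed)
    maf = pool.pool_maf
    rare = np.flatnonzero(maf < RARE_MAF)
    low = np.flatnonzero((maf >= RARE_MAF) & (maf <= COMMON_MAF))
    common = np.flatnonzero(maf > COMMON_MAF)
    name = model_name.strip().lower().replace(" ", "").replace("_", "")

    if name == "null":
        return PhenotypeModelSpec.null(baseline_prob)
    if name == "rare":
        k = len(rare) // 2  # "50%", round to nearest with ties down
        if k == 0:
            raise InvalidInputError("pool has too few rare sites for the Rare model")
        causal = np.sort(rng.choice(rare, size=k, replace=False))
        return PhenotypeModelSpec("Rare", causal, np.full(k, 3.0), baseline_prob)
    if name == "lowfrequency":
        if len(low):
            site = int(rng.choice(low))
        elif len(common):
            site = int(common[np.argmin(maf[common])])  # lowest MAF above 5%
        else:
            raise InvalidInputError("pool has no low-frequency or common site")
        return PhenotypeModelSpec(
            "LowFrequency", np.array([site]), np.array([2.5]), baseline_prob
        )
    if name == "common":
        if not len(common):
            raise InvalidInputError("pool has no common site for the Common model")
        site = int(rng.choice(common))
        return PhenotypeModelSpec("Common", np.array([site]), np.array([1.5]), baseline_prob)
    if name == "interaction":
        if not len(common):
            raise InvalidInputError("pool has no common partner site")
        partner = int(rng.choice(common))
        eligible = rare[rare != partner]
        k = len(eligible) // 2
        if k == 0:
            raise InvalidInputError("pool has too few rare sites for the Interaction model")
        causal = np.sort(rng.choice(eligible, size=k, replace=False))
        return PhenotypeModelSpec(
            "Interaction", causal, np.full(k, 6.0), baseline_prob, interaction_partner=partner
        )
    raise InvalidInputError(f"unknown phenotype model {model_name!r}")


@dataclass
class Replicate:
    """One sampled case-control data set with phase information."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray  # 0/1, cases first
    haplotype_pairs: np.ndarray  # (N, 2) indices into the pool
    n_cases: int
    n_controls: int


def _disease_probability(
    minor_hap: np.ndarray, pairs: np.ndarray, spec: PhenotypeModelSpec
) -> np.ndarray:
    """Logistic disease probability for individuals given as haplotype pairs."""
    b0 = logit(spec.baseline_prob)
    if len(spec.causal_sites) == 0:
        return np.full(pairs.shape[0], spec.baseline_prob)
    h1 = minor_hap[pairs[:, 0]][:, spec.causal_sites]
    h2 = minor_hap[pairs[:, 1]][:, spec.causal_sites]
    if spec.interaction_partner is not None:
        # cis rule: a haplotype counts only if it also carries the partner's
        # minor allele on the SAME haplotype
        p1 = minor_hap[pairs[:, 0], spec.interaction_partner][:, None]
        p2 = minor_hap[pairs[:, 1], spec.interaction_partner][:, None]
        exposure = h1 * p1 + h2 * p2
    else:
        exposure = h1 + h2
    eta = b0 + exposure @ np.log(spec.odds_ratios)
    return expit(eta)


def sample_replicate(
    pool: HaplotypePool,
    spec: PhenotypeModelSpec,
    n_cases: int = 500,
    n_controls: int = 500,
    seed: int = 0,
    max_draws: Optional[int] = None,
) -> Replicate:
    """Rejection-sample a case-control replicate from a pool.

    Individuals are random haplotype pairs; disease is Bernoulli under the
    logistic model and draws continue until both quotas are met exactly.
    """
    if n_cases < 1 or n_controls < 1:
        raise InvalidInputError("case and control quotas must be at least 1")
    if max_draws is None:
        # cases are the bottleneck at a ~1% baseline
        max_draws = int(500 * (n_cases + n_controls) / max(spec.baseline_prob * 100, 0.1))
    rng = np.random.default_rng(seed)
    minor_hap = pool.minor_haplotypes()
    case_pairs, control_pairs = [], []
    drawn = 0
    need_cases, need_controls = n_cases, n_controls
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quotas unmet after {drawn} draws; "
                "increase max_draws or the baseline probability"
            )
        batch = min(max(4 * (need_cases + need_controls), 2000), max_draws - drawn)
        pairs = rng.integers(0, pool.n_hap, size=(batch, 2))
        drawn += batch
        prob = _disease_probability(minor_hap, pairs, spec)
        disease = rng.random(batch) < prob
        if need_cases > 0:
            take = pairs[disease][:need_cases]
            case_pairs.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = pairs[~disease][:need_controls]
            control_pairs.append(take)
            need_controls -= take.shape[0]
    pairs = np.vstack(case_pairs + control_pairs)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    geno = minor_hap[pairs[:, 0]] + minor_hap[pairs[:, 1]]
    gm = GenotypeMatrix(
        values=geno.astype(np.int64),
        variant_ids=[f"s{p}" for p in pool.positions],
        positions=pool.positions,
    )
    return Replicate(
        genotypes=gm,
        phenotype=y,
        haplotype_pairs=pairs,
        n_cases=n_cases,
        n_controls=n_controls,
    )


@dataclass
class StudyConfig:
    """Declarative configuration of a power / type-I-error study."""

    models: Sequence[str] = ("Null", "Rare", "LowFrequency", "Common")
    n_pools: int = 10
    n_replicates: int = 200
    n_cases: int = 500
    n_controls: int = 500
    interaction_cases: int = 1000
    interaction_controls: int = 1000
    B: int = 500
    alpha: float = 0.05
    maf_threshold: float = 0.01
    mode: str = "empirical-cdf"
    seed: int = 0
    pool_kwargs: dict = field(default_factory=dict)


def run_power_study(config: StudyConfig) -> pd.DataFrame:
    """Estimate empirical power (or type-I error for the null model).

    For each phenotype model, replicates draw a pool at random, sample a
    case-control data set, and run both the MAF-partitioned test and the
    score test by permutation; power is the fraction of replicates with
    p <= alpha, reported with its binomial standard error.
    """
    rng = np.random.default_rng(config.seed)
    pools = [
        generate_haplotype_pool(seed=int(rng.integers(2**31)), **config.pool_kwargs)
        for _ in range(config.n_pools)
    ]
    rows = []
    for model in config.models:
        if model.lower() == "interaction":
            ncase, nctrl = config.interaction_cases, config.interaction_controls
        else:
            ncase, nctrl = config.n_cases, config.n_controls
        hits = {"partitioned": 0, "score": 0}
        used = 0
        for _ in range(config.n_replicates):
            pool_idx = int(rng.integers(len(pools)))
            pool = pools[pool_idx]
            try:
                spec = make_model(pool, model, seed=int(rng.integers(2**31)))
            except InvalidInputError:
                logger.warning("pool %d lacks eligible sites for %s; redrawing", pool_idx, model)
                continue
            rep = sample_replicate(
                pool, spec, ncase, nctrl, seed=int(rng.integers(2**31))
            )
            gm = prepare_genotypes(rep.genotypes)
            part = maf_partition(gm, config.maf_threshold)
            res = permutation_test(
                gm,
                rep.phenotype,
                part,
                B=config.B,
                seed=int(rng.integers(2**31)),
                mode=config.mode,
            )
            used += 1
            hits["partitioned"] += res.p_value <= config.alpha
            hits["score"] += res.p_value_score <= config.alpha
        for test, h in hits.items():
            power = h / used if used else float("nan")
            se = float(np.sqrt(power * (1 - power) / used)) if used else float("nan")
            rows.append(
                {
                    "model": model,
                    "test": test,
                    "power": power,
                    "se": se,
                    "n_replicates": used,
                    "alpha": config.alpha,
                    "B": config.B,
                    "seed": config.seed,
                }
            )
            logger.info("%s / %s: power %.3f (se %.3f)", model, test, power, se)
    return pd.DataFrame(rows)
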