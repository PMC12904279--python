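"""Synthetic select-and-resequence experiments.

Generates the objects the analysis consumes: a strain genotype panel
organised into perfect-linkage LD groups on three replicons, a
host-dependent fitness landscape with planted pervasive and
limited-effect causal variant groups, post-selection communities,
binomially sampled pooled read counts, and pot-level host traits.

Defaults emulate the study design this package targets: an 86-strain
*Sinorhizobium meliloti* community typed at ~30 076 LD-group-tagged
SNPs across the chromosome, pSymA and pSymB, inoculated at near-equal
frequencies onto a wild-type host (A17) plus 15 nodulating symbiosis
mutants, five replicate pots per host in five blocks, and pooled
sequencing at ~75x mean depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_REPLICONS,
    PooledCounts,
    StrainGenotypeMatrix,
    ValidationError,
)

# rng stream offsets so each operation draws from its own substream
_GENOMES, _LANDSCAPE, _INOCULUM, _READS, _TRAITS = 1, 2, 3, 4, 5

STAGES = ("early", "late", "AON")


class InvalidConfigError(ValidationError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic select-and-resequence experiment.

    Effect sizes are in log2-fitness units: a causal alternate allele
    with beta = 1.5 multiplies a carrier's frequency ratio by 2**1.5
    in the hosts where it acts.
    """

    n_strains: int = 86
    variants_per_replicon: Mapping[str, int] = field(
        default_factory=lambda: {"chromosome": 12000, "pSymA": 9000, "pSymB": 9076}
    )
    ld_block_size: float = 2.0  # mean variants per LD group
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    n_hosts: int = 16  # including one wild type
    replicates_per_host: int = 5
    depth_mean: float = 75.0  # reads per variant
    seq_error: float = 1e-3
    n_pervasive: int = 2  # causal groups with effects in >=6 mutant hosts
    n_limited: int = 10  # causal groups with effects in <=5 mutant hosts
    pervasive_hosts: int = 8  # mutant hosts a pervasive group acts in
    limited_hosts_max: int = 3  # upper bound on hosts for a limited group
    effect_size_sd: float = 1.5  # |beta|, log2-fitness units
    tradeoff_fraction: float = 1.0  # P(pervasive wild-type sign is flipped)
    noise_sd: float = 0.5  # strain x host fitness noise, log2 units
    baseline_sd: float = 0.5  # strain main effect (cancels in shifts), log2 units
    causal_maf_range: tuple[float, float] | None = None  # optional planted-group alt-freq window
    seed: int = 0
    n_inoculum_aliquots: int = 8
    # Dirichlet concentration per strain; 10 reproduces the emulated study's
    # inoculum spread (5-95% strain frequency ~0.006-0.018 around ~1/86)
    inoculum_concentration: float = 10.0
    wildtype: str = "A17"

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise InvalidConfigError("n_strains must be >= 2")
        for name in ("n_hosts", "replicates_per_host", "n_inoculum_aliquots"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.depth_mean <= 0:
            raise InvalidConfigError("depth_mean must be positive")
        for name in ("seq_error", "tradeoff_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must be a probability")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("allele_freq_range must lie within (0, 0.5]")
        if self.ld_block_size < 1:
            raise InvalidConfigError("ld_block_size must be >= 1")
        if min(self.variants_per_replicon.values()) < 1:
            raise InvalidConfigError("each replicon needs >= 1 variant")
        if self.n_pervasive < 0 or self.n_limited < 0:
            raise InvalidConfigError("causal-group counts must be >= 0")

    # -- derived labels --------------------------------------------------
    @property
    def hosts(self) -> list[str]:
        mutants = [f"m{i:02d}" for i in range(1, self.n_hosts)]
        return [self.wildtype] + mutants

    @property
    def mutant_hosts(self) -> list[str]:
        return self.hosts[1:]

    def stage_of(self, host: str) -> str:
        if host == self.wildtype:
            return "wildtype"
        i = self.mutant_hosts.index(host)
        return STAGES[i % len(STAGES)]


@dataclass
class CausalGroup:
    """A planted causal LD group and its per-host allele effects."""

    group_id: str
    kind: str  # "pervasive" or "limited"
    host_effects: dict  # mutant host -> beta (log2 units)
    wildtype_effect: float  # beta in the wild-type host

    @property
    def mutant_hosts(self) -> list[str]:
        return [h for h, b in self.host_effects.items() if b != 0.0]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    true_inoculum_freqs: pd.Series  # simplex over strains
    true_fitness: pd.DataFrame  # strains x hosts, log2 units
    causal_groups: list  # list[CausalGroup]
    true_final_freqs: pd.DataFrame | None = None  # strains x samples


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_strain_genomes(config: SimulationConfig) -> StrainGenotypeMatrix:
    """Draw a biallelic 0/1 panel partitioned into perfect-LD groups.

    Variants within one LD group share a single carrier set, so their
    pairwise genotype correlation across strains is exactly 1. Each
    replicon draws its carrier sets independently, giving the replicons
    distinct strain-relatedness structure.
    """
    rng = np.random.default_rng([config.seed, _GENOMES])
    n = config.n_strains
    lo, hi = config.allele_freq_range
    cols, meta = [], []
    for replicon, n_var in config.variants_per_replicon.items():
        made = 0
        group_idx = 0
        while made < n_var:
            if config.ld_block_size <= 1:
                size = 1
            else:
                size = 1 + rng.poisson(config.ld_block_size - 1.0)
            size = min(size, n_var - made)
            group_idx += 1
            gid = f"{replicon}_g{group_idx}"
            p = rng.uniform(lo, hi)
            k = int(np.clip(round(p * n), 1, n // 2))
            carriers = rng.choice(n, size=k, replace=False)
            col = np.zeros(n)
            col[carriers] = 1.0
            for _ in range(size):
                made += 1
                vid = f"{replicon}:{made * 100}"
                cols.append(col)
                meta.append((vid, replicon, made * 100, gid))
    strain_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    variant_ids = [m[0] for m in meta]
    calls = pd.DataFrame(
        np.column_stack(cols), index=strain_ids, columns=variant_ids
    )
    variants = pd.DataFrame(
        [(m[1], m[2], m[3]) for m in meta],
        index=pd.Index(variant_ids, name="variant_id"),
        columns=["replicon", "pos", "ld_group"],
    )
    replicon_set = tuple(config.variants_per_replicon)
    if set(replicon_set) <= set(DEFAULT_REPLICONS):
        replicon_set = DEFAULT_REPLICONS
    return StrainGenotypeMatrix(calls, variants, replicon_set)


# ---------------------------------------------------------------------------
# fitness landscape
# ---------------------------------------------------------------------------

def simulate_fitness_landscape(
    config: SimulationConfig, genotypes: StrainGenotypeMatrix
) -> SyntheticTruth:
    """Plant causal LD groups and build the strain x host fitness matrix.

    w(strain, host) = strain baseline + host intercept
                      + sum over causal groups of beta_vh * g_v
                      + N(0, noise_sd).

    Pervasive groups act (same sign) in ``pervasive_hosts`` mutant
    hosts and always carry a wild-type effect whose sign is flipped
    with probability ``tradeoff_fraction``; limited groups act in at
    most ``limited_hosts_max`` mutant hosts and have no wild-type
    effect. Pervasive groups are planted on pSymA when that replicon
    exists (the symbiotic replicon carries most pervasive variation in
    the system this emulates); limited groups are drawn from all
    replicons.
    """
    rng = np.random.default_rng([config.seed, _LANDSCAPE])
    mutants = config.mutant_hosts
    if config.pervasive_hosts > len(mutants) and config.n_pervasive > 0:
        raise InvalidConfigError("pervasive_hosts exceeds number of mutant hosts")

    groups = genotypes.ld_map()
    by_replicon = genotypes.variants.groupby("replicon")["ld_group"].unique()
    psyma_groups = list(by_replicon.get("pSymA", np.array([], dtype=object)))
    all_groups = list(pd.unique(groups))

    af = genotypes.alt_freq()

    def maf_ok(gid) -> bool:
        # causal alleles sit at the low alternate-allele frequencies the
        # emulated study reported for its candidates (AF ~0.05-0.14)
        if config.causal_maf_range is None:
            return True
        lo, hi = config.causal_maf_range
        tag = groups.index[groups == gid][0]
        return lo <= af[tag] <= hi

    n_causal = config.n_pervasive + config.n_limited
    if n_causal:
        eligible = [g for g in all_groups if maf_ok(g)]
        if len(eligible) < n_causal:  # too small a panel: ignore the MAF window
            eligible = all_groups
        all_groups = eligible
        psyma_eligible = [g for g in psyma_groups if g in set(eligible)]
        psyma_groups = psyma_eligible or psyma_groups
    pool_perv = psyma_groups if psyma_groups else all_groups
    if config.n_pervasive > len(pool_perv):
        raise InvalidConfigError("more pervasive groups requested than available")
    perv_ids = list(rng.choice(pool_perv, size=config.n_pervasive, replace=False))
    remaining = [g for g in all_groups if g not in set(perv_ids)]
    if config.n_limited > len(remaining):
        raise InvalidConfigError("more limited groups requested than available")
    lim_ids = list(rng.choice(remaining, size=config.n_limited, replace=False))

    causal: list[CausalGroup] = []
    for gid in perv_ids:
        hosts = list(rng.choice(mutants, size=config.pervasive_hosts, replace=False))
        sign = 1.0  # alternate allele favoured in mutant hosts
        beta = sign * config.effect_size_sd
        wt_beta = -beta if rng.random() < config.tradeoff_fraction else beta
        causal.append(CausalGroup(gid, "pervasive", {h: beta for h in hosts}, wt_beta))
    for gid in lim_ids:
        k = int(rng.integers(1, config.limited_hosts_max + 1))
        hosts = list(rng.choice(mutants, size=k, replace=False))
        beta = float(rng.choice([-1.0, 1.0])) * config.effect_size_sd
        causal.append(CausalGroup(gid, "limited", {h: beta for h in hosts}, 0.0))

    # one tag variant represents each causal group (members are in perfect LD)
    tag_of = {}
    for gid in perv_ids + lim_ids:
        tag_of[gid] = groups.index[groups == gid][0]

    hosts = config.hosts
    n, h = config.n_strains, len(hosts)
    baseline = rng.normal(0.0, config.baseline_sd, size=n)
    host_int = rng.normal(0.0, 1.0, size=h)
    w = baseline[:, None] + host_int[None, :]
    for cg in causal:
        g = genotypes.calls[tag_of[cg.group_id]].to_numpy()
        betas = np.array(
            [
                cg.wildtype_effect if host == config.wildtype
                else cg.host_effects.get(host, 0.0)
                for host in hosts
            ]
        )
        w = w + np.outer(g, betas)
    w = w + rng.normal(0.0, config.noise_sd, size=(n, h))
    true_fitness = pd.DataFrame(w, index=genotypes.strain_ids, columns=hosts)

    inoculum = simulate_inoculum(config)
    return SyntheticTruth(inoculum, true_fitness, causal)


def simulate_inoculum(config: SimulationConfig) -> pd.Series:
    """Near-equal inoculum frequencies (a mildly uneven Dirichlet draw)."""
    rng = np.random.default_rng([config.seed, _INOCULUM])
    alpha = np.full(config.n_strains, config.inoculum_concentration)
    f = rng.dirichlet(alpha)
    ids = [f"S{i:03d}" for i in range(1, config.n_strains + 1)]
    return pd.Series(f, index=ids, name="inoculum_freq")


# ---------------------------------------------------------------------------
# selection and sequencing
# ---------------------------------------------------------------------------

def simulate_selection(
    inoculum_freqs: pd.Series | np.ndarray, fitness: pd.Series | np.ndarray
) -> pd.Series | np.ndarray:
    """One episode of selection: f'_i proportional to f_i * 2**w_i.

    Inverts the relative-fitness definition w = log2(final/initial) up
    to the common normalisation constant.
    """
    f = np.asarray(inoculum_freqs, dtype=float)
    w = np.asarray(fitness, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("fitness values must be finite")
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("inoculum frequencies must be on the simplex")
    out = f * np.exp2(w)
    out = out / out.sum()
    if isinstance(inoculum_freqs, pd.Series):
        return pd.Series(out, index=inoculum_freqs.index)
    return out


def simulate_pool_reads(
    freqs: pd.Series,
    genotypes: StrainGenotypeMatrix,
    depth_mean: float,
    seq_error: float,
    seed,
    sample_id: str = "pool",
) -> PooledCounts:
    """Binomial read sampling from a pooled community.

    Per variant v: depth n_v ~ Poisson(depth_mean) and alternate count
    a_v ~ Binomial(n_v, q_v(1-e) + (1-q_v)e) with q_v the
    frequency-weighted alternate-allele dosage.
    """
    if depth_mean <= 0:
        raise InvalidConfigError("depth_mean must be positive")
    f = freqs.reindex(genotypes.strain_ids).to_numpy(dtype=float)
    if np.isnan(f).any() or (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("freqs must be a simplex over the panel's strains")
    g = genotypes.dosage()
    if np.isnan(g).any():
        raise ValueError("panel has missing calls; simulation requires complete genotypes")
    q = f @ g
    m = q * (1.0 - seq_error) + (1.0 - q) * seq_error
    rng = np.random.default_rng(seed)
    n = rng.poisson(depth_mean, size=g.shape[1])
    a = rng.binomial(n, m)
    counts = pd.DataFrame(
        {"ref_count": n - a, "alt_count": a},
        index=genotypes.variant_ids.rename("variant_id"),
    )
    return PooledCounts(sample_id, counts)


# ---------------------------------------------------------------------------
# host traits
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = (
    "nodules_per_plant",
    "avg_nodule_area",
    "total_nodule_area",
    "biomass_per_plant",
    "root_shoot_ratio",
    "cfu_per_plant",
    "cfu_per_nodule",
)


def simulate_host_traits(
    config: SimulationConfig,
    true_fitness: pd.DataFrame,
    loading: float = 1.0,
    trait_noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Pot-level host traits with a configurable loading on host quality.

    Host quality is the standardized host-mean fitness. Positive
    ``loading`` makes hosts that support higher rhizobial fitness
    larger (biomass, nodule area, CFU) with lower root:shoot ratio --
    the mutualism-reinforcing covariance the analysis probes.
    """
    rng = np.random.default_rng([config.seed, _TRAITS])
    hosts = list(true_fitness.columns)
    qual = true_fitness.mean(axis=0).to_numpy()
    sd = qual.std()
    z = (qual - qual.mean()) / sd if sd > 0 else np.zeros_like(qual)
    rows = []
    for b in range(1, config.replicates_per_host + 1):
        block_eff = rng.normal(0.0, 0.1)
        for hi, host in enumerate(hosts):
            e = lambda: rng.normal(0.0, trait_noise_sd)
            base = loading * z[hi] + block_eff
            n_plants = 3
            nodules = rng.poisson(np.exp(3.5 + 0.3 * base + 0.3 * e()))
            avg_area = np.exp(0.5 + 0.3 * base + e())
            biomass = np.exp(1.0 + 0.5 * base + e())
            root_shoot = np.exp(-0.2 - 0.4 * base + e())
            cfu_nod = np.exp(np.log(2e5) + 0.8 * base + e())
            rows.append(
                {
                    "sample_id": f"{host}_b{b}",
                    "host_genotype": host,
                    "block": b,
                    "n_plants": n_plants,
                    "nodules_per_plant": nodules / n_plants,
                    "avg_nodule_area": avg_area,
                    "total_nodule_area": avg_area * nodules / n_plants,
                    "biomass_per_plant": biomass,
                    "root_shoot_ratio": root_shoot,
                    "cfu_per_plant": cfu_nod * nodules / n_plants,
                    "cfu_per_nodule": cfu_nod,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    """Everything one greenhouse run would hand to the pipeline."""

    config: SimulationConfig
    genotypes: StrainGenotypeMatrix
    truth: SyntheticTruth
    inoculum_counts: list  # list[PooledCounts], one per aliquot
    sample_counts: dict  # sample id -> PooledCounts (nodule pools)
    samplesheet: pd.DataFrame
    traits: pd.DataFrame


def simulate_experiment(
    config: SimulationConfig, nodule_subsample: int | None = None
) -> SimulatedExperiment:
    """Run the whole generative model under one seed.

    Selection acts once (inoculum -> nodule pool). Replicate pots of a
    host share the host's true post-selection community and differ by
    read sampling; ``nodule_subsample`` optionally adds a multinomial
    nodule-occupancy draw of that many nodules per pot (default off:
    the emulated design pools >100 nodules per pot precisely to damp
    this stochasticity).
    """
    genotypes = simulate_strain_genomes(config)
    truth = simulate_fitness_landscape(config, genotypes)
    f0 = truth.true_inoculum_freqs

    inoculum_counts = [
        simulate_pool_reads(
            f0, genotypes, config.depth_mean, config.seq_error,
            [config.seed, _READS, 0, k], sample_id=f"inoculum_a{k}",
        )
        for k in range(1, config.n_inoculum_aliquots + 1)
    ]

    sample_counts: dict[str, PooledCounts] = {}
    final_cols = {}
    sheet_rows = []
    for hi, host in enumerate(config.hosts):
        f_final = simulate_selection(f0, truth.true_fitness[host])
        for b in range(1, config.replicates_per_host + 1):
            sid = f"{host}_b{b}"
            f_pot = f_final
            if nodule_subsample is not None:
                rng = np.random.default_rng([config.seed, _READS, 1, hi, b])
                occ = rng.multinomial(nodule_subsample, f_final.to_numpy())
                f_pot = pd.Series(occ / occ.sum(), index=f_final.index)
            sample_counts[sid] = simulate_pool_reads(
                f_pot, genotypes, config.depth_mean, config.seq_error,
                [config.seed, _READS, 2, hi, b], sample_id=sid,
            )
            final_cols[sid] = f_pot
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "host_genotype": host,
                    "stage_category": config.stage_of(host),
                    "block": b,
                    "n_plants": 3,
                    "n_nodules": nodule_subsample if nodule_subsample else 120,
                }
            )
    truth.true_final_freqs = pd.DataFrame(final_cols)
    samplesheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    traits = simulate_host_traits(config, truth.true_fitness)
    return SimulatedExperiment(
        config, genotypes, truth, inoculum_counts, sample_counts, samplesheet, traits
    )
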