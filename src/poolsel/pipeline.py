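"""End-to-end orchestration: simulate -> estimate -> fitness -> gwas ->
rank -> rda, with a manifest of output hashes and a markdown report.

Each stage writes its artifacts under the run directory and hands its
in-memory results to the next stage. Per-stage seeds are derived from
the master seed by fixed offsets, so a rerun with the same config is
hash-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitness as fit_mod
from . import frequency, io, lmm, multivariate, ranking
from .datatypes import AssociationResult
from .simulate import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)

STAGES = ("simulate", "estimate", "fitness", "gwas", "rank", "rda", "report")

# per-stage seed offsets from the master seed
_SEED_OFFSETS = {"simulate": 0, "estimate": 1000, "rda": 2000}


@dataclass
class RunConfig:
    """Parameters of one pipeline run (echoed into the run log)."""

    outdir: str = "poolsel_run"
    seed: int = 1
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    floor: float = -8.0
    seq_error: float = 1e-3
    aggregate: str = "mean"  # replicate aggregation for shifts
    maf: float = 0.05
    missingness: float = 0.2
    k: int = 5
    top: int = 10
    min_hosts: int = 6
    p_thresh: float = 1e-5
    n_perm: int = 1000
    per_variant_reml: bool = True
    until: str = "report"  # last stage to run

    def __post_init__(self) -> None:
        if self.until not in STAGES:
            raise ValueError(f"unknown stage {self.until!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed + _SEED_OFFSETS["simulate"], **self.simulation
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the staged pipeline; returns the artifact manifest.

    On a stage failure, partial outputs are kept, a ``<stage>.failed``
    marker is written and the exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    last = STAGES.index(config.until)
    state: dict = {}
    for stage in STAGES[: last + 1]:
        logger.info("stage %s: starting (seed=%d)", stage, config.seed)
        try:
            globals()[f"_stage_{stage}"](config, out, state)
        except Exception:
            (out / f"{stage}.failed").touch()
            raise
    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    sim = simulate_experiment(config.simulation_config())
    state["sim"] = sim
    io.write_genotypes_vcf(sim.genotypes, out / "genotypes.vcf")
    io.write_counts(sim.inoculum_counts, out / "inoculum_counts.tsv")
    io.write_counts(list(sim.sample_counts.values()), out / "sample_counts.tsv")
    io.write_table(sim.samplesheet, out / "samplesheet.csv")
    io.write_table(sim.traits, out / "traits.csv")
    io.write_table(
        sim.truth.true_fitness.rename_axis("strain_id"), out / "truth_fitness.tsv"
    )
    io.write_table(
        sim.truth.true_inoculum_freqs.rename_axis("strain_id").to_frame(),
        out / "truth_inoculum.tsv",
    )


def _stage_estimate(config: RunConfig, out: Path, state: dict) -> None:
    sim = state["sim"]
    kw = dict(seq_error=config.seq_error)
    state["inoculum_estimates"] = frequency.estimate_many(
        sim.inoculum_counts, sim.genotypes, **kw
    )
    state["sample_estimates"] = frequency.estimate_many(
        sim.sample_counts.values(), sim.genotypes, **kw
    )
    rows = []
    for est in state["inoculum_estimates"] + state["sample_estimates"]:
        for strain, f in est.freqs.items():
            rows.append((est.sample_id, strain, f, est.loglik, est.converged))
    io.write_table(
        pd.DataFrame(
            rows, columns=["sample_id", "strain_id", "frequency", "loglik", "converged"]
        ),
        out / "freqs.tsv",
        index=False,
    )


def _stage_fitness(config: RunConfig, out: Path, state: dict) -> None:
    sim = state["sim"]
    inoc = frequency.summarize_inoculum(state["inoculum_estimates"])
    state["inoculum"] = inoc
    final = pd.concat(
        [e.freqs.rename(e.sample_id) for e in state["sample_estimates"]], axis=1
    )
    table = fit_mod.fitness_table(
        final, inoc.per_strain_median, sim.samplesheet["host_genotype"],
        floor=config.floor,
    )
    shifts = fit_mod.fitness_shift(
        table, sim.config.wildtype, aggregate=config.aggregate
    )
    diversity = pd.Series(
        {e.sample_id: fit_mod.shannon_diversity(e.freqs) for e in state["sample_estimates"]},
        name="shannon_h",
    )
    state["fitness"], state["shifts"], state["diversity"] = table, shifts, diversity
    io.write_table(table.w.rename_axis("strain_id"), out / "fitness.tsv")
    io.write_table(shifts.shifts.rename_axis("strain_id"), out / "shifts.tsv")
    io.write_table(diversity.rename_axis("sample_id").to_frame(), out / "diversity.tsv")
    io.write_table(
        inoc.per_strain_median.rename_axis("strain_id").to_frame(),
        out / "inoculum_freqs.tsv",
    )


def _stage_gwas(config: RunConfig, out: Path, state: dict) -> None:
    sim = state["sim"]
    wt = sim.config.wildtype
    gdir = out / "gwas"
    gdir.mkdir(exist_ok=True)
    kw = dict(
        maf=config.maf, missingness=config.missingness,
        per_variant_reml=config.per_variant_reml,
    )
    shift_results = lmm.run_gwas(
        state["shifts"].shifts, sim.genotypes, mode="shift", **kw
    )
    # wild-type relative fitness GWAS for the trade-off comparison
    wt_cols = sim.samplesheet.index[sim.samplesheet["host_genotype"] == wt]
    wt_fitness = state["fitness"].w[wt_cols].mean(axis=1).to_frame(wt)
    wt_results = lmm.run_gwas(wt_fitness, sim.genotypes, mode="fitness", **kw)
    group_results = [lmm.collapse_to_ld_groups(r) for r in shift_results + wt_results]
    state["gwas_variant"] = shift_results + wt_results
    state["gwas_group"] = group_results
    for res in group_results:
        label = res.response.replace(":", "_")
        io.write_table(
            res.table.assign(members=res.table["members"].str.join(",")),
            gdir / f"{label}_{res.replicon}.tsv",
        )


def _group_by_host(results: list[AssociationResult], mode: str) -> dict:
    out: dict[str, list[AssociationResult]] = {}
    for res in results:
        m, label = res.response.split(":", 1)
        if m == mode:
            out.setdefault(label, []).append(res)
    return out


def _stage_rank(config: RunConfig, out: Path, state: dict) -> None:
    by_host = _group_by_host(state["gwas_group"], "shift")
    wt_results = next(iter(_group_by_host(state["gwas_group"], "fitness").values()))
    candidates = ranking.select_top_k(by_host, k=config.k)
    report = ranking.classify_pervasiveness(
        candidates, by_host, top=config.top, min_hosts=config.min_hosts,
        p_threshold=config.p_thresh,
    )
    report = ranking.detect_sign_tradeoff(report, wt_results)
    state["report"] = report
    tab = report.table.copy()
    for col in ("hosts_top10", "hosts_selected_top5", "filtered_in_hosts"):
        tab[col] = tab[col].map(lambda t: ",".join(t))
    tab["beta_by_host"] = tab["beta_by_host"].map(json.dumps)
    io.write_table(tab, out / "pervasiveness.tsv")


def _stage_rda(config: RunConfig, out: Path, state: dict) -> None:
    sim = state["sim"]
    seed = config.seed + _SEED_OFFSETS["rda"]
    y = state["fitness"].w.T  # samples x strains
    hosts = sim.samplesheet["host_genotype"]
    stages = sim.samplesheet["stage_category"]
    res_g = multivariate.rda_permanova(
        y, hosts, n_perm=config.n_perm, seed=seed, term="host_genotype",
        return_scores=False,
    )
    res_s = multivariate.rda_permanova(
        y, stages, n_perm=config.n_perm, seed=seed + 1, term="stage",
        return_scores=False,
    )
    contrasts = multivariate.pairwise_rda_contrasts(
        y, hosts, sim.config.wildtype, n_perm=config.n_perm, seed=seed + 2
    )
    rows = [res_g, res_s] + list(contrasts.values())
    io.write_table(
        pd.DataFrame(
            [
                {
                    "term": r.term, "r2": r.r2, "adj_r2": r.adj_r2,
                    "pseudo_f": r.pseudo_f, "permutation_p": r.permutation_p,
                }
                for r in rows
            ]
        ).set_index("term"),
        out / "rda.tsv",
    )
    state["rda"] = {"host_genotype": res_g, "stage": res_s, "contrasts": contrasts}

    stage_map = {h: sim.config.stage_of(h) for h in sim.config.hosts}
    comparison = multivariate.fit_trait_models(sim.traits, stage_map)
    io.write_table(comparison.table.rename_axis("trait"), out / "trait_models.tsv")
    pca = multivariate.trait_pca(sim.traits)
    io.write_table(pca["scores"], out / "trait_pca_scores.tsv")
    io.write_table(
        pca["variance_fractions"].rename_axis("axis").to_frame("variance_fraction"),
        out / "trait_pca_variance.tsv",
    )
    io.write_table(genotype_corr := multivariate.genotype_correlations(sim.traits),
                   out / "genotype_correlations.tsv")
    state["trait_models"] = comparison
    state["trait_pca"] = pca


def _stage_report(config: RunConfig, out: Path, state: dict) -> None:
    rep = state["report"].table
    n_perv = int((rep["classification"] == "pervasive").sum())
    n_lim = int((rep["classification"] == "limited").sum())
    n_trade = int(rep["tradeoff"].sum())
    inoc = state["inoculum"]
    lines = [
        "# poolsel run report",
        "",
        f"- seed: {config.seed}",
        f"- strains: {state['sim'].config.n_strains}; hosts: {state['sim'].config.n_hosts} "
        f"(wild type {state['sim'].config.wildtype}); "
        f"variants: {state['sim'].genotypes.n_variants}",
        f"- inoculum: median strain frequency {inoc.median:.4f} "
        f"(5-95%: {inoc.q05:.4f}-{inoc.q95:.4f})",
        f"- candidate variant groups: {len(rep)} "
        f"({n_perv} pervasive, {n_lim} limited, {n_trade} with sign trade-off)",
        f"- RDA host-genotype: R2={state['rda']['host_genotype'].r2:.3f} "
        f"(perm p={state['rda']['host_genotype'].permutation_p:.4g}); "
        f"stage: R2={state['rda']['stage'].r2:.3f} "
        f"(perm p={state['rda']['stage'].permutation_p:.4g})",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
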