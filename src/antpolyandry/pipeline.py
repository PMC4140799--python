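"""End-to-end orchestration: genotypes (or simulation) to report bundle.

The pipeline runs the stages in analysis order — worker filtering,
queen inference, parsimonious patriline assignment, paternity
estimators, skew statistics, population-genetic summaries, and (given a
tree and >= 3 species) the comparative PGLS — writing tidy TSV reports
plus one machine-readable JSON summary that contains every number the
reports do.  All stochastic stages draw their seeds from the master
seed, so a run is fully determined by (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import estimators as est
from . import popgen, skew
from .comparative import PhyloTree, SpeciesRecord, pgls, slope_null_interval, \
    transform_for_regression
from .genotypes import (
    ColonySample,
    ParentSet,
    allele_frequencies,
    read_genotype_table,
    write_frequency_table,
    write_genepop,
)
from .inference import assign_patrilines, filter_workers, infer_queen, \
    non_detection_error
from .simulate import SimulationConfig, simulate_colony_set

log = logging.getLogger("antpolyandry")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    genotype_table: Optional[str] = None
    dialect: str = "csv"
    simulation: Optional[SimulationConfig] = None
    tree_file: Optional[str] = None
    min_loci: int = 3
    max_foreign: int = 2
    estimator: str = "corrected"        # m_e inside the S-index machinery
    weighting: str = "gene_copy"        # allele-frequency weighting of parents
    n_sims_B: int = 1000
    n_sims_S: int = 3000
    n_runs_slope: int = 100
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    colonies: list[dict] = field(default_factory=list)
    species: list[dict] = field(default_factory=list)
    popgen: dict = field(default_factory=dict)
    comparative: dict = field(default_factory=dict)
    summary_path: Optional[str] = None


def _analyze_colony(colony: ColonySample, cfg: RunConfig, freqs, seed: int) -> dict:
    t0 = time.time()
    filtered, excluded = filter_workers(colony, min_loci=cfg.min_loci)
    candidates = infer_queen(filtered, freqs=freqs, max_foreign=cfg.max_foreign)
    top = candidates[0]
    keep = [w for w in range(filtered.n_workers) if w not in top.unexplained]
    sub = ColonySample(
        colony_id=filtered.colony_id, species_id=filtered.species_id,
        location=filtered.location, panel=filtered.panel,
        workers=[filtered.workers[w] for w in keep],
        worker_ids=[filtered.worker_ids[w] for w in keep],
    )
    partition = assign_patrilines(sub, top.genotype, freqs=freqs)
    partition.validate(sub)
    e = est.paternity_estimates(colony.colony_id, partition.counts)
    sk = skew.skew_statistics(
        colony.colony_id, partition.counts, estimator=cfg.estimator,
        n_sims_B=cfg.n_sims_B, n_sims_S=cfg.n_sims_S, seed=seed,
    )
    log.info(
        "colony %s: n=%d k_obs=%d seed=%d elapsed=%.2fs",
        colony.colony_id, e.n, e.k_obs, seed, time.time() - t0,
    )
    return {
        "colony": colony.colony_id,
        "species": colony.species_id,
        "n_excluded_few_loci": len(excluded),
        "n_foreign": top.n_unexplained,
        "queen_support": top.support,
        "partition": partition,
        "parents": ParentSet(
            colony_id=colony.colony_id, panel=colony.panel,
            queen=top.genotype, males=partition.patrilines,
        ),
        "sample": sub,
        "estimates": e,
        "skew": sk,
    }


def _popgen_block(per_colony: list[dict], cfg: RunConfig, seed: int) -> dict:
    parents = [c["parents"] for c in per_colony]
    freqs = allele_frequencies(parents, weighting=cfg.weighting)
    out: dict = {}
    h_o_all = []
    rng = np.random.default_rng(seed)
    for c in per_colony:
        ho = popgen.observed_heterozygosity(
            c["sample"], c["partition"], seed=int(rng.integers(2 ** 31))
        )
        h_o_all.append(ho)
        c["H_O"] = ho.value
    h_s = popgen.expected_heterozygosity(parents, weighting=cfg.weighting)
    # pooled H_O: mean of per-locus means over colonies
    pooled = {}
    for ho in h_o_all:
        for locus, v in ho.per_locus.items():
            pooled.setdefault(locus, []).append(v)
    h_o_per_locus = {l: float(np.mean(v)) for l, v in pooled.items()}
    h_o = popgen.PopGenSummary(
        "H_O", float(np.mean(list(h_o_per_locus.values()))), h_o_per_locus,
        None, None, None, None,
    )
    fis = popgen.inbreeding_coefficient(h_o, h_s)
    out["H_O"] = h_o.value
    out["H_S"] = h_s.value
    out["F_IS"] = {"value": fis.value, "se": fis.se, "t": fis.t,
                   "df": fis.df, "p": fis.p}
    if len(per_colony) >= 2:
        locus_names = [l.name for l in parents[0].panel]
        pops = []
        for p in parents:
            inds = [tuple(tuple(pair) if pair is not None else None
                          for pair in p.queen)]
            inds += [tuple((a,) if a is not None else None for a in m)
                     for m in p.males]
            pops.append(inds)
        try:
            fst = popgen.fst_weir_cockerham(pops, locus_names)
            out["F_ST"] = {"value": fst.value, "se": fst.se, "t": fst.t,
                           "df": fst.df, "p": fst.p}
        except ValueError as exc:
            out["F_ST"] = {"error": str(exc)}
    # relatedness per colony and pooled
    locus_names = [l.name for l in parents[0].panel]
    rel = {}
    for c in per_colony:
        cid = c["colony"]
        pairs = popgen.worker_pairs(c["sample"], max_pairs=2000,
                                    seed=int(rng.integers(2 ** 31)))
        r_ww = popgen.qg_relatedness(pairs, freqs, locus_names, "r_ww")
        r_qm = popgen.qg_relatedness(
            popgen.queen_mate_pairs(c["parents"]), freqs, locus_names, "r_qm")
        r_mm = popgen.qg_relatedness(
            popgen.mate_pairs(c["parents"]), freqs, locus_names, "r_mm")
        rel[cid] = {
            "g_ww": c["estimates"].g_ww,
            "r_ww": {"value": r_ww.value, "se": r_ww.se},
            "r_qm": {"value": r_qm.value, "se": r_qm.se},
            "r_mm": {"value": r_mm.value, "se": r_mm.se},
        }
    out["relatedness"] = rel
    out["non_detection_error"] = {
        c["colony"]: non_detection_error(freqs) for c in per_colony
    }
    return out


def _comparative_block(per_colony: list[dict], cfg: RunConfig, tree: PhyloTree,
                       seed: int) -> dict:
    by_species: dict[str, list[dict]] = {}
    for c in per_colony:
        by_species.setdefault(c["species"], []).append(c)
    records, null_draws = [], {}
    for sp, cols in by_species.items():
        ests = [c["estimates"] for c in cols]
        summ = est.species_means(sp, ests, which_m_e=cfg.estimator)
        s_vals = [c["skew"].S for c in cols if c["skew"].S is not None]
        b_vals = [c["skew"].B for c in cols if c["skew"].B is not None]
        records.append(SpeciesRecord(
            species_id=sp,
            k_obs=summ.k_obs_mean,
            k_est=summ.k_est_mean,
            S=float(np.mean(s_vals)) if s_vals else None,
            B=float(np.mean(b_vals)) if b_vals else None,
        ))
        draws = []
        for c in cols:
            _, _, d = skew.s_null_interval(
                c["estimates"].n, c["estimates"].k_obs,
                estimator=cfg.estimator, n_iters=cfg.n_sims_S, seed=seed + 17,
            )
            draws.append(d)
        null_draws[sp] = np.mean(draws, axis=0)
    if len(records) < 3:
        return {"skipped": f"only {len(records)} species (< 3)"}
    usable = [r for r in records if r.S is not None]
    species = [r.species_id for r in usable]
    y = transform_for_regression([r.S for r in usable], "skew")
    x = [r.k_obs for r in usable]
    fit = pgls(y, x, tree, species=species)
    low, high, slopes = slope_null_interval(
        usable, tree, null_draws, n_runs=cfg.n_runs_slope, seed=seed + 31,
    )
    return {
        "fit_S_on_k_obs": dataclasses.asdict(fit),
        "slope_null_low": low,
        "slope_null_high": high,
        "slope_below_null": bool(fit.slope < low),
        "species": {r.species_id: {"k_obs": r.k_obs, "S": r.S, "B": r.B}
                    for r in records},
    }


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in master.spawn(8)]

    if cfg.genotype_table is not None:
        colonies = read_genotype_table(cfg.genotype_table, dialect=cfg.dialect)
    elif cfg.simulation is not None:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=stage_seeds[0])
        colonies, _, _ = simulate_colony_set(sim_cfg)
    else:
        raise ValueError("config needs a genotype_table or a simulation block")

    per_colony = []
    for i, colony in enumerate(colonies):
        per_colony.append(
            _analyze_colony(colony, cfg, freqs=None,
                            seed=stage_seeds[1] + i)
        )
    # reference frequencies from all deduced parents; rerun relatedness etc.
    parents = [c["parents"] for c in per_colony]
    write_genepop(parents, out_dir / "parents.genepop.txt")
    freqs = allele_frequencies(parents, weighting=cfg.weighting)
    write_frequency_table(freqs, out_dir / "allele_frequencies.tsv")

    pop_block = _popgen_block(per_colony, cfg, seed=stage_seeds[2])

    species_ids = {c["species"] for c in per_colony}
    comp_block = {}
    if cfg.tree_file is not None and len(species_ids) >= 3:
        tree = PhyloTree.from_file(cfg.tree_file)
        comp_block = _comparative_block(per_colony, cfg, tree,
                                        seed=stage_seeds[3])

    colony_rows = []
    for c in per_colony:
        e, sk = c["estimates"], c["skew"]
        colony_rows.append({
            "colony": c["colony"], "species": c["species"],
            "n": e.n, "k_obs": e.k_obs,
            "k_est": est.round_half_up(e.k_est),
            "m_e_uncorrected": e.m_e_uncorrected,
            "m_e_corrected": e.m_e_corrected,
            "g_ww": e.g_ww,
            "H_O": c.get("H_O"),
            "B": sk.B, "B_p_high": sk.p_high, "B_p_low": sk.p_low,
            "S": sk.S, "S_null_low": sk.S_null_low,
            "S_null_high": sk.S_null_high,
            "S_significant": sk.S_significant,
            "n_foreign": c["n_foreign"],
            "n_excluded_few_loci": c["n_excluded_few_loci"],
        })
    by_species: dict[str, list] = {}
    for c in per_colony:
        by_species.setdefault(c["species"], []).append(c["estimates"])
    species_rows = []
    for sp, ests in by_species.items():
        s = est.species_means(sp, ests, which_m_e=cfg.estimator)
        species_rows.append(dataclasses.asdict(s))

    _write_tsv(out_dir / "colonies.tsv", colony_rows)
    _write_tsv(out_dir / "species.tsv", species_rows)
    summary = {
        "config": cfg.to_dict(),
        "colonies": colony_rows,
        "species": species_rows,
        "popgen": pop_block,
        "comparative": comp_block,
    }
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return PipelineResult(
        colonies=colony_rows, species=species_rows, popgen=pop_block,
        comparative=comp_block, summary_path=str(summary_path),
    )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(path, rows: list[dict]) -> None:
    if not rows:
        return
    keys = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join("" if row.get(k) is None else str(row.get(k))
                               for k in keys) + "\n")
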