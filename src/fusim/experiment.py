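"""Orchestration of the full simulation study.

Three products, mirroring the study's result tables:

* :func:`run_pod_grid` — diversity (Hd, Hd variance across loci) of every
  simulated dataset in the scenario x composition grid, including the four
  extra replicate rows of the 40-allele/50-locus composition (52 datasets
  in the canonical grid).
* :func:`run_distinguishability` — for each grid cell, the proportion of
  the true fusion scenario's 90% CI unique against each non-fusion model,
  per statistic (long table; the heat-map grid of the study).
* :func:`run_hyptest_tables` — replicate datasets per fusion scenario
  tested against size constancy: observed across-locus means with
  significance flags, and counts of falsely inferred decline.

Everything derives its randomness from one root seed through spawned
child streams, so any single cell can be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coalsim import simulate_pod
from .demography import (
    DatasetComposition,
    FusionScenario,
    SingleDemeModel,
    canonical_compositions,
    canonical_fusion_scenarios,
    canonical_nonfusion_models,
)
from .hky import MutationModel
from .hyptest import test_pod
from .nulldist import central_90_CI, estimate_distributions
from .sumstats import STATISTICS, profile
from .distinguish import unique_proportion

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "grid_compositions", "run_pod_grid",
           "run_distinguishability", "run_hyptest_tables"]


def grid_compositions(extra_pod8_replicates: int = 4) -> list[DatasetComposition]:
    """The 13 grid rows: the nine canonical compositions plus replicate
    rows b..e of the 40-allele / 400 bp / 50-locus composition."""
    comps = canonical_compositions()
    pod8 = comps[7]
    for i in range(extra_pod8_replicates):
        comps.append(
            DatasetComposition(
                n_alleles=pod8.n_alleles,
                locus_length=pod8.locus_length,
                n_loci=pod8.n_loci,
                name=f"POD-8{'bcdefgh'[i]}",
            )
        )
    # keep table order: POD-1..8, replicates, POD-9
    return comps[:8] + comps[9:] + [comps[8]]


@dataclass
class ExperimentConfig:
    scenarios: list[FusionScenario] = field(default_factory=canonical_fusion_scenarios)
    compositions: list[DatasetComposition] = field(default_factory=grid_compositions)
    nonfusion_models: list[SingleDemeModel] = field(
        default_factory=canonical_nonfusion_models
    )
    mutation_model: MutationModel = field(default_factory=MutationModel)
    n_reps: int = 1000  # null-distribution replicates per model
    n_replicate_pods: int = 5  # datasets per scenario in the testing tables
    seed: int = 0
    statistics: tuple[str, ...] = STATISTICS

    def __post_init__(self) -> None:
        if self.n_reps < 20:
            raise ValueError("n_reps must be >= 20 for stable 90% CIs")

    def root_seq(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed)


def run_pod_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate every (scenario, composition) dataset; report Hd and Hd_var."""
    rows = []
    cells = [(s, c) for s in config.scenarios for c in config.compositions]
    for (scen, comp), child in zip(cells, config.root_seq().spawn(len(cells))):
        pod = simulate_pod(scen, comp, config.mutation_model, child)
        prof = profile(pod, statistics=())
        logger.info("pod_grid %s %s Hd=%.3f", scen.name, comp.name,
                    prof.across_loci["Hd"])
        rows.append(
            {
                "scenario": scen.name,
                "dl_ratio": scen.dl_ratio,
                "composition": comp.name,
                "n_alleles": comp.n_alleles,
                "locus_length": comp.locus_length,
                "n_loci": comp.n_loci,
                "Hd": prof.across_loci["Hd"],
                "Hd_var": prof.Hd_var,
            }
        )
    return pd.DataFrame(rows)


def run_distinguishability(config: ExperimentConfig) -> pd.DataFrame:
    """Unique-proportion long table over scenarios x compositions x models."""
    rows = []
    cells = [(s, c) for s in config.scenarios for c in config.compositions]
    for (scen, comp), child in zip(cells, config.root_seq().spawn(len(cells))):
        pod_seq, fuse_seq, *model_seqs = child.spawn(2 + len(config.nonfusion_models))
        pod = simulate_pod(scen, comp, config.mutation_model, pod_seq)
        try:
            fuse_dists = estimate_distributions(
                pod, scen, config.n_reps, np.random.default_rng(fuse_seq),
                config.statistics,
            )
        except ValueError as err:
            logger.warning("skipping degenerate cell %s/%s: %s",
                           scen.name, comp.name, err)
            continue
        fuse_cis = {
            s: central_90_CI(d) for s, d in fuse_dists.items() if d.values.size >= 20
        }
        for model, mseq in zip(config.nonfusion_models, model_seqs):
            dists = estimate_distributions(
                pod, model, config.n_reps, np.random.default_rng(mseq),
                config.statistics,
            )
            for s in config.statistics:
                if s not in fuse_cis or dists[s].values.size < 20:
                    rows.append(
                        {"scenario": scen.name, "composition": comp.name,
                         "model": model.name, "statistic": s,
                         "unique_proportion": np.nan, "overlap_case": "undefined"}
                    )
                    continue
                res = unique_proportion(
                    fuse_cis[s], central_90_CI(dists[s]), statistic=s,
                    nonfusion_model=model.name,
                )
                rows.append(
                    {"scenario": scen.name, "composition": comp.name,
                     "model": model.name, "statistic": s,
                     "unique_proportion": res.unique_proportion,
                     "overlap_case": res.overlap_case}
                )
        logger.info("distinguishability cell %s/%s done", scen.name, comp.name)
    return pd.DataFrame(rows)


def run_hyptest_tables(
    config: ExperimentConfig, comp: DatasetComposition | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate testing tables: (decline counts, per-replicate values).

    By default replicates use the 40-allele / 400 bp / 50-locus composition,
    the one analysed repeatedly in the study.
    """
    comp = comp or canonical_compositions()[7]
    value_rows = []
    counts: dict[tuple[str, str], int] = {}
    for scen, child in zip(config.scenarios, config.root_seq().spawn(len(config.scenarios))):
        for rep, rep_seq in enumerate(child.spawn(config.n_replicate_pods), start=1):
            pod_seq, null_seq = rep_seq.spawn(2)
            pod = simulate_pod(scen, comp, config.mutation_model, pod_seq)
            results = test_pod(
                pod, config.n_reps, np.random.default_rng(null_seq),
                config.statistics,
            )
            for s, res in results.items():
                flag = ""
                if res.inference == "decline":
                    flag = "*" if s in ("D", "F_star", "F_S", "Y_star") else "L"
                    counts[(scen.name, s)] = counts.get((scen.name, s), 0) + 1
                elif res.inference == "growth":
                    flag = "-" if s in ("D", "F_star", "F_S", "Y_star") else "S"
                value_rows.append(
                    {"scenario": scen.name, "replicate": rep, "statistic": s,
                     "observed": res.observed, "p_lower": res.p_lower,
                     "p_upper": res.p_upper, "alpha": res.alpha,
                     "inference": res.inference, "flag": flag}
                )
            logger.info("hyptest %s replicate %d done", scen.name, rep)
    count_rows = [
        {"statistic": s,
         **{scen.name: counts.get((scen.name, s), 0) for scen in config.scenarios}}
        for s in config.statistics
    ]
    return pd.DataFrame(count_rows), pd.DataFrame(value_rows)
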