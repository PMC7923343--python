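"""End-to-end experiment orchestration on synthetic data.

``run_breed_proportion_experiment`` mirrors the accuracy sweeps of the
panel-design study: simulate reference breeds and crossbreds, estimate a
full-marker baseline, then score every (criterion x panel size) cell by the
r-squared of its total-dairy estimates against the baseline (and against
the simulation truth, which synthetic data makes available).

``run_parentage_experiment`` mirrors the parentage sweeps: simulate
families with genotyping error, select MAF panels (pruned and unpruned),
and report sv, Pa and Pe per (panel x size x scenario).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ancestry import (
    AncestryEstimate,
    ReferencePanelFreqs,
    accuracy_r2,
    estimate_admixture_supervised,
)
from .freqs import AlleleFrequencyTable, population_allele_frequencies
from .io import GenotypeMatrix, concat_samples
from .panels import (
    BREED_PROPORTION_SCHEDULE,
    PARENTAGE_SCHEDULE,
    SnpPanel,
    select_panel_maf,
    select_panel_split,
    select_panel_weighted,
)
from .parentage import (
    candidate_pairs,
    opposing_homozygote_counts,
    power_statistics,
    reconstruct_pairs,
    separation_value,
)
from .simulate import (
    AFT,
    BI,
    EUT,
    SimulationConfig,
    add_genotyping_errors,
    realized_divergence,
    simulate_ancestral_frequencies,
    simulate_crossbreds,
    simulate_families,
    simulate_genotypes_from_freqs,
)

logger = logging.getLogger("admixpanel")

DEFAULT_CRITERIA: tuple[dict, ...] = tuple(
    {"mode": "weighted_pool", "w": w} for w in (0.3, 0.5, 0.7)
)


@dataclass
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    criteria: tuple[dict, ...] = DEFAULT_CRITERIA
    panel_sizes: tuple[int, ...] = (100, 200, 300, 400, 500)
    n_replicates: int = 10
    threshold_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("criteria grid must be non-empty")
        sizes = tuple(int(s) for s in self.panel_sizes)
        if any(s <= 0 for s in sizes) or list(sizes) != sorted(set(sizes)):
            raise ValueError("panel sizes must be positive and strictly increasing")
        self.panel_sizes = sizes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        config = cls(
            simulation=SimulationConfig(**sim) if sim else SimulationConfig(),
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.items()
            },
        )
        return config


def _replicate_config(base: SimulationConfig, replicate: int) -> SimulationConfig:
    cfg = SimulationConfig(**{**base.__dict__, "seed": base.seed + replicate})
    return cfg


def simulate_reference_and_crossbreds(
    cfg: SimulationConfig,
) -> tuple[AlleleFrequencyTable, GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Simulate the three reference breeds and a crossbred cohort.

    Returns (true ancestral frequencies, stacked reference genotypes,
    crossbred genotypes, true crossbred ancestry vectors).
    """
    anc = simulate_ancestral_frequencies(cfg)
    refs = concat_samples(
        simulate_genotypes_from_freqs(
            anc, pop, cfg.n_reference, seed=cfg.seed * 1000 + i,
            missing_rate=cfg.missing_rate,
        )
        for i, pop in enumerate((EUT, AFT, BI))
    )
    crossbreds, truth = simulate_crossbreds(
        anc, cfg.admixture_law, cfg.n_crossbred, seed=cfg.seed * 1000 + 7,
        missing_rate=cfg.missing_rate,
    )
    div = realized_divergence(anc)
    logger.info(
        "replicate seed=%d realized divergence %s",
        cfg.seed,
        {f"{a}-{b}": round(v, 3) for (a, b), v in div.items()},
    )
    return anc, refs, crossbreds, truth.q_true


def _select(criterion: dict, ref_freqs: AlleleFrequencyTable,
            sizes: Sequence[int]) -> SnpPanel:
    mode = criterion["mode"]
    if mode == "weighted_pool":
        return select_panel_weighted(
            ref_freqs, w=criterion["w"], sizes=sizes,
            schedule=criterion.get("schedule", BREED_PROPORTION_SCHEDULE),
        )
    if mode == "split_fraction":
        return select_panel_split(
            ref_freqs, f=criterion["f"], sizes=sizes,
            schedule=criterion.get("schedule", BREED_PROPORTION_SCHEDULE),
        )
    if mode == "maf":
        return select_panel_maf(
            ref_freqs, target_population=criterion["target"], sizes=sizes,
            pruned=criterion.get("pruned", True),
        )
    raise ValueError(f"unknown criterion mode {mode!r}")


def _criterion_label(criterion: dict) -> str:
    mode = criterion["mode"]
    if mode == "weighted_pool":
        return f"weighted_w{criterion['w']:.1f}"
    if mode == "split_fraction":
        return f"split_f{criterion['f']:.1f}"
    if mode == "maf":
        tag = "pruned" if criterion.get("pruned", True) else "unpruned"
        return f"maf_{criterion['target']}_{tag}"
    return mode


def run_breed_proportion_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Accuracy table: one row per (replicate, criterion, panel size)."""
    rows = []
    for rep in range(config.n_replicates):
        cfg = _replicate_config(config.simulation, rep)
        _, refs_g, crossbreds, q_true = simulate_reference_and_crossbreds(cfg)
        ref_freqs = population_allele_frequencies(refs_g)
        refs = ReferencePanelFreqs.from_table(
            ref_freqs, populations=[EUT, AFT, BI], dairy_populations=[EUT]
        )
        baseline = estimate_admixture_supervised(crossbreds, refs)
        truth_dairy = q_true[EUT].reindex(baseline.total_dairy.index)
        r2_baseline_truth = accuracy_r2(baseline.total_dairy, truth_dairy)
        rows.append(
            {
                "replicate": rep,
                "criterion": "full_markers",
                "size": crossbreds.n_snps,
                "r2_vs_baseline": 1.0,
                "r2_vs_truth": r2_baseline_truth,
            }
        )
        for criterion in config.criteria:
            panel = _select(criterion, ref_freqs, config.panel_sizes)
            label = _criterion_label(criterion)
            for size in config.panel_sizes:
                ids = panel.ids(size)
                est = estimate_admixture_supervised(
                    crossbreds.subset(snp_ids=ids), refs.subset(ids)
                )
                rows.append(
                    {
                        "replicate": rep,
                        "criterion": label,
                        "size": size,
                        "r2_vs_baseline": accuracy_r2(
                            est.total_dairy, baseline.total_dairy
                        ),
                        "r2_vs_truth": accuracy_r2(est.total_dairy, truth_dairy),
                    }
                )
    return pd.DataFrame(rows)


def best_panel_difference_table(accuracy: pd.DataFrame) -> pd.DataFrame:
    """Per panel size: mean r2 of each criterion and its deficit relative to
    the best criterion at that size (panel-difference summary)."""
    panel_rows = accuracy[accuracy["criterion"] != "full_markers"]
    mean = (
        panel_rows.groupby(["criterion", "size"])["r2_vs_baseline"]
        .mean()
        .reset_index()
    )
    best = mean.groupby("size")["r2_vs_baseline"].transform("max")
    mean["diff_from_best"] = mean["r2_vs_baseline"] - best
    return mean


def simulate_parentage_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Crossbred pool plus families, with genotyping error applied.

    Returns (all genotypes, pedigree truth).  The pool supplies both the
    parents and the unrelated animals of the search space.
    """
    anc = simulate_ancestral_frequencies(cfg)
    pool, _ = simulate_crossbreds(
        anc, cfg.admixture_law, cfg.n_crossbred, seed=cfg.seed * 1000 + 11
    )
    # offspring draw their second parent from the crossbred mean frequencies
    pool_freqs = population_allele_frequencies(pool)
    offspring, truth = simulate_families(
        pool, pool_freqs, population="crossbred",
        n_pairs=cfg.n_families, seed=cfg.seed * 1000 + 13,
    )
    together = concat_samples([pool, offspring])
    noisy = add_genotyping_errors(together, cfg.error_rate, seed=cfg.seed * 1000 + 17)
    return noisy, truth.pedigree


def run_parentage_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """sv/Pa/Pe table per (replicate, panel, size, scenario)."""
    rows = []
    sizes = config.panel_sizes
    for rep in range(config.n_replicates):
        cfg = _replicate_config(config.simulation, rep)
        g, pedigree = simulate_parentage_dataset(cfg)
        crossbred_ids = [
            s for s in g.sample_ids if not s.startswith("prog_")
        ]
        maf_freqs = population_allele_frequencies(
            g.subset(sample_ids=crossbred_ids)
        )
        panels = {
            "maf_pruned": select_panel_maf(
                maf_freqs, "crossbred", sizes=sizes, pruned=True
            ),
            "maf_unpruned": select_panel_maf(
                maf_freqs, "crossbred", sizes=sizes, pruned=False
            ),
        }
        parent_ids = pedigree["parent_id"].tolist()
        progeny_ids = pedigree["offspring_id"].tolist()
        scenarios = {
            1: candidate_pairs(g.samples, scenario=1),
            2: candidate_pairs(
                g.samples, scenario=2,
                parent_ids=parent_ids, progeny_ids=progeny_ids,
            ),
        }
        evaluations = [("full", None, g.n_snps)] + [
            (name, panel.ids(size), size)
            for name, panel in panels.items()
            for size in sizes
        ]
        for scenario, pairs in scenarios.items():
            for name, ids, size in evaluations:
                counts = opposing_homozygote_counts(g, snp_ids=ids, pairs=pairs)
                sv = separation_value(counts, pedigree)
                assigned = reconstruct_pairs(
                    counts, config.threshold_fraction, n_markers=size
                )
                pa, pe = power_statistics(assigned, pedigree, len(pedigree))
                rows.append(
                    {
                        "replicate": rep,
                        "panel": name,
                        "size": size,
                        "scenario": scenario,
                        "sv": sv,
                        "pa": pa,
                        "pe": pe,
                        "n_assigned": len(assigned),
                    }
                )
    return pd.DataFrame(rows)
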