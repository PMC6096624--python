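"""End-to-end convenience wiring of the analysis stages.

Connects the simulator (or externally supplied inputs) through genotyping,
imputation, phenotype adjustment and clustering into a
:class:`poolgs.validation.ForwardDataset` ready for forward validation.
Mirrors the study design: imputation and the two-stage phenotype adjustment
are performed once on the full data set, while marker filtering, prior
elicitation, model fitting and group re-clustering happen inside forward
validation on each year's reference population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from poolgs import genotyping, imputation, phenotypes, relationship, simulate, validation


@dataclass
class PipelineData:
    """Imputed genotypes plus per-trait forward-validation datasets."""

    afm: genotyping.AlleleFrequencyMatrix
    datasets: dict  # trait -> validation.ForwardDataset
    assignment: relationship.GroupAssignment
    sim: simulate.SimulationResult | None = None


def genotype_and_impute(
    rcm: genotyping.ReadCountMatrix,
    min_locus_depth: int = genotyping.DEFAULT_MIN_LOCUS_DEPTH,
    min_call_depth: int = genotyping.DEFAULT_MIN_CALL_DEPTH,
    params: imputation.ImputationParams | None = None,
    seed: int = 0,
) -> genotyping.AlleleFrequencyMatrix:
    """Depth filters -> allele frequencies -> LD-kNN imputation."""
    keep = genotyping.filter_low_depth_loci(rcm, min_depth=min_locus_depth)
    rcm = rcm.subset_loci(keep)
    afm = genotyping.compute_allele_frequencies(rcm, min_call_depth=min_call_depth)
    return imputation.impute_ldknni(afm, params=params, seed=seed)


def prepare_from_simulation(
    sim: simulate.SimulationResult,
    traits: tuple = ("biomass", "heading"),
    params: imputation.ImputationParams | None = None,
    fixed_k: int | None = None,
) -> PipelineData:
    """Run genotyping, imputation, adjustment and global clustering."""
    afm = genotype_and_impute(sim.read_counts, params=params, seed=sim.config.seed)
    grm = relationship.compute_grm(afm)
    assignment = relationship.cluster_groups(grm, fixed_k=fixed_k)
    datasets = {}
    for trait in traits:
        adj = phenotypes.adjust_phenotypes(sim.phenotypes, sim.reference_chain, trait=trait)
        h2 = adj.heritability[["trial_id", "sowing_year", "season", "h2"]]
        datasets[trait] = validation.ForwardDataset(
            afm=afm,
            metadata=sim.metadata,
            adjusted=adj.values,
            trial_h2=h2,
            global_assignment=assignment,
        )
    return PipelineData(afm=afm, datasets=datasets, assignment=assignment, sim=sim)
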