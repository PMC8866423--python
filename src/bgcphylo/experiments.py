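"""End-to-end simulation experiments exercising the full analysis chain.

Each function runs one seeded replicate of a study-scale experiment:

* :func:`mantel_coherence_replicate` — the BGC-phylogeny coherence analysis:
  evolve repertoires, build the BGC network, cluster into families, compute
  genome-level Bray-Curtis distances and Mantel-test them against patristic
  distances.
* :func:`pooled_antagonism_replicate` — inhibition zones under the unique-BGC
  rule regressed on phylogenetic distance, pooled over all strain pairs.
* :func:`mediation_replicate` — the two-level analysis: per-antagonist
  association strength regressed on the antagonist's BGC count.  Repertoire
  sizes are varied by lineage loss (large ancestral repertoire, loss-dominated
  turnover) and per-cluster potencies kept small relative to replicate noise,
  so strains retaining few clusters have noise-dominated assays — the regime
  in which repertoire size is expected to mediate association strength.
* :func:`knockout_attribution_replicate` — a noiseless knockout panel for the
  most cluster-rich strain, attributed back to per-cluster potency shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .antagonism_attribution import AttributionResult, PresenceCall, attribution_table
from .association_stats import (
    LMResult,
    MantelResult,
    distance_lm,
    mantel_test,
    meta_regression,
    per_strain_association,
)
from .bgc_similarity import build_network
from .gcf_clustering import assign_families_and_clans
from .genome_profiles import build_abundance_matrix, genome_bgc_distance
from .phylo import patristic_distances
from .records import DistanceMatrix
from .synthetic_data import (
    RepertoireSimulation,
    SimParams,
    evolve_repertoires,
    simulate_inhibition,
    simulate_knockouts,
    simulate_tree,
)

__all__ = [
    "mantel_coherence_replicate",
    "pooled_antagonism_replicate",
    "mediation_replicate",
    "knockout_attribution_replicate",
    "MEDIATION_PARAMS",
]

#: Conditions of the repertoire-size mediation experiment (see module docs).
MEDIATION_PARAMS = dict(
    n_taxa=30,
    root_n_clusters=26,
    gain_rate=0.5,
    loss_rate=0.4,
    potency_mu=0.0,
    potency_sigma=0.8,
    noise_sd=2.5,
)


def _simulate(seed: int, **overrides) -> tuple[RepertoireSimulation, SimParams]:
    params = SimParams(seed=seed, **overrides)
    tree = simulate_tree(params.n_taxa, params.birth_rate, seed=seed)
    return evolve_repertoires(tree, params), params


def mantel_coherence_replicate(
    seed: int, hgt_rate: float = 0.0, n_taxa: int = 60, n_perm: int = 999
) -> MantelResult:
    """Mantel r/p between genome BGC distance and patristic distance."""
    sim, params = _simulate(seed, n_taxa=n_taxa, hgt_rate=hgt_rate)
    net = build_network(sim.records)
    asn = assign_families_and_clans(net)
    mat = build_abundance_matrix(asn, sim.records, genomes=sim.tree.leaf_labels)
    bgc_d = genome_bgc_distance(mat)
    phylo_d = patristic_distances(sim.tree.to_newick())
    return mantel_test(bgc_d, phylo_d, n_perm=n_perm, seed=seed)


def pooled_antagonism_replicate(
    seed: int, n_taxa: int = 30, noise_sd: float = 0.5
) -> LMResult:
    """Pooled LM of mean inhibition zone on phylogenetic distance."""
    sim, params = _simulate(seed, n_taxa=n_taxa, noise_sd=noise_sd)
    inhibition = simulate_inhibition(
        sim.records, sim.lineage_of, sim.potencies,
        noise_sd=noise_sd, n_replicates=params.n_replicates, seed=seed + 1000,
    )
    phylo_d = patristic_distances(sim.tree.to_newick())
    means = inhibition.mean_zones()
    pairs = [
        (phylo_d[a, t], z) for a, t, z in means.itertuples(index=False) if a != t
    ]
    x, y = map(np.asarray, zip(*pairs))
    return distance_lm(x, y)


def _lineage_jaccard_distance(sim: RepertoireSimulation) -> DistanceMatrix:
    """Genome distance as Jaccard on true cluster-lineage sets."""
    genomes = sim.tree.leaf_labels
    sets: dict[str, set] = {g: set() for g in genomes}
    for r in sim.records:
        sets[r.genome_id].add(sim.lineage_of[r.bgc_id])
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[genomes[i]], sets[genomes[j]]
            d[i, j] = d[j, i] = 1 - len(a & b) / len(a | b) if a | b else 0.0
    return DistanceMatrix(tuple(genomes), d, metric="lineage-jaccard")


def mediation_replicate(seed: int) -> LMResult:
    """Meta-regression of per-strain zone~phylogeny association on BGC count."""
    sim, params = _simulate(seed, **MEDIATION_PARAMS)
    inhibition = simulate_inhibition(
        sim.records, sim.lineage_of, sim.potencies,
        noise_sd=params.noise_sd, n_replicates=params.n_replicates,
        seed=seed + 1000,
    )
    phylo_d = patristic_distances(sim.tree.to_newick())
    bgc_d = _lineage_jaccard_distance(sim)
    summary = per_strain_association(
        inhibition, phylo_d, bgc_d, sim.bgc_counts()
    )
    return meta_regression(summary, response="phylo_assoc")


@dataclass
class KnockoutGroundTruth:
    result: AttributionResult
    antagonist: str
    lineage_sets: dict[str, set]
    potencies: dict[str, float]


def knockout_attribution_replicate(seed: int, n_taxa: int = 8) -> KnockoutGroundTruth:
    """Noiseless knockout panel plus the ground truth needed to check it."""
    sim, params = _simulate(seed, n_taxa=n_taxa)
    counts = sim.bgc_counts()
    antagonist = max(sorted(counts), key=lambda g: counts[g])
    targets = [g for g in sim.tree.leaf_labels if g != antagonist]
    table, mutant_map = simulate_knockouts(
        antagonist, sim.records, sim.lineage_of, sim.potencies, targets,
        noise_sd=0.0, n_replicates=3, seed=seed + 2000,
    )
    sets: dict[str, set] = {g: set() for g in sim.tree.leaf_labels}
    for r in sim.records:
        sets[r.genome_id].add(sim.lineage_of[r.bgc_id])
    calls = {
        (s, lin): PresenceCall(s, lin, lin in sets[s], "genome")
        for s in sim.tree.leaf_labels
        for lin in sorted(sim.potencies)
    }
    result = attribution_table(table, antagonist, mutant_map, presence_calls=calls)
    return KnockoutGroundTruth(result, antagonist, sets, sim.potencies)
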