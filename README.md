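# bgcphylo

Analysis pipeline linking biosynthetic gene cluster (BGC) repertoires,
phylogeny, and interference competition in bacteria, built around the
*Bacillus* setting: closely related strains carry similar arsenals of
secondary-metabolite gene clusters, and antagonism between strains is driven
by the clusters one strain has and the other lacks (carrying a cluster
implies self-resistance to its product).

## Who this is for

Microbial genomicists and ecologists who want to (a) compare BGC repertoires
across genomes, (b) test whether repertoire similarity tracks phylogeny, and
(c) attribute inhibition-assay phenotypes to specific clusters — plus a
ground-truth simulator to validate each step at desk scale.

## The chain

1. **Pairwise BGC distance** ``d(a,b) = 1 − (w_J·JI + w_A·AI + w_D·DSS)``
   where JI is the Jaccard index on domain-type sets, AI the Jaccard index on
   adjacent domain-type pairs (synteny), and DSS the domain sequence
   similarity under an optimal one-to-one assignment of instances per shared
   type, with unmatched instances penalised.  Default weights
   (0.2, 0.05, 0.75).
2. **Gene cluster families / clans**: connected components of the network at
   distance cutoffs 0.3 (GCF) and 0.7 (GCC); families always refine clans.
3. **Genome profiles**: a genome × GCF abundance matrix, genome-level BGC
   distance (Bray–Curtis by default) and a UPGMA dendrogram of genomes.
4. **Association statistics**: OLS with adjusted R² and a one-sided F test on
   unfolded distance pairs; Mantel permutation tests on the matrices
   themselves; Duncan's multiple range test with letter displays; and a
   two-level analysis regressing each antagonist's zone~phylogeny association
   (signed adjusted R²) on its BGC count.
5. **Knockout attribution**: contribution of a cluster to inhibiting a target
   is ``100·(mean wt − mean mutant)/mean wt``; presence in a target is called
   from its genome, or from species prevalence (strictly > 80%) when no
   genome is available; a consistency report flags shared clusters that
   nevertheless appear to contribute.
6. **Simulator**: Yule trees; repertoires evolved by per-cluster loss,
   de-novo gain, horizontal transfer from contemporaneous lineages, and
   per-site domain-sequence mutation; inhibition zones equal to the summed
   potency of clusters present in the antagonist and absent in the target,
   with truncated Gaussian replicate noise; knockout panels with an
   *sfp*-like all-null mutant.

## Worked example

```sh
bgcphylo pipeline --n-taxa 12 --seed 4 --out-dir demo
```

writes the simulated inputs (`tree.nwk`, `bgc_table.jsonl`,
`inhibition.tsv`), every intermediate (`network.tsv`, `gcf_assignment.tsv`,
`abundance.tsv`, `genome_distance.tsv`, `dendrogram.nwk`), the knockout panel
(`knockouts.tsv`, `contribution.tsv`, `consistency.tsv`) and prints:

```
Mantel (BGC distance ~ phylogenetic distance): r = 0.8912, p = 0.001 (999 permutations, seed 4)
LM zone ~ phylogenetic distance: slope = 2.4321, adj R2 = 0.4913, F = 127.5 on 1 and 130 DF, p = 4.984e-21
LM zone ~ BGC distance: slope = 29.5836, adj R2 = 0.5676, F = 173 on 1 and 130 DF, p = 1.197e-25
```

Reading: genome-level BGC distance is strongly coupled to patristic distance
(Mantel r = 0.89, the smallest p attainable with 999 permutations), and mean
inhibition zones grow by ≈2.4 mm per unit of phylogenetic distance — the
coherence and antagonism gradients the pipeline is designed to measure.  The
same stages are available individually (`simulate`, `similarity`, `cluster`,
`profile`, `associate`, `attribute`), and as library functions:

```python
from bgcphylo import (SimParams, simulate_tree, evolve_repertoires,
                      build_network, assign_families_and_clans)

tree = simulate_tree(n_taxa=20, seed=0)
sim = evolve_repertoires(tree, SimParams(n_taxa=20, seed=0))
families = assign_families_and_clans(build_network(sim.records))
```

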