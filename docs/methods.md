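# Methods

## BGC distance

A cluster is summarised as an ordered list of domain instances, each a
(domain type, pseudo-sequence) pair.  For clusters *a, b*:

* **JI** = |types(a) ∩ types(b)| / |types(a) ∪ types(b)|.
* **AI** = the same ratio over *unordered adjacent type pairs* taken from each
  cluster's domain order.  When both clusters are single-domain there are no
  pairs and AI is defined as 0.  This convention means two identical
  single-domain clusters score distance w_A·(1 − 0) = 0.05 rather than 0;
  identity at distance 0 holds for all clusters with at least two domains.
* **DSS**: for each type shared by both clusters, instances are matched
  one-to-one by the Hungarian algorithm maximising summed sequence
  similarity, where similarity = 1 − Levenshtein/max-length (computed with
  edlib).  DSS = Σ matched similarity / (matched + unmatched instance count),
  unmatched counting instances of unshared types and surplus instances of
  shared types on either side.

Combined distance = 1 − (w_J·JI + w_A·AI + w_D·DSS) with default weights
(0.2, 0.05, 0.75) — the published BiG-SCAPE "mix" weights; class-specific
weights and anchor-domain boosting are deliberately out of scope, as is HMM
domain calling (pseudo-sequences stand in for domain alignments).  The
network build deduplicates identical domain contents and caches
sequence-pair similarities; both optimisations are exact.

## Families and clans

Gene cluster families (GCFs) and clans (GCCs) are connected components of
the pair graph at distance cutoffs 0.3 and 0.7.  Components are used instead
of exemplar-based (affinity-propagation) clustering: they are deterministic,
parameter-free and preserve the cutoff semantics; BGCs with no neighbour at
the cutoff form singleton families.  Component labels are the
lexicographically smallest member id, so assignments are reproducible.
Because the 0.3-edge set is a subset of the 0.7-edge set, the family
partition refines the clan partition by construction.

## Genome profiles

The genome × GCF count matrix feeds three interchangeable genome distances:
Bray–Curtis on counts (default — bounded and abundance-aware), Jaccard on
presence/absence, and 1 − Pearson row correlation (range [0, 2]; a constant
row has undefined correlation and is assigned the maximum 2 with a warning).
The genome dendrogram is average-linkage (UPGMA) agglomeration written by
hand so that equal-distance merge candidates break toward the
lexicographically smallest label pair; on tie-free inputs it reproduces
scipy's average-linkage cophenetic matrix (tested).

## Phylogenetic distances

Patristic distances are path-length sums on a provided newick tree
(dendropy).  When only an aligned 16S FASTA is available, uncorrected
p-distances with *pairwise* gap deletion are used; pairwise (not complete)
deletion keeps short toy alignments usable.  Strains without genomes map to
the reference with the highest 16S similarity, ties broken to the
lexicographically smallest reference id and logged.

## Association statistics

`distance_lm` is ordinary least squares on unfolded pairs with
adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2) and the upper-tail F test on
(1, n − 2) df.  Constant predictors *or responses* raise a degenerate-design
error.  Because unfolded distance pairs are not independent, a Mantel
permutation test (joint row/column permutation of one matrix, one-sided for
positive association, add-one p = (1 + #{r* ≥ r})/(n_perm + 1)) accompanies
every distance–distance regression; phylogenetic regression beyond Mantel
(e.g. PGLS) is out of scope.

Duncan's multiple range test uses the pooled one-way-ANOVA MSE, harmonic
mean group size for unequal n, and critical ranges
q(1 − (1 − α)^(p−1); p, df)·√(MSE/n_h) from the studentized range
distribution.  Letters are assigned to maximal non-significant runs of the
descending-mean ranking; at two groups the procedure reduces exactly to the
pooled-variance t test (tested).  With MSE = 0, any mean difference is
declared significant.

The two-level analysis summarises each antagonist by the *signed* adjusted
R² (adjusted R² × sign(slope)) of its mean-zone~distance regression —
chosen because association strength plotted against BGC count must
distinguish positive from inverted associations, and because negative
adjusted R² values occur naturally in weak fits.  Replicates are averaged
per (antagonist, target) before regression; antagonists with fewer than
three usable targets are skipped with a warning.

## Knockout attribution

Contribution of a knocked-out cluster against a target =
100·(mean wt − mean mutant)/mean wt, computed on replicate means.  Negative
contributions (mutant inhibits more) are retained, not clipped — they are
informative about interactions.  Targets the wild-type does not inhibit are
reported as uncallable and excluded.  The "Sum" column adds all single-BGC
contributions; the all-null (sfp-like) mutant's relative reduction is
reported separately and excluded from Sum.  Presence calls from a genome
always override species-prevalence calls; prevalence calls are positive only
when strictly greater than 0.80.  The consistency report flags any cell
where a cluster the target itself carries shows |contribution| above a noise
threshold (default: twice the pooled replicate SD as a percentage of the
wild-type mean).

## Simulator

**Tree.** Pure-birth (Yule) process, root split at time zero, one extra
exponential waiting time after the n-th lineage appears so every pendant
branch is positive; trees are exactly ultrametric.

**Repertoires.** The root carries `root_n_clusters` clusters, each 2–5
domain instances with types from a 30-type pool and random length-40
pseudo-sequences over the 20 amino-acid alphabet.  Evolution is a
chronological sweep between split times; within each epoch, events across
all live branches are applied in time order:

* loss — per-cluster exponential at `loss_rate`; clusters gained or received
  mid-epoch are immediately at risk for the remainder of the epoch;
* gain — Poisson at `gain_rate`, fresh lineage id, fresh log-normal potency;
* horizontal transfer — each lineage receives transfers at
  `hgt_rate` × (its cluster count at epoch start); the donor lineage is
  uniform among the other live lineages and its *contemporaneous* cluster
  state is copied.  Using the epoch-start count for the receipt rate (and
  epoch-end mutation for mid-epoch copies) is a second-order approximation;
  epochs on Yule trees are short.

Sequences mutate per site with probability 1 − exp(−`mutation_rate`·Δt),
pro-rated for clusters created mid-epoch.  The event log records every
gain/loss/transfer with branch and time; per leaf, root clusters − losses +
gains + transfers on the root-to-leaf path equals the emitted repertoire
size (tested).

**Inhibition.** Expected zone(A→T) = Σ potency over lineages present in A
and absent in T; replicates add Gaussian(0, `noise_sd`) truncated at 0, so
means are compared only where expected zones are well above the truncation
point.  Knockout panels contain the wild type, one mutant per antagonist
lineage, and an all-null mutant with every potency-bearing lineage silenced.

**Default study conditions.** 60 taxa, birth rate 1; gain 2.5 and loss 0.25
per unit branch length (equilibrium ≈10 clusters per genome, loss × tree
height ≈ 1 on a 60-taxon Yule tree — the simulated genomes average ≈11 BGCs,
matching the scale of real *Bacillus* genomes); no HGT unless enabled;
mutation 0.02 per site (within-lineage distance stays under the 0.3 family
cutoff across the tree); log-normal potencies (μ=1, σ=0.8 on the log scale,
in mm) so a few clusters dominate zones; noise 1 mm; three replicates.

**Mediation experiment** (`bgcphylo.experiments.MEDIATION_PARAMS`): 30 taxa,
26 root clusters, gain 0.5 / loss 0.4 (loss-dominated, so repertoire sizes
vary ≈2–20 through differential retention of *ancestral* clusters), small
potencies (μ=0) and 2.5 mm noise.  Under these conditions strains retaining
few clusters have noise-dominated assays while cluster-rich strains show a
clear zone~phylogeny gradient — the regime in which BGC count mediates
association strength.  Count variation through de-novo gains does *not*
produce mediation: gained lineages are unique against every target and only
shift zones by a constant.

**What the simulator does not emulate.** Real domain architectures and HMM
scores, selection on clusters, within-species population structure,
nutrient competition in assays, regulation (a carried cluster is always
"expressed").  Passing tests therefore validate the statistical machinery
and the unique-BGC logic, not the biology of any particular dataset.

## Problem sizes

The test suite runs the coherence experiment at 60 taxa × 20 replicates per
HGT level (levels 0, 0.5× and 2× the loss rate), the antagonism and
mediation experiments at 30 taxa × 20 seeds, the metric and clustering
oracles at 200 pairs / 50 networks, and calibration at 500 (LM) and 200
(Mantel, 999 permutations) null replicates.  These sizes keep every
experiment well-powered while the whole suite completes in minutes.
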