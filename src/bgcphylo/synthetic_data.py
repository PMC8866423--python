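"""Ground-truth simulator: phylogenies, evolving BGC repertoires, inhibition.

The generator produces the three linked inputs the pipeline consumes:

1. a pure-birth (Yule) ultrametric phylogeny;
2. BGC repertoires evolved along it — the root carries a set of ancestral
   clusters which are lost (per-cluster exponential), gained de novo
   (Poisson), transferred horizontally from contemporaneous lineages, and
   whose domain pseudo-sequences accumulate per-site substitutions;
3. inhibition-zone assays under the unique-BGC rule: the expected zone of
   antagonist A against target T is the summed potency of the cluster
   lineages present in A and absent in T (presence implies self-resistance),
   plus replicate-level Gaussian noise truncated at zero.

Potencies are log-normal so a few clusters dominate inhibition, mirroring
assays where single polyketides drive clade-specific antagonism.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import BGCRecord, InhibitionTable, ValidationError

__all__ = [
    "SimParams",
    "TreeNode",
    "Phylogeny",
    "RepertoireSimulation",
    "simulate_tree",
    "evolve_repertoires",
    "simulate_inhibition",
    "simulate_knockouts",
    "ALL_LINEAGES",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PRODUCT_CLASSES = ("NRPS", "PKSother", "RiPP", "terpene", "other")
_N_DOMAIN_TYPES = 30
ALL_LINEAGES = "__all__"  # marker for the sfp-like all-null knockout


@dataclass
class SimParams:
    """Study conditions for the simulator.

    Defaults emulate a *Bacillus*-like setting: ~10 clusters per genome at
    gain/loss equilibrium (gain_rate / loss_rate = 10), loss_rate scaled so
    that loss x tree height is ~1 on a 60-taxon Yule tree, slow domain
    sequence divergence so within-lineage BGC distance stays under the 0.3
    family cutoff, log-normal potencies in mm and ~1 mm replicate noise with
    three biological replicates.
    """

    n_taxa: int = 60
    birth_rate: float = 1.0
    root_n_clusters: int = 10
    gain_rate: float = 2.5
    loss_rate: float = 0.25
    hgt_rate: float = 0.0
    mutation_rate: float = 0.02
    domain_len: int = 40
    potency_mu: float = 1.0
    potency_sigma: float = 0.8
    noise_sd: float = 1.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.birth_rate, self.gain_rate, self.loss_rate,
            self.hgt_rate, self.mutation_rate, self.potency_sigma,
            self.noise_sd,
        )
        if any(r < 0 for r in rates):
            raise ValidationError("all rates must be nonnegative")
        if self.birth_rate <= 0:
            raise ValidationError("birth_rate must be positive")
        if self.n_taxa < 3:
            raise ValidationError("n_taxa must be >= 3")
        if self.domain_len < 4:
            raise ValidationError("domain_len must be >= 4")
        if self.root_n_clusters < 1:
            raise ValidationError("root_n_clusters must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class TreeNode:
    node_id: int
    time: float  # birth time (depth from the root)
    end: float = math.nan  # split time, or tree height for leaves
    parent: "TreeNode | None" = None
    children: list = field(default_factory=list)
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        return self.end - self.time


class Phylogeny:
    """Rooted ultrametric tree with labeled leaves."""

    def __init__(self, root: TreeNode, height: float):
        self.root = root
        self.height = height
        self.nodes: dict[int, TreeNode] = {}
        stack = [root]
        while stack:
            n = stack.pop()
            self.nodes[n.node_id] = n
            stack.extend(n.children)
        self.leaves = sorted(
            (n for n in self.nodes.values() if n.is_leaf), key=lambda n: n.label
        )

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def path_to_root(self, leaf_label: str) -> list[int]:
        """Node ids of the branches from a leaf up to (excluding) the root."""
        (leaf,) = [n for n in self.leaves if n.label == leaf_label]
        path = []
        n: TreeNode | None = leaf
        while n is not None and n.parent is not None:
            path.append(n.node_id)
            n = n.parent
        return path

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.label}:{n.branch_length:.17g}"
            inner = ",".join(fmt(c) for c in n.children)
            if n.parent is None:
                return f"({inner})"
            return f"({inner}):{n.branch_length:.17g}"

        return fmt(self.root) + ";"


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with ``n_taxa`` leaves.

    The root splits at time zero; thereafter each lineage splits at rate
    ``birth_rate``.  After the last split the tree is extended by one more
    exponential waiting time so every pendant branch has positive length.
    """
    if n_taxa < 3:
        raise ValidationError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = TreeNode(node_id=0, time=0.0, end=0.0)
    next_id = 1
    active: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(node_id=next_id, time=0.0, parent=root)
        next_id += 1
        root.children.append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.end = t
        for _ in range(2):
            child = TreeNode(node_id=next_id, time=t, parent=node)
            next_id += 1
            node.children.append(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_taxa))
    width = max(3, len(str(n_taxa)))
    # label leaves in preorder for a stable, readable numbering
    counter = 0

    def label_preorder(n: TreeNode) -> None:
        nonlocal counter
        if n.is_leaf:
            counter += 1
            n.label = f"G{counter:0{width}d}"
            n.end = t
        else:
            for c in n.children:
                label_preorder(c)

    label_preorder(root)
    return Phylogeny(root, height=t)


@dataclass
class _Cluster:
    lineage: str
    product_class: str
    domains: list[tuple[str, str]]
    created: float


@dataclass
class RepertoireSimulation:
    """Everything evolve_repertoires knows about the ground truth."""

    records: list[BGCRecord]
    lineage_of: dict[str, str]  # bgc_id -> ancestral-cluster lineage id
    potencies: dict[str, float]  # lineage id -> inhibition-zone potency (mm)
    events: pd.DataFrame  # columns: event, time, branch, lineage, donor
    tree: Phylogeny

    def records_by_genome(self) -> dict[str, list[BGCRecord]]:
        out: dict[str, list[BGCRecord]] = {g: [] for g in self.tree.leaf_labels}
        for r in self.records:
            out[r.genome_id].append(r)
        return out

    def bgc_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in self.tree.leaf_labels}
        for r in self.records:
            counts[r.genome_id] += 1
        return counts


def _random_cluster(
    rng: np.random.Generator, lineage: str, domain_len: int, created: float
) -> _Cluster:
    n_dom = int(rng.integers(2, 6))
    types = [f"D{int(i):02d}" for i in rng.integers(0, _N_DOMAIN_TYPES, size=n_dom)]
    domains = [
        (
            t,
            "".join(_AA[i] for i in rng.integers(0, len(_AA), size=domain_len)),
        )
        for t in types
    ]
    pc = _PRODUCT_CLASSES[int(rng.integers(len(_PRODUCT_CLASSES)))]
    return _Cluster(lineage=lineage, product_class=pc, domains=domains, created=created)


def _mutate(
    rng: np.random.Generator, cluster: _Cluster, rate: float, dt: float
) -> None:
    if rate <= 0 or dt <= 0:
        return
    p = 1.0 - math.exp(-rate * dt)
    new_domains = []
    for dtype, seq in cluster.domains:
        k = int(rng.binomial(len(seq), p))
        if k:
            pos = rng.choice(len(seq), size=k, replace=False)
            chars = list(seq)
            for i in pos:
                old = _AA.index(chars[i])
                chars[i] = _AA[(old + 1 + int(rng.integers(len(_AA) - 1))) % len(_AA)]
            seq = "".join(chars)
        new_domains.append((dtype, seq))
    cluster.domains = new_domains


def evolve_repertoires(tree: Phylogeny, params: SimParams) -> RepertoireSimulation:
    """Evolve BGC repertoires along the tree by gain, loss, HGT and mutation.

    The simulation sweeps the tree chronologically between split times; within
    each epoch, loss / gain / transfer events across all live branches are
    applied in time order, so a horizontal transfer copies the donor lineage's
    *contemporaneous* cluster state.  Each lineage receives transfers at rate
    ``hgt_rate`` per cluster it carries per unit branch length; the donor
    lineage is chosen uniformly among the other live lineages.
    """
    rng = np.random.default_rng(params.seed)
    potencies: dict[str, float] = {}
    lineage_counter = 0

    def new_lineage() -> str:
        nonlocal lineage_counter
        lineage_counter += 1
        lid = f"L{lineage_counter:04d}"
        potencies[lid] = float(rng.lognormal(params.potency_mu, params.potency_sigma))
        return lid

    root_state = [
        _random_cluster(rng, new_lineage(), params.domain_len, 0.0)
        for _ in range(params.root_n_clusters)
    ]

    def copy_cluster(c: _Cluster, created: float) -> _Cluster:
        return _Cluster(c.lineage, c.product_class, list(c.domains), created)

    states: dict[int, list[_Cluster]] = {
        child.node_id: [copy_cluster(c, 0.0) for c in root_state]
        for child in tree.root.children
    }
    log_rows: list[tuple] = []

    split_times = sorted({n.end for n in tree.nodes.values() if not n.is_leaf if n.parent is not None})
    boundaries = [0.0] + [s for s in split_times if s > 0.0] + [tree.height]

    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        dt = t1 - t0
        branch_ids = sorted(states)
        heap: list[tuple] = []
        seq = 0

        def push(time: float, kind: str, branch: int, payload) -> None:
            nonlocal seq
            heapq.heappush(heap, (time, seq, kind, branch, payload))
            seq += 1

        for b in branch_ids:
            state = states[b]
            if params.loss_rate > 0:
                for c in state:
                    tl = t0 + rng.exponential(1.0 / params.loss_rate)
                    if tl < t1:
                        push(tl, "loss", b, c)
            n_gain = int(rng.poisson(params.gain_rate * dt))
            for tg in sorted(rng.uniform(t0, t1, size=n_gain)):
                push(float(tg), "gain", b, None)
            if params.hgt_rate > 0 and state:
                n_hgt = int(rng.poisson(params.hgt_rate * len(state) * dt))
                for th in sorted(rng.uniform(t0, t1, size=n_hgt)):
                    push(float(th), "hgt", b, None)

        while heap:
            time, _, kind, b, payload = heapq.heappop(heap)
            state = states[b]
            if kind == "loss":
                if payload in state:
                    state.remove(payload)
                    log_rows.append(("loss", time, b, payload.lineage, ""))
            elif kind == "gain":
                c = _random_cluster(rng, new_lineage(), params.domain_len, time)
                state.append(c)
                log_rows.append(("gain", time, b, c.lineage, ""))
                if params.loss_rate > 0:
                    tl = time + rng.exponential(1.0 / params.loss_rate)
                    if tl < t1:
                        push(tl, "loss", b, c)
            else:  # hgt receipt
                donors = [d for d in branch_ids if d != b]
                if not donors:
                    continue
                donor = donors[int(rng.integers(len(donors)))]
                donor_state = states[donor]
                if not donor_state:
                    continue
                src = donor_state[int(rng.integers(len(donor_state)))]
                c = copy_cluster(src, time)
                state.append(c)
                log_rows.append(("transfer", time, b, c.lineage, str(donor)))
                if params.loss_rate > 0:
                    tl = time + rng.exponential(1.0 / params.loss_rate)
                    if tl < t1:
                        push(tl, "loss", b, c)

        for b in branch_ids:
            for c in states[b]:
                _mutate(rng, c, params.mutation_rate, t1 - max(t0, c.created))

        # branches splitting at t1 hand copies of their state to both children
        for b in branch_ids:
            node = tree.nodes[b]
            if not node.is_leaf and node.end == t1:
                for child in node.children:
                    states[child.node_id] = [copy_cluster(c, t1) for c in states[b]]
                del states[b]

    records: list[BGCRecord] = []
    lineage_of: dict[str, str] = {}
    for leaf in tree.leaves:
        state = states.get(leaf.node_id, [])
        for i, c in enumerate(state, start=1):
            bgc_id = f"{leaf.label}_B{i:03d}"
            records.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=leaf.label,
                    species_id=leaf.label,
                    product_class=c.product_class,
                    domains=tuple(c.domains),
                )
            )
            lineage_of[bgc_id] = c.lineage

    events = pd.DataFrame(
        log_rows, columns=["event", "time", "branch", "lineage", "donor"]
    )
    return RepertoireSimulation(
        records=records,
        lineage_of=lineage_of,
        potencies=potencies,
        events=events,
        tree=tree,
    )


def _lineage_sets(
    records: Iterable[BGCRecord], lineage_of: Mapping[str, str]
) -> dict[str, frozenset[str]]:
    per_genome: dict[str, set[str]] = {}
    for r in records:
        if r.bgc_id not in lineage_of:
            raise ValidationError(f"BGC {r.bgc_id!r} has no lineage mapping")
        per_genome.setdefault(r.genome_id, set()).add(lineage_of[r.bgc_id])
    return {g: frozenset(s) for g, s in per_genome.items()}


def _expected_zone(
    antagonist: frozenset[str], target: frozenset[str], potencies: Mapping[str, float]
) -> float:
    return sum(potencies[l] for l in antagonist - target)


def simulate_inhibition(
    records: Iterable[BGCRecord],
    lineage_of: Mapping[str, str],
    potencies: Mapping[str, float],
    noise_sd: float = 1.0,
    n_replicates: int = 3,
    seed: int = 0,
    antagonists: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
) -> InhibitionTable:
    """Inhibition zones under the unique-BGC rule.

    Expected zone(A -> T) = sum of potencies of the cluster lineages present
    in A and absent in T; replicates add Gaussian(0, noise_sd) noise,
    truncated at zero.  Self pairs therefore have expected zone 0.
    """
    sets = _lineage_sets(records, lineage_of)
    for g, lins in sets.items():
        missing = [l for l in lins if l not in potencies]
        if missing:
            raise ValidationError(f"genome {g}: lineages without potency: {missing}")
    genomes = sorted(sets)
    ants = list(antagonists) if antagonists is not None else genomes
    tgts = list(targets) if targets is not None else genomes
    rng = np.random.default_rng(seed)
    rows = []
    for a in ants:
        for t in tgts:
            mu = _expected_zone(sets.get(a, frozenset()), sets.get(t, frozenset()), potencies)
            for rep in range(1, n_replicates + 1):
                z = mu if noise_sd == 0 else mu + rng.normal(0.0, noise_sd)
                rows.append((a, t, rep, max(0.0, z)))
    return InhibitionTable(
        pd.DataFrame(rows, columns=["antagonist", "target", "replicate", "zone_mm"])
    )


def simulate_knockouts(
    antagonist_id: str,
    records: Iterable[BGCRecord],
    lineage_of: Mapping[str, str],
    potencies: Mapping[str, float],
    targets: Sequence[str],
    noise_sd: float = 1.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[InhibitionTable, dict[str, str | None]]:
    """Knockout panel: wild-type, one mutant per antagonist lineage, all-null.

    Each mutant's zones are simulated with the knocked-out lineage removed
    from the antagonist's repertoire; the all-null (sfp-like) mutant has every
    potency-bearing lineage silenced.  Returns the replicate table plus a map
    from assay strain name to the knocked lineage (None for wild-type,
    :data:`ALL_LINEAGES` for the all-null mutant).
    """
    recs = list(records)
    sets = _lineage_sets(recs, lineage_of)
    if antagonist_id not in sets:
        raise KeyError(f"antagonist {antagonist_id!r} has no repertoire")
    a_set = sets[antagonist_id]
    rng = np.random.default_rng(seed)
    variants: list[tuple[str, str | None, frozenset[str]]] = [
        (antagonist_id, None, a_set)
    ]
    for lin in sorted(a_set):
        variants.append((f"{antagonist_id}__d_{lin}", lin, a_set - {lin}))
    variants.append((f"{antagonist_id}__d_all", ALL_LINEAGES, frozenset()))

    rows = []
    for name, _, lin_set in variants:
        for t in targets:
            if t not in sets:
                raise KeyError(f"target {t!r} has no repertoire")
            mu = _expected_zone(lin_set, sets[t], potencies)
            for rep in range(1, n_replicates + 1):
                z = mu if noise_sd == 0 else mu + rng.normal(0.0, noise_sd)
                rows.append((name, t, rep, max(0.0, z)))
    table = InhibitionTable(
        pd.DataFrame(rows, columns=["antagonist", "target", "replicate", "zone_mm"])
    )
    mutant_map = {name: knocked for name, knocked, _ in variants}
    return table, mutant_map
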