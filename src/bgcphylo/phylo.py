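"""Phylogenetic distances and the nearest-reference proxy rule.

Patristic distances (path-length sums) are computed from newick trees via
dendropy.  When only an aligned 16S FASTA is available, uncorrected
p-distances with pairwise gap deletion stand in for tree-based distances.
Strains without a sequenced genome are mapped to the reference genome with
the highest 16S similarity (argmax, lexicographic tie-break).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from Bio import SeqIO

from .records import DistanceMatrix, ValidationError

__all__ = [
    "ProxyMap",
    "patristic_distances",
    "p_distance",
    "nearest_reference",
    "read_tree",
]

log = logging.getLogger("bgcphylo")

_AMBIGUOUS = set("-.NRYSWKMBDHVX?")


@dataclass(frozen=True)
class ProxyMap:
    """strain id -> (reference genome id, 16S similarity)."""

    mapping: dict[str, tuple[str, float]]

    def reference_of(self, strain: str) -> str:
        return self.mapping[strain][0]


def read_tree(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree from a path or a literal newick string."""
    text = str(source)
    if not text.strip().startswith("("):
        text = Path(source).read_text()
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"malformed newick: {exc}") from exc


def patristic_distances(tree: dendropy.Tree | str | Path) -> DistanceMatrix:
    """Sum of branch lengths on the path between every pair of leaves."""
    if not isinstance(tree, dendropy.Tree):
        tree = read_tree(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d, metric="patristic")


def p_distance(aligned_fasta: str | Path | Mapping[str, str]) -> DistanceMatrix:
    """Uncorrected p-distance on an aligned FASTA, pairwise gap deletion.

    Sites where either sequence has a gap or ambiguity code are excluded
    from that pair's comparison; a pair with zero comparable sites is an
    error.
    """
    if isinstance(aligned_fasta, Mapping):
        seqs = {k: v.upper() for k, v in aligned_fasta.items()}
    else:
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(aligned_fasta), "fasta")
        }
    if len(seqs) < 2:
        raise ValidationError("p_distance requires >= 2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValidationError(f"sequences are not aligned (lengths {sorted(lengths)})")
    labels = tuple(sorted(seqs))
    arr = np.array([list(seqs[l]) for l in labels])
    valid = ~np.isin(arr, list(_AMBIGUOUS))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(labels, d, metric="p-distance")


def nearest_reference(strain_16s_sims: Mapping[str, Mapping[str, float]]) -> ProxyMap:
    """Map each strain to its highest-16S-similarity reference genome.

    Ties are broken toward the lexicographically smallest reference id and
    logged.
    """
    mapping: dict[str, tuple[str, float]] = {}
    for strain, candidates in strain_16s_sims.items():
        if not candidates:
            raise ValidationError(f"strain {strain!r} has no candidate references")
        best_sim = max(candidates.values())
        winners = sorted(r for r, s in candidates.items() if s == best_sim)
        if len(winners) > 1:
            log.info(
                "16S similarity tie for %s among %s; choosing %s",
                strain, winners, winners[0],
            )
        mapping[strain] = (winners[0], float(best_sim))
    return ProxyMap(mapping)
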