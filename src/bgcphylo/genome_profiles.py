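"""Genome x GCF abundance profiles and genome-level BGC distances.

Each genome is summarised by how many of its BGCs fall in each gene cluster
family; genome-level BGC distance is computed on these abundance rows
(Bray-Curtis by default, Jaccard on presence/absence, or 1 - Pearson).  An
average-linkage (UPGMA) dendrogram over genomes reproduces the heatmap-side
clustering of genomes by repertoire.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .gcf_clustering import GCFAssignment
from .records import BGCRecord, DistanceMatrix, ValidationError

__all__ = [
    "build_abundance_matrix",
    "genome_bgc_distance",
    "average_linkage_dendrogram",
]


def build_abundance_matrix(
    assignment: GCFAssignment,
    records: Iterable[BGCRecord],
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count each genome's BGCs per family.

    Rows are genome ids (sorted, or the provided ``genomes`` order — genomes
    with zero BGCs keep an all-zero row), columns are family ids (sorted).
    """
    recs = list(records)
    for r in recs:
        if r.bgc_id not in assignment.families:
            raise ValidationError(f"BGC {r.bgc_id!r} has no family assignment")
    if genomes is None:
        genomes = sorted({r.genome_id for r in recs})
    families = sorted(set(assignment.families.values()))
    mat = pd.DataFrame(0, index=list(genomes), columns=families, dtype=int)
    for r in recs:
        mat.loc[r.genome_id, assignment.families[r.bgc_id]] += 1
    mat.index.name = "genome_id"
    return mat


def genome_bgc_distance(matrix: pd.DataFrame, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise genome distance on GCF abundance rows.

    ``braycurtis`` on counts (default), ``jaccard`` on presence/absence, or
    ``one_minus_pearson`` (1 - Pearson correlation of rows, range [0, 2]).
    A pair where correlation is undefined (a constant row) gets the maximum
    distance 2 under ``one_minus_pearson``.
    """
    labels = tuple(str(g) for g in matrix.index)
    x = matrix.to_numpy(dtype=float)
    n = len(labels)
    if metric == "braycurtis":
        d = squareform(pdist(x, metric="braycurtis"))
        d = np.nan_to_num(d, nan=0.0)  # two all-zero genomes: identical repertoires
    elif metric == "jaccard":
        d = squareform(pdist(x > 0, metric="jaccard"))
    elif metric == "one_minus_pearson":
        d = np.zeros((n, n))
        sd = x.std(axis=1)
        for i in range(n):
            for j in range(i + 1, n):
                if sd[i] == 0.0 or sd[j] == 0.0:
                    d[i, j] = d[j, i] = 2.0
                else:
                    r = np.corrcoef(x[i], x[j])[0, 1]
                    d[i, j] = d[j, i] = float(np.clip(1.0 - r, 0.0, 2.0))
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, d, metric=metric)


def average_linkage_dendrogram(dist: DistanceMatrix) -> str:
    """UPGMA merge tree over genomes, returned as a newick string.

    Heights are ultrametric (leaf-to-node = merge height / 2).  Ties between
    candidate merges are broken toward the lexicographically smallest label
    pair, so the output is deterministic.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValidationError("dendrogram requires at least 2 genomes")

    # active clusters: key -> (newick, size, height, smallest original label)
    active: dict[int, tuple[str, int, float, str]] = {
        i: (lbl, 1, 0.0, lbl) for i, lbl in enumerate(dist.labels)
    }
    d = {
        (i, j): float(dist.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_key = n
    while len(active) > 1:
        best = None
        for (i, j), v in d.items():
            if i not in active or j not in active:
                continue
            tag = tuple(sorted((active[i][3], active[j][3])))
            cand = (v, tag, i, j)
            if best is None or cand < best:
                best = cand
        assert best is not None
        v, _, i, j = best
        ni, nj = active[i], active[j]
        h = v / 2.0
        first, second = (ni, nj) if ni[3] <= nj[3] else (nj, ni)
        newick = f"({first[0]}:{h - first[2]:.10g},{second[0]}:{h - second[2]:.10g})"
        size = ni[1] + nj[1]
        for k in list(active):
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(next_key, k), max(next_key, k))] = (
                ni[1] * dik + nj[1] * djk
            ) / size
        del active[i], active[j]
        active[next_key] = (newick, size, h, min(ni[3], nj[3]))
        next_key += 1
    (root,) = active.values()
    return root[0] + ";"
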