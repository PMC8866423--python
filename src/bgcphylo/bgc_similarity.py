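"""Pairwise BGC distances: Jaccard, adjacency and domain-sequence similarity.

The distance between two clusters is ``1 - (wJ*JI + wA*AI + wD*DSS)``:

* **JI** — Jaccard index on the sets of domain types.
* **AI** — Jaccard index on the sets of unordered adjacent domain-type pairs,
  capturing synteny of the domain order.
* **DSS** — domain sequence similarity: instances of each shared domain type
  are matched one-to-one by an optimal assignment maximising summed sequence
  similarity (1 - normalised Levenshtein); the summed matched similarity is
  divided by (number of matches + all unmatched instances on both sides), so
  domain content missing from one cluster dilutes the score.

Default weights (0.2, 0.05, 0.75) are the published BiG-SCAPE "mix" weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .records import BGCRecord, ValidationError

__all__ = [
    "PairScore",
    "BGCDistanceNetwork",
    "jaccard_index",
    "adjacency_index",
    "domain_sequence_similarity",
    "sequence_similarity",
    "combined_distance",
    "build_network",
]


@dataclass(frozen=True)
class PairScore:
    """Similarity components and combined distance for one BGC pair."""

    bgc_a: str
    bgc_b: str
    JI: float
    AI: float
    DSS: float
    distance: float


@dataclass
class BGCDistanceNetwork:
    """All-pairs BGC distances as a lexicographically sorted edge list."""

    edges: pd.DataFrame  # columns: bgc_a, bgc_b, JI, AI, DSS, distance
    weights: tuple[float, float, float]

    @property
    def bgc_ids(self) -> list[str]:
        return sorted(set(self.edges["bgc_a"]) | set(self.edges["bgc_b"]))


def jaccard_index(a: BGCRecord, b: BGCRecord) -> float:
    """Jaccard index of the two domain-type sets."""
    ta, tb = a.domain_types, b.domain_types
    union = ta | tb
    if not union:
        return 0.0
    return len(ta & tb) / len(union)


def _adjacent_pairs(record: BGCRecord) -> frozenset[frozenset[str]]:
    types = [t for t, _ in record.domains]
    return frozenset(
        frozenset((types[i], types[i + 1])) for i in range(len(types) - 1)
    )


def adjacency_index(a: BGCRecord, b: BGCRecord) -> float:
    """Jaccard index of unordered adjacent domain-type pairs; 0 if both empty."""
    pa, pb = _adjacent_pairs(a), _adjacent_pairs(b)
    union = pa | pb
    if not union:
        return 0.0  # single-domain clusters carry no synteny information
    return len(pa & pb) / len(union)


def sequence_similarity(s1: str, s2: str) -> float:
    """1 - Levenshtein(s1, s2) / max(len(s1), len(s2))."""
    if s1 == s2:
        return 1.0
    d = edlib.align(s1, s2, task="distance")["editDistance"]
    return 1.0 - d / max(len(s1), len(s2))


def domain_sequence_similarity(
    a: BGCRecord,
    b: BGCRecord,
    _cache: dict[tuple[str, str], float] | None = None,
) -> float:
    """Assignment-based similarity over instances of shared domain types.

    For each domain type present in both clusters, instances are matched
    one-to-one to maximise the summed pairwise sequence similarity (exact via
    the Hungarian algorithm; ties resolved to the lexicographically first
    instance order by scipy's deterministic solver).  Unmatched instances of
    shared types and all instances of unshared types count against the score:

        DSS = sum(matched similarities) / (n_matched + n_unmatched_total)
    """
    by_type_a: dict[str, list[str]] = {}
    by_type_b: dict[str, list[str]] = {}
    for t, s in a.domains:
        by_type_a.setdefault(t, []).append(s)
    for t, s in b.domains:
        by_type_b.setdefault(t, []).append(s)

    shared = set(by_type_a) & set(by_type_b)
    matched_sim = 0.0
    n_matched = 0
    n_unmatched = 0
    for t in by_type_a:
        if t not in shared:
            n_unmatched += len(by_type_a[t])
    for t in by_type_b:
        if t not in shared:
            n_unmatched += len(by_type_b[t])

    for t in shared:
        sa, sb = by_type_a[t], by_type_b[t]
        if len(sa) == 1 and len(sb) == 1:
            sims = None
            if _cache is not None:
                key = (sa[0], sb[0]) if sa[0] <= sb[0] else (sb[0], sa[0])
                sim = _cache.get(key)
                if sim is None:
                    sim = sequence_similarity(sa[0], sb[0])
                    _cache[key] = sim
            else:
                sim = sequence_similarity(sa[0], sb[0])
            matched_sim += sim
            n_matched += 1
            continue
        sims = np.empty((len(sa), len(sb)))
        for i, s1 in enumerate(sa):
            for j, s2 in enumerate(sb):
                if _cache is not None:
                    key = (s1, s2) if s1 <= s2 else (s2, s1)
                    v = _cache.get(key)
                    if v is None:
                        v = sequence_similarity(s1, s2)
                        _cache[key] = v
                else:
                    v = sequence_similarity(s1, s2)
                sims[i, j] = v
        rows, cols = linear_sum_assignment(sims, maximize=True)
        matched_sim += float(sims[rows, cols].sum())
        n_matched += len(rows)
        n_unmatched += (len(sa) - len(rows)) + (len(sb) - len(rows))

    denom = n_matched + n_unmatched
    if denom == 0:
        return 0.0
    return matched_sim / denom


def _check_weights(weights: Sequence[float]) -> tuple[float, float, float]:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x < 0 for x in w) or not math.isclose(sum(w), 1.0, abs_tol=1e-9):
        raise ValidationError(f"weights must be 3 nonnegative values summing to 1: {weights!r}")
    return w  # type: ignore[return-value]


def combined_distance(
    a: BGCRecord,
    b: BGCRecord,
    weights: Sequence[float] = (0.2, 0.05, 0.75),
    _cache: dict[tuple[str, str], float] | None = None,
) -> PairScore:
    """Weighted combined distance ``1 - (wJ*JI + wA*AI + wD*DSS)``."""
    wj, wa, wd = _check_weights(weights)
    ji = jaccard_index(a, b)
    if ji == 0.0:
        # no shared domain types => AI and DSS are 0 by construction
        ai = adjacency_index(a, b)
        dss = 0.0
    else:
        ai = adjacency_index(a, b)
        dss = domain_sequence_similarity(a, b, _cache=_cache)
    dist = 1.0 - (wj * ji + wa * ai + wd * dss)
    # clamp float fuzz only
    dist = min(1.0, max(0.0, dist))
    key_a, key_b = (a.bgc_id, b.bgc_id) if a.bgc_id <= b.bgc_id else (b.bgc_id, a.bgc_id)
    return PairScore(key_a, key_b, ji, ai, dss, dist)


def _canonical_key(r: BGCRecord) -> tuple:
    return r.domains  # full domain content determines every component


def build_network(
    records: Iterable[BGCRecord],
    weights: Sequence[float] = (0.2, 0.05, 0.75),
) -> BGCDistanceNetwork:
    """Score all unordered pairs of records.

    Identical domain contents are deduplicated before scoring (components
    depend only on the ordered domain list), and sequence-pair similarities
    are cached across the build; both are exact optimisations.
    """
    recs = list(records)
    if len(recs) < 2:
        raise ValidationError("build_network requires at least 2 records")
    w = _check_weights(weights)

    groups: dict[tuple, list[BGCRecord]] = {}
    for r in recs:
        groups.setdefault(_canonical_key(r), []).append(r)
    reps = [members[0] for members in groups.values()]
    cache: dict[tuple[str, str], float] = {}

    rows: list[tuple] = []
    for gi in range(len(reps)):
        for gj in range(gi, len(reps)):
            if gi == gj:
                members = groups[_canonical_key(reps[gi])]
                if len(members) < 2:
                    continue
                score = combined_distance(reps[gi], reps[gi], w, _cache=cache)
                ji, ai, dss, dist = score.JI, score.AI, score.DSS, score.distance
                pairs = [
                    (members[x], members[y])
                    for x in range(len(members))
                    for y in range(x + 1, len(members))
                ]
            else:
                score = combined_distance(reps[gi], reps[gj], w, _cache=cache)
                ji, ai, dss, dist = score.JI, score.AI, score.DSS, score.distance
                pairs = [
                    (ra, rb)
                    for ra in groups[_canonical_key(reps[gi])]
                    for rb in groups[_canonical_key(reps[gj])]
                ]
            for ra, rb in pairs:
                ka, kb = (
                    (ra.bgc_id, rb.bgc_id)
                    if ra.bgc_id <= rb.bgc_id
                    else (rb.bgc_id, ra.bgc_id)
                )
                rows.append((ka, kb, ji, ai, dss, dist))

    edges = pd.DataFrame(rows, columns=["bgc_a", "bgc_b", "JI", "AI", "DSS", "distance"])
    edges = edges.sort_values(["bgc_a", "bgc_b"], kind="mergesort").reset_index(drop=True)
    return BGCDistanceNetwork(edges=edges, weights=w)
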