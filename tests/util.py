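"""Shared helpers and independent oracles for the test suite.

Everything here is written independently of the package internals (naive
enumeration, textbook DP) so it can serve as a cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

from bgcphylo.records import BGCRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_record(
    rng: np.random.Generator,
    bgc_id: str,
    genome_id: str = "G1",
    n_types: int = 6,
    max_domains: int = 5,
    max_per_type: int = 4,
    seq_len: tuple[int, int] = (4, 10),
) -> BGCRecord:
    n_dom = int(rng.integers(1, max_domains + 1))
    domains = []
    counts: dict[str, int] = {}
    while len(domains) < n_dom:
        t = f"T{int(rng.integers(n_types))}"
        if counts.get(t, 0) >= max_per_type:
            continue
        counts[t] = counts.get(t, 0) + 1
        length = int(rng.integers(seq_len[0], seq_len[1] + 1))
        seq = "".join(AA[i] for i in rng.integers(0, len(AA), size=length))
        domains.append((t, seq))
    return BGCRecord(
        bgc_id=bgc_id,
        genome_id=genome_id,
        species_id=genome_id,
        product_class="NRPS",
        domains=tuple(domains),
    )


def levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def seq_sim_oracle(a: str, b: str) -> float:
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def ji_oracle(a: BGCRecord, b: BGCRecord) -> float:
    ta = {t for t, _ in a.domains}
    tb = {t for t, _ in b.domains}
    return len(ta & tb) / len(ta | tb) if ta | tb else 0.0


def ai_oracle(a: BGCRecord, b: BGCRecord) -> float:
    def pairs(r):
        ts = [t for t, _ in r.domains]
        return {frozenset(p) for p in zip(ts, ts[1:])}

    pa, pb = pairs(a), pairs(b)
    return len(pa & pb) / len(pa | pb) if pa | pb else 0.0


def dss_oracle(a: BGCRecord, b: BGCRecord) -> float:
    """Exhaustive-permutation optimal assignment per shared domain type."""
    by_a: dict[str, list[str]] = {}
    by_b: dict[str, list[str]] = {}
    for t, s in a.domains:
        by_a.setdefault(t, []).append(s)
    for t, s in b.domains:
        by_b.setdefault(t, []).append(s)
    shared = set(by_a) & set(by_b)
    total_sim, n_matched, n_unmatched = 0.0, 0, 0
    for t in set(by_a) | set(by_b):
        sa = by_a.get(t, [])
        sb = by_b.get(t, [])
        if t not in shared:
            n_unmatched += len(sa) + len(sb)
            continue
        k = min(len(sa), len(sb))
        best = -1.0
        small, large = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
        for combo in itertools.permutations(range(len(large)), k):
            best = max(
                best, sum(seq_sim_oracle(small[i], large[j]) for i, j in enumerate(combo))
            )
        total_sim += best
        n_matched += k
        n_unmatched += (len(sa) - k) + (len(sb) - k)
    denom = n_matched + n_unmatched
    return total_sim / denom if denom else 0.0


def combined_oracle(a: BGCRecord, b: BGCRecord, w=(0.2, 0.05, 0.75)) -> float:
    return 1.0 - (w[0] * ji_oracle(a, b) + w[1] * ai_oracle(a, b) + w[2] * dss_oracle(a, b))


def brute_force_components(ids, edges) -> list[frozenset]:
    """Union-find over an edge list, for clustering cross-checks."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[str, set] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in comps.values()]
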