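"""Gene cluster family (GCF) and clan (GCC) assignment.

Families are the connected components of the BGC graph whose edges are pairs
at combined distance <= 0.3; clans use the looser 0.7 cutoff.  Because the
edge set at 0.3 is a subset of the edge set at 0.7, the family partition
always refines the clan partition.  Component labels are deterministic: each
component is named after its lexicographically smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .bgc_similarity import BGCDistanceNetwork
from .records import ValidationError

__all__ = ["GCFAssignment", "cluster_at_cutoff", "assign_families_and_clans"]


@dataclass
class GCFAssignment:
    """bgc_id -> (family_id, clan_id) with the cutoffs that produced them."""

    families: dict[str, str]
    clans: dict[str, str]
    family_cutoff: float
    clan_cutoff: float

    def to_frame(self, genome_of: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for bgc_id in sorted(self.families):
            rows.append(
                {
                    "bgc_id": bgc_id,
                    "genome_id": (genome_of or {}).get(bgc_id, ""),
                    "family_id": self.families[bgc_id],
                    "clan_id": self.clans[bgc_id],
                }
            )
        return pd.DataFrame(rows, columns=["bgc_id", "genome_id", "family_id", "clan_id"])


def cluster_at_cutoff(
    network: BGCDistanceNetwork, cutoff: float, prefix: str = "GCF_"
) -> dict[str, str]:
    """Partition bgc_ids by connected components at ``distance <= cutoff``.

    Singletons (no edge at or below the cutoff) form their own components.
    Returns a map bgc_id -> component label ``{prefix}{smallest member}``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")
    g = nx.Graph()
    g.add_nodes_from(network.bgc_ids)
    kept = network.edges.loc[network.edges["distance"] <= cutoff]
    g.add_edges_from(zip(kept["bgc_a"], kept["bgc_b"]))
    labels: dict[str, str] = {}
    for comp in nx.connected_components(g):
        name = prefix + min(comp)
        for bgc in comp:
            labels[bgc] = name
    return labels


def assign_families_and_clans(
    network: BGCDistanceNetwork,
    family_cutoff: float = 0.3,
    clan_cutoff: float = 0.7,
) -> GCFAssignment:
    """Assign each BGC a family (tight cutoff) and a clan (loose cutoff)."""
    if family_cutoff > clan_cutoff:
        raise ValidationError(
            f"family_cutoff ({family_cutoff}) must be <= clan_cutoff ({clan_cutoff})"
        )
    families = cluster_at_cutoff(network, family_cutoff, prefix="GCF_")
    clans = cluster_at_cutoff(network, clan_cutoff, prefix="GCC_")
    return GCFAssignment(
        families=families,
        clans=clans,
        family_cutoff=family_cutoff,
        clan_cutoff=clan_cutoff,
    )
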