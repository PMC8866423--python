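"""Attribution of antagonism to specific BGCs from knockout assays.

The contribution of a cluster to the inhibition of a target is the percentage
decrease of the inhibition zone when that cluster is knocked out:

    contribution = 100 * (mean(wt) - mean(mutant)) / mean(wt)

Presence of a cluster family in a target strain is called from its genome
when one is available, otherwise from species prevalence (present only when
strictly more than 80% of the species' reference genomes carry the family).
Under the unique-BGC rule, clusters shared by antagonist and target should
contribute nothing; the consistency report flags violations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import InhibitionTable, ValidationError
from .synthetic_data import ALL_LINEAGES

__all__ = [
    "PresenceCall",
    "AttributionResult",
    "UndefinedContributionError",
    "contribution",
    "presence_call",
    "unique_bgc_set",
    "attribution_table",
]

ALL_NULL_COLUMN = "all_null"


class UndefinedContributionError(ValidationError):
    """Wild-type does not inhibit the target; contribution is undefined."""


@dataclass(frozen=True)
class PresenceCall:
    strain: str
    family: str
    present: bool
    basis: str  # "genome" | "species_prevalence"


@dataclass
class AttributionResult:
    table: pd.DataFrame  # rows: targets; columns: knocked families, all_null, Sum
    consistency: pd.DataFrame  # flagged (target, family, contribution, threshold)
    uncallable: list[str] = field(default_factory=list)


def contribution(wt_zones: Iterable[float], mutant_zones: Iterable[float]) -> float:
    """Percentage decrease of the mean inhibition zone in the mutant."""
    wt = np.asarray(list(wt_zones), dtype=float)
    mut = np.asarray(list(mutant_zones), dtype=float)
    if len(wt) == 0 or len(mut) == 0:
        raise ValidationError("need >= 1 replicate for wild-type and mutant")
    if wt.mean() <= 0.0:
        raise UndefinedContributionError(
            "wild-type mean zone is 0: target not inhibited"
        )
    return 100.0 * (wt.mean() - mut.mean()) / wt.mean()


def presence_call(
    strain: str,
    family: str,
    genome_families: Iterable[str] | None = None,
    species_prevalence: float | None = None,
    threshold: float = 0.8,
) -> PresenceCall:
    """Call family presence from the genome, else from species prevalence.

    A genome-based call always overrides prevalence.  Prevalence-based calls
    are positive only when strictly greater than ``threshold``.
    """
    if genome_families is not None:
        return PresenceCall(strain, family, family in set(genome_families), "genome")
    if species_prevalence is not None:
        if not 0.0 <= species_prevalence <= 1.0:
            raise ValidationError(f"prevalence must be in [0, 1]: {species_prevalence}")
        return PresenceCall(
            strain, family, species_prevalence > threshold, "species_prevalence"
        )
    raise ValidationError(
        f"strain {strain!r}, family {family!r}: no genome and no species references"
    )


def unique_bgc_set(
    antagonist: str,
    target: str,
    presence_calls: Mapping[tuple[str, str], PresenceCall],
    families: Iterable[str] | None = None,
) -> set[str]:
    """Families present in the antagonist and absent in the target."""
    if families is None:
        families = sorted({f for (s, f) in presence_calls if s == antagonist})
    out = set()
    for fam in families:
        try:
            a_call = presence_calls[(antagonist, fam)]
            t_call = presence_calls[(target, fam)]
        except KeyError as exc:
            raise ValidationError(f"uncallable family {fam!r}: missing {exc}") from exc
        if a_call.present and not t_call.present:
            out.add(fam)
    return out


def _pooled_replicate_sd(data: pd.DataFrame, target: str) -> float:
    sub = data.loc[data["target"] == target]
    groups = [g["zone_mm"].to_numpy() for _, g in sub.groupby("antagonist") if len(g) > 1]
    if not groups:
        return 0.0
    num = sum(((g - g.mean()) ** 2).sum() for g in groups)
    den = sum(len(g) - 1 for g in groups)
    return math.sqrt(num / den) if den else 0.0


def attribution_table(
    inhibition: InhibitionTable,
    wildtype: str,
    mutant_map: Mapping[str, str | None],
    presence_calls: Mapping[tuple[str, str], PresenceCall] | None = None,
    family_of_lineage: Mapping[str, str] | None = None,
    noise_threshold: float | None = None,
) -> AttributionResult:
    """Per-(target, knocked BGC) contribution table with a "Sum" column.

    ``mutant_map`` names each assay strain's knocked lineage (None marks the
    wild-type row, :data:`ALL_LINEAGES` the sfp-like all-null mutant, whose
    relative reduction is reported in the ``all_null`` column and excluded
    from "Sum").  Targets the wild-type does not inhibit are listed as
    uncallable and excluded.  When presence calls are supplied, every cell
    where the target carries the knocked family but |contribution| exceeds
    the noise threshold is flagged in the consistency report (default
    threshold: twice the pooled replicate SD as a percentage of the
    wild-type mean).
    """
    data = inhibition.data
    wt_rows = data.loc[data["antagonist"] == wildtype]
    if not len(wt_rows):
        raise ValidationError(f"missing wild-type rows for {wildtype!r}")
    mutants = {
        name: knocked
        for name, knocked in mutant_map.items()
        if knocked is not None
    }
    fam = family_of_lineage or {}

    def column_of(knocked: str) -> str:
        if knocked == ALL_LINEAGES:
            return ALL_NULL_COLUMN
        return fam.get(knocked, knocked)

    columns = sorted(
        {column_of(k) for k in mutants.values() if k != ALL_LINEAGES}
    )
    has_null = any(k == ALL_LINEAGES for k in mutants.values())

    targets = sorted(wt_rows["target"].unique())
    table_rows: dict[str, dict[str, float]] = {}
    uncallable: list[str] = []
    flags: list[dict] = []

    for tgt in targets:
        wt_z = wt_rows.loc[wt_rows["target"] == tgt, "zone_mm"].to_numpy()
        if wt_z.mean() <= 0.0:
            uncallable.append(tgt)
            continue
        row: dict[str, float] = {}
        for name, knocked in sorted(mutants.items()):
            mz = data.loc[
                (data["antagonist"] == name) & (data["target"] == tgt), "zone_mm"
            ].to_numpy()
            if len(mz) == 0:
                raise ValidationError(f"missing mutant rows: {name!r} vs {tgt!r}")
            col = column_of(knocked)
            row[col] = contribution(wt_z, mz)
        row["Sum"] = sum(v for c, v in row.items() if c not in (ALL_NULL_COLUMN, "Sum"))
        table_rows[tgt] = row

        if presence_calls is not None:
            if noise_threshold is None:
                sd = _pooled_replicate_sd(data, tgt)
                thr = 200.0 * sd / wt_z.mean()
            else:
                thr = noise_threshold
            for name, knocked in sorted(mutants.items()):
                if knocked == ALL_LINEAGES:
                    continue
                col = column_of(knocked)
                call = presence_calls.get((tgt, col))
                if call is not None and call.present and abs(row[col]) > thr:
                    flags.append(
                        {
                            "target": tgt,
                            "family": col,
                            "contribution": row[col],
                            "threshold": thr,
                        }
                    )

    all_cols = columns + ([ALL_NULL_COLUMN] if has_null else []) + ["Sum"]
    table = pd.DataFrame.from_dict(table_rows, orient="index")
    table = table.reindex(columns=all_cols)
    table.index.name = "target"
    consistency = pd.DataFrame(
        flags, columns=["target", "family", "contribution", "threshold"]
    )
    return AttributionResult(table=table, consistency=consistency, uncallable=uncallable)
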