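"""Core domain types shared across the pipeline.

A :class:`BGCRecord` is the unit of analysis: one biosynthetic gene cluster
summarised as an ordered list of protein-domain instances, each instance a
(domain type, pseudo-sequence) pair.  Genome-level containers (abundance and
distance matrices) live in :mod:`bgcphylo.genome_profiles`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BGCRecord",
    "RunConfig",
    "InhibitionTable",
    "DistanceMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violated a documented invariant."""


@dataclass(frozen=True)
class BGCRecord:
    """One biosynthetic gene cluster.

    Parameters
    ----------
    bgc_id, genome_id, species_id:
        Identifier tokens; ``bgc_id`` must be unique within a table.
    product_class:
        Predicted product class token (e.g. ``NRPS``, ``PKSother``, ``RiPP``).
    domains:
        Ordered domain instances as ``(domain_type, sequence)`` tuples.
        Sequences are uppercase A–Z pseudo-sequences.
    """

    bgc_id: str
    genome_id: str
    species_id: str
    product_class: str
    domains: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.bgc_id:
            raise ValidationError("bgc_id must be nonempty")
        if not self.genome_id:
            raise ValidationError(f"{self.bgc_id}: genome_id must be nonempty")
        if len(self.domains) == 0:
            raise ValidationError(f"{self.bgc_id}: domains must be nonempty")
        for dtype, seq in self.domains:
            if not dtype:
                raise ValidationError(f"{self.bgc_id}: empty domain type")
            if not seq or not all("A" <= c <= "Z" for c in seq):
                raise ValidationError(
                    f"{self.bgc_id}: domain sequences must be nonempty uppercase A-Z"
                )
        object.__setattr__(self, "domains", tuple((t, s) for t, s in self.domains))

    @property
    def domain_types(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.domains)


@dataclass
class RunConfig:
    """Resolved pipeline parameters.

    ``weights`` mixes the three BGC similarity components (Jaccard, adjacency,
    domain sequence similarity); the defaults are the published BiG-SCAPE
    "mix" weights.  Family/clan cutoffs are the 0.3 / 0.7 distance thresholds
    used to define gene cluster families and clans.
    """

    w_jaccard: float = 0.2
    w_adjacency: float = 0.05
    w_dss: float = 0.75
    family_cutoff: float = 0.3
    clan_cutoff: float = 0.7
    genome_metric: str = "braycurtis"
    presence_threshold: float = 0.8
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.w_jaccard, self.w_adjacency, self.w_dss)
        if any(x < 0 for x in w):
            raise ValidationError("similarity weights must be nonnegative")
        if not math.isclose(sum(w), 1.0, abs_tol=1e-9):
            raise ValidationError(f"similarity weights must sum to 1, got {sum(w)!r}")
        for name in ("family_cutoff", "clan_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.family_cutoff > self.clan_cutoff:
            raise ValidationError("family_cutoff must be <= clan_cutoff")
        if self.genome_metric not in ("braycurtis", "jaccard", "one_minus_pearson"):
            raise ValidationError(f"unknown genome_metric {self.genome_metric!r}")
        if not 0.0 < self.presence_threshold < 1.0:
            raise ValidationError("presence_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_jaccard, self.w_adjacency, self.w_dss)


_INHIBITION_COLUMNS = ["antagonist", "target", "replicate", "zone_mm"]


@dataclass
class InhibitionTable:
    """Replicate-level inhibition-zone diameters (mm).

    Wraps a DataFrame with columns ``antagonist, target, replicate, zone_mm``.
    """

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_INHIBITION_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in _INHIBITION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"inhibition table missing columns: {missing}")
        self.data = self.data[_INHIBITION_COLUMNS].reset_index(drop=True)
        if len(self.data) and (self.data["zone_mm"] < 0).any():
            bad = self.data.loc[self.data["zone_mm"] < 0].index[0]
            raise ValidationError(f"negative zone_mm at row {bad}")

    def __len__(self) -> int:
        return len(self.data)

    def mean_zones(self) -> pd.DataFrame:
        """Mean zone per (antagonist, target) across replicates."""
        if not len(self.data):
            return pd.DataFrame(columns=["antagonist", "target", "zone_mm"])
        return (
            self.data.groupby(["antagonist", "target"], sort=True)["zone_mm"]
            .mean()
            .reset_index()
        )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labeled entities."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels")
        if n and not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix not symmetric")
        if n and not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("diagonal must be zero")
        if n and (self.values < -1e-12).any():
            raise ValidationError("entries must be nonnegative")
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper triangle (row-major), as used by scipy."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            tuple(labels), self.values[np.ix_(idx, idx)], metric=self.metric
        )
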