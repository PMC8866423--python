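"""On-disk formats: BGC tables (JSON Lines), TSV tables/matrices, config.

The BGC table is one canonical JSON object per line with keys ``bgc_id,
genome_id, species_id, product_class, domains`` (domains as ``[type,
sequence]`` pairs); writing then reading reproduces the records exactly.
Matrices are labeled TSV with floats at 10 significant digits.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import (
    BGCRecord,
    DistanceMatrix,
    InhibitionTable,
    RunConfig,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_bgc_table",
    "write_bgc_table",
    "read_inhibition_tsv",
    "write_inhibition_tsv",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_config",
    "write_config",
    "setup_logging",
]

log = logging.getLogger("bgcphylo")

_FLOAT_FMT = "%.10g"
_RECORD_KEYS = ("bgc_id", "genome_id", "species_id", "product_class", "domains")


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


def setup_logging(quiet: bool = False) -> None:
    """Log to stderr; --quiet raises the level to WARNING."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers.clear()
    log.addHandler(handler)
    log.setLevel(logging.WARNING if quiet else logging.INFO)


def record_to_dict(r: BGCRecord) -> dict:
    return {
        "bgc_id": r.bgc_id,
        "genome_id": r.genome_id,
        "species_id": r.species_id,
        "product_class": r.product_class,
        "domains": [[t, s] for t, s in r.domains],
    }


def read_bgc_table(path: str | Path) -> list[BGCRecord]:
    """Read a JSON-Lines BGC table, validating all record invariants."""
    records: list[BGCRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"record {i}: invalid JSON ({exc})") from exc
            missing = [k for k in _RECORD_KEYS if k not in obj]
            if missing:
                raise ParseError(f"record {i}: missing keys {missing}")
            try:
                rec = BGCRecord(
                    bgc_id=obj["bgc_id"],
                    genome_id=obj["genome_id"],
                    species_id=obj["species_id"],
                    product_class=obj["product_class"],
                    domains=tuple((t, s) for t, s in obj["domains"]),
                )
            except (ValidationError, TypeError, ValueError) as exc:
                raise ParseError(f"record {i}: {exc}") from exc
            if rec.bgc_id in seen:
                raise ValidationError(f"record {i}: duplicate bgc_id {rec.bgc_id!r}")
            seen.add(rec.bgc_id)
            records.append(rec)
    return records


def write_bgc_table(records: Iterable[BGCRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(record_to_dict(r), sort_keys=True, separators=(",", ":")))
            fh.write("\n")


def read_inhibition_tsv(path: str | Path) -> InhibitionTable:
    """Read replicate-level inhibition zones; an empty file is an empty table."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return InhibitionTable()
    return InhibitionTable(df)


def write_inhibition_tsv(table: InhibitionTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column labels differ")
    return DistanceMatrix(tuple(str(l) for l in df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dist.values, index=list(dist.labels), columns=list(dist.labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_labeled_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


_CONFIG_FIELDS = {
    "w_jaccard": float,
    "w_adjacency": float,
    "w_dss": float,
    "family_cutoff": float,
    "clan_cutoff": float,
    "genome_metric": str,
    "presence_threshold": float,
    "n_permutations": int,
    "seed": int,
}


def read_config(path: str | Path) -> RunConfig:
    """Read a plain-text ``key = value`` config into a validated RunConfig."""
    kwargs: dict = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"config line {i}: expected key = value, got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_FIELDS:
            raise ParseError(f"config line {i}: unknown key {key!r}")
        kwargs[key] = _CONFIG_FIELDS[key](value.strip())
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = [f"{k} = {getattr(config, k)}" for k in _CONFIG_FIELDS]
    Path(path).write_text("\n".join(lines) + "\n")
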