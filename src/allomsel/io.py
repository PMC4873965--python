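"""Delimited-text readers and writers plus configuration loading.

All tables are plain CSV (TSV auto-detected on read).  Numbers are written
with fixed precision — 2 decimals for mm — so write-then-read is the
identity up to rendering precision.  Users converting spreadsheet exports
with different headers can supply a ``column_map`` instead of renaming
columns by hand.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .records import REQUIRED_COLUMNS, validate_morph_table
from .selection import SelectionRound
from .simulate import SimConfig

log = logging.getLogger(__name__)

MORPH_COLUMN_ORDER = list(REQUIRED_COLUMNS) + ["selected", "sired", "n_offspring"]


def read_morph_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a morph table (CSV or TSV, sniffed).

    ``column_map`` maps file column names to schema names, e.g.
    ``{"SL": "sl_mm", "Gono": "gono_mm"}``.  Unknown columns are kept as
    opaque metadata.  Row numbers in error messages refer to data rows
    (0-based, header excluded).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except Exception as e:
        raise SchemaError(f"{path}: cannot parse as delimited text: {e}") from e
    if column_map:
        df = df.rename(columns=column_map)
    return validate_morph_table(df, source=str(path))


def write_morph_table(records: pd.DataFrame, path) -> None:
    """Write a morph table with deterministic row/column order.

    Rows sort by (replicate, line, generation, fish_id); mm columns render
    with 2 decimals.  An empty collection writes a header-only file.
    """
    path = Path(path)
    df = records.copy()
    for col in MORPH_COLUMN_ORDER:
        if col not in df.columns:
            if col in ("selected", "sired", "n_offspring"):
                continue
            raise SchemaError(f"cannot write table without column {col!r}")
    cols = [c for c in MORPH_COLUMN_ORDER if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    if len(df):
        df = df.sort_values(["replicate", "line", "generation", "fish_id"],
                            kind="stable")
        for col in ("sl_mm", "gono_mm"):
            df[col] = df[col].astype(float).round(2)
    df[cols].to_csv(path, index=False)


def write_rounds(rounds, path) -> None:
    """Serialize the selection audit trail, one row per round.

    Id sets are ';'-joined; offspring counts render as ``id:count``
    pairs.  Measured ids are not stored — they are recoverable as all
    males of that (replicate, line, generation) in the morph table.
    """
    rows = []
    for r in rounds:
        rows.append({
            "replicate": r.replicate, "line": r.line,
            "generation": r.generation, "direction": r.direction,
            "n_measured": len(r.measured_ids),
            "selected_ids": ";".join(map(str, r.selected_ids)),
            "sire_ids": ";".join(map(str, r.sire_ids)),
            "offspring_counts": ";".join(
                f"{k}:{v}" for k, v in r.offspring_counts.items()),
            "S": r.S, "S_eff": r.S_eff,
        })
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_rounds(path, morph: pd.DataFrame) -> list[SelectionRound]:
    """Rebuild SelectionRound objects from an audit table + morph table."""
    df = pd.read_csv(Path(path))
    males = morph[morph["sex"] == "male"]
    rounds = []
    for row in df.itertuples(index=False):
        cohort = males[(males["replicate"] == row.replicate)
                       & (males["line"] == row.line)
                       & (males["generation"] == row.generation)]
        counts = {}
        if isinstance(row.offspring_counts, str) and row.offspring_counts:
            for pair in row.offspring_counts.split(";"):
                k, v = pair.rsplit(":", 1)
                counts[k] = int(v)
        rounds.append(SelectionRound(
            replicate=row.replicate, line=row.line,
            generation=int(row.generation), direction=row.direction,
            measured_ids=cohort["fish_id"].to_numpy(),
            selected_ids=np.array(str(row.selected_ids).split(";"), dtype=object),
            sire_ids=np.array(str(row.sire_ids).split(";"), dtype=object),
            offspring_counts=counts,
            S=float(row.S), S_eff=float(row.S_eff),
        ))
    return rounds


def load_config(path, seed: int | None = None) -> SimConfig:
    """Load a simulator configuration from YAML (JSON accepted).

    Unknown keys raise; ``seed`` overrides the file's value.  All
    effective values are logged for provenance.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "replicates" in data:
        data["replicates"] = tuple(data["replicates"])
    if seed is not None:
        data["seed"] = int(seed)
    cfg = SimConfig(**data)
    log.info("simulator config: %s", json.dumps(dataclasses.asdict(cfg)))
    return cfg
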