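"""Morphology-table schema and validation.

The package's working currency is a pandas DataFrame with one row per
measured fish ("morph table"):

======================  =======================================================
column                  meaning
======================  =======================================================
``replicate``           experimental replicate label (``A``/``B``/``C``)
``line``                selection regime: ``up``, ``down`` or ``control``
``generation``          integer generation, 1-based
``fish_id``             opaque unique identifier
``sex``                 ``male`` or ``female``
``sl_mm``               standard length, mm (snout to caudal-fin base)
``gono_mm``             gonopodium length, mm (males; NaN for females)
======================  =======================================================

Optional columns ``selected`` (0/1), ``sired`` (0/1) and ``n_offspring``
are passed through untouched, as are any unknown columns.

Across poeciliids the gonopodium spans roughly 18-53% of body length, so a
relative length outside 10-60% is almost certainly a measurement or data
entry problem; such rows are *flagged* with a logged warning, not rejected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "replicate",
    "line",
    "generation",
    "fish_id",
    "sex",
    "sl_mm",
    "gono_mm",
)
OPTIONAL_COLUMNS = ("selected", "sired", "n_offspring")

LINES = ("up", "down", "control")
SEXES = ("male", "female")

#: plausible range of gonopodium length as a fraction of standard length
RELATIVE_LENGTH_FLAG_RANGE = (0.10, 0.60)

GENERATION_RANGE = (1, 10)


def validate_morph_table(df: pd.DataFrame, *, source: str = "<table>") -> pd.DataFrame:
    """Validate and normalize a morph table.

    Line and sex labels are normalized to lower case; numeric columns are
    coerced; hard violations raise :class:`~allomsel.errors.SchemaError`
    with row numbers, soft violations (implausible relative length,
    generation outside 1-10) are logged as warnings.

    Returns a normalized copy.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {', '.join(missing)}")

    out = df.copy()
    out["replicate"] = out["replicate"].astype(str).str.strip()
    out["line"] = out["line"].astype(str).str.strip().str.lower()
    out["sex"] = out["sex"].astype(str).str.strip().str.lower()
    out["fish_id"] = out["fish_id"].astype(str)

    bad_line = ~out["line"].isin(LINES)
    if bad_line.any():
        rows = list(out.index[bad_line][:5])
        raise SchemaError(
            f"{source}: unrecognized line label(s) {sorted(out.loc[bad_line, 'line'].unique())} "
            f"(rows {rows}); expected one of {LINES}"
        )
    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError(
            f"{source}: unrecognized sex label(s) "
            f"{sorted(out.loc[bad_sex, 'sex'].unique())}"
        )

    gen = pd.to_numeric(out["generation"], errors="coerce")
    if gen.isna().any():
        rows = list(out.index[gen.isna()][:5])
        raise SchemaError(f"{source}: unparseable generation at row(s) {rows}")
    out["generation"] = gen.astype(int)
    lo, hi = GENERATION_RANGE
    odd_gen = (out["generation"] < lo) | (out["generation"] > hi)
    if odd_gen.any():
        log.warning(
            "%s: %d row(s) with generation outside %d-%d",
            source, int(odd_gen.sum()), lo, hi,
        )

    for col in ("sl_mm", "gono_mm"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    males = out["sex"] == "male"

    bad_sl = ~np.isfinite(out["sl_mm"]) | (out["sl_mm"] <= 0)
    bad_gono = males & (~np.isfinite(out["gono_mm"]) | (out["gono_mm"] <= 0))
    for name, mask in (("sl_mm", bad_sl), ("gono_mm", bad_gono)):
        if mask.any():
            rows = list(out.index[mask][:5])
            raise SchemaError(
                f"{source}: non-positive or unparseable {name} at row(s) {rows}"
            )

    rel = out.loc[males, "gono_mm"] / out.loc[males, "sl_mm"]
    lo, hi = RELATIVE_LENGTH_FLAG_RANGE
    flagged = (rel < lo) | (rel > hi)
    if flagged.any():
        log.warning(
            "%s: %d male(s) with relative gonopodium length outside %.0f-%.0f%% "
            "(rows %s) — kept, but check the measurements",
            source, int(flagged.sum()), 100 * lo, 100 * hi,
            list(rel.index[flagged][:5]),
        )

    dup = out["fish_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"{source}: duplicated fish_id(s): "
            f"{sorted(out.loc[dup, 'fish_id'].unique()[:5])}"
        )
    return out


def male_records(df: pd.DataFrame, *, warn: bool = True) -> pd.DataFrame:
    """Return only male rows; optionally warn if females were dropped."""
    males = df[df["sex"] == "male"]
    n_dropped = len(df) - len(males)
    if n_dropped and warn:
        log.warning("filtered out %d female record(s)", n_dropped)
    return males
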