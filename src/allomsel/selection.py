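"""Truncation selection on residuals and selection differentials.

Sires are chosen by rank on their signed allometric residual: the most
positive residuals in up-selected lines, the most negative in
down-selected lines, or a seeded random subset in control lines.  The
selection differential S is the mean residual of the selected males minus
the mean of all measured males; the *effective* differential S_eff uses
only the males that actually sired offspring (optionally weighted by
offspring number).  Cumulating S_eff over rounds gives S_c, the regressor
in the realized-heritability analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .allometry import ResidualSet
from .errors import InsufficientCandidatesError, WeightMismatchError

log = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "none")


@dataclass
class SelectionRound:
    """Audit record of one line x generation selection event."""

    replicate: str
    line: str
    generation: int
    direction: str                       # "up" | "down" | "none"
    measured_ids: np.ndarray
    selected_ids: np.ndarray             # candidate sires (e.g. top/bottom 40)
    sire_ids: np.ndarray                 # males that actually bred
    offspring_counts: dict = field(default_factory=dict)   # sire_id -> n fry
    S: float = float("nan")              # residual units
    S_eff: float = float("nan")

    def __post_init__(self):
        sel = set(map(str, self.selected_ids))
        if not sel <= set(map(str, self.measured_ids)):
            raise ValueError("selected_ids must be a subset of measured_ids")
        if not set(map(str, self.sire_ids)) <= sel:
            raise ValueError("sire_ids must be a subset of selected_ids")


def select_extremes(residuals: ResidualSet, n_select: int, direction: str,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Ids of the ``n_select`` most extreme residuals.

    direction "up" takes the most positive, "down" the most negative,
    "none" a uniform random subset (requires ``rng``).  Ties at the
    truncation boundary are broken by stable sort on fish_id and logged.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    vals = residuals.values
    ids = residuals.ids
    n = vals.size
    if n_select > n:
        raise InsufficientCandidatesError(
            f"asked for {n_select} of {n} measured males"
        )
    if direction == "none":
        if rng is None:
            raise ValueError("direction='none' requires a seeded rng")
        return rng.choice(ids, size=n_select, replace=False)

    # lexsort: last key is primary.  Sort by residual, ties by fish_id,
    # so the chosen set is deterministic for any input order.
    key = -vals if direction == "up" else vals
    order = np.lexsort((ids, key))
    chosen = order[:n_select]
    if n_select < n:
        boundary, first_out = vals[order[n_select - 1]], vals[order[n_select]]
        if boundary == first_out:
            log.warning(
                "tie at the truncation boundary (residual %.6g); "
                "broken by fish_id order", boundary,
            )
    return ids[chosen]


def selection_differential(residuals: ResidualSet,
                           selected_ids: Sequence,
                           sire_ids: Sequence | None = None,
                           weights: Mapping | None = None) -> tuple[float, float]:
    """(S, S_eff) in the residual set's units.

    S     = mean(residual | selected) - mean(residual | all measured)
    S_eff = same, with the selected mean taken over the actual sires,
            offspring-count weighted when ``weights`` maps sire_id -> count.

    With no sire list, S_eff falls back to S.
    """
    selected_ids = np.asarray(selected_ids, dtype=object)
    if selected_ids.size == 0:
        raise ValueError("selected_ids must be nonempty")
    lookup = {str(i): v for i, v in zip(residuals.ids, residuals.values)}
    try:
        sel_vals = np.array([lookup[str(i)] for i in selected_ids])
    except KeyError as e:
        raise ValueError(f"selected id {e} not among measured ids") from None
    base = float(np.mean(residuals.values))
    S = float(np.mean(sel_vals)) - base

    if sire_ids is None:
        if weights is not None:
            raise WeightMismatchError("weights supplied without a sire list")
        return S, S

    sire_ids = np.asarray(sire_ids, dtype=object)
    if sire_ids.size == 0:
        raise ValueError("sire_ids must be nonempty when supplied")
    sire_vals = np.array([lookup[str(i)] for i in sire_ids])
    if weights is None:
        S_eff = float(np.mean(sire_vals)) - base
    else:
        extra = set(map(str, weights)) - set(map(str, sire_ids))
        if extra:
            raise WeightMismatchError(
                f"offspring counts for non-sires: {sorted(extra)[:5]}"
            )
        w = np.array([float(weights.get(str(i), 0.0)) for i in sire_ids])
        if w.sum() <= 0:
            raise WeightMismatchError("offspring-count weights sum to zero")
        S_eff = float(np.average(sire_vals, weights=w)) - base
    return S, S_eff


def cumulative_differentials(rounds: Sequence[SelectionRound]) -> np.ndarray:
    """Running sum of S_eff over rounds ordered by generation.

    S_c,t = sum of S_eff over rounds up to and including t.  A gap in the
    generation sequence is logged but the sum still runs over the rounds
    supplied.
    """
    gens = [r.generation for r in rounds]
    if gens != sorted(gens):
        raise ValueError("rounds must be ordered by generation")
    if len({(r.replicate, r.line) for r in rounds}) > 1:
        raise ValueError("rounds must belong to a single line")
    if gens and (np.diff(gens) > 1).any():
        log.warning("generation gaps in selection rounds: %s", gens)
    return np.cumsum([r.S_eff for r in rounds])
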