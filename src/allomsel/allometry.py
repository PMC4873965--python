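"""Log-log allometry fitting and residuals.

Static allometry — the among-individual scaling of a trait with body size —
is modelled here as a straight line on log10-log10 axes,

    log10(trait) = intercept + slope * log10(SL),

fitted either by ordinary least squares (OLS) or by reduced major axis
(RMA, also called standardized major axis) regression.  RMA minimizes
perpendicular-area deviations; its slope is the ratio of standard
deviations signed by the correlation,

    b_RMA = sign(r) * sd(log trait) / sd(log SL) = b_OLS / r,

so |b_RMA| = |b_OLS| / |r| holds exactly on every dataset.  A slope below 1
is negative allometry: larger fish carry proportionally shorter trait
values.

Residuals come in two flavours: *vertical* (trait-axis deviation, the OLS
residual) and *perpendicular* (signed point-to-line distance, equal to the
vertical residual divided by sqrt(1 + slope^2)).  Selection on either picks
the same individuals because they differ by a positive constant factor.

Lengths are stored in mm throughout the package; a fit can be requested in
cm, which leaves the slope unchanged and shifts the intercept by
(1 - slope) * log10(scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateGroupError,
    DegenerateInputError,
    SingularFitError,
    UndefinedSignError,
    UnitMismatchError,
)
from .records import male_records

log = logging.getLogger(__name__)

_UNIT_SCALE = {"mm": 1.0, "cm": 0.1}  # multiply mm by this to get the unit


@dataclass(frozen=True)
class AllometricFit:
    """A fitted log10-log10 allometric line.

    ``slope`` is dimensionless; ``intercept`` is in log10 units of the
    trait axis and therefore depends on ``units``.
    """

    method: str            # "OLS" or "RMA"
    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int
    se_slope: float
    se_intercept: float
    units: str = "mm"
    log_base: int = field(default=10, repr=False)

    def predict_log10(self, sl_mm: np.ndarray | float) -> np.ndarray | float:
        """Predicted log10(trait) in the fit's own units, from SL in mm."""
        x = np.log10(np.asarray(sl_mm, dtype=float) * _UNIT_SCALE[self.units])
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class ResidualSet:
    """Signed residuals of a set of males from an allometric line."""

    mode: str                       # "vertical" or "perpendicular"
    reference: AllometricFit
    values: np.ndarray              # log10 units (along y, or along the normal)
    ids: np.ndarray                 # fish_id per value, same order

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=object))
        if self.values.shape != self.ids.shape:
            raise ValueError("values and ids must align")


def _xy_log10(sl_mm, trait_mm, units: str):
    if units not in _UNIT_SCALE:
        raise ValueError(f"units must be one of {sorted(_UNIT_SCALE)}, got {units!r}")
    sl = np.asarray(sl_mm, dtype=float)
    tr = np.asarray(trait_mm, dtype=float)
    if sl.size != tr.size:
        raise ValueError("sl and trait arrays must have equal length")
    if np.any(~np.isfinite(sl)) or np.any(~np.isfinite(tr)):
        raise DegenerateInputError("non-finite lengths in input")
    if np.any(sl <= 0) or np.any(tr <= 0):
        raise DegenerateInputError("all lengths must be > 0 for log-log fitting")
    s = _UNIT_SCALE[units]
    return np.log10(sl * s), np.log10(tr * s)


def _extract(records, trait: str):
    """Accept a morph table or a pair of arrays."""
    if isinstance(records, pd.DataFrame):
        males = male_records(records)
        return males["sl_mm"].to_numpy(), males[trait].to_numpy()
    sl, tr = records
    return np.asarray(sl, float), np.asarray(tr, float)


def fit_ols(records, units: str = "mm", *, trait: str = "gono_mm") -> AllometricFit:
    """OLS fit of log10(trait) on log10(SL).

    ``records`` is either a morph table (males are used; SL from ``sl_mm``,
    trait from ``trait``) or a ``(sl_mm, trait_mm)`` pair of sequences.
    """
    sl, tr = _extract(records, trait)
    x, y = _xy_log10(sl, tr, units)
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise SingularFitError("zero variance in SL; slope undefined")
    res = stats.linregress(x, y)
    return AllometricFit(
        method="OLS",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        n=int(n),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        units=units,
    )


def fit_rma(records, units: str = "mm", *, trait: str = "gono_mm") -> AllometricFit:
    """Reduced major axis (standardized major axis) fit.

    slope = sign(r) * sd(log trait) / sd(log SL); the intercept passes the
    line through the bivariate mean.  The slope standard error equals the
    OLS slope standard error (the standard SMA result).
    """
    ols = fit_ols(records, units, trait=trait)
    if ols.r == 0.0:
        raise UndefinedSignError("correlation is zero; RMA slope sign undefined")
    sl, tr = _extract(records, trait)
    x, y = _xy_log10(sl, tr, units)
    slope = float(np.sign(ols.r) * np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return replace(
        ols, method="RMA", slope=slope, intercept=intercept,
        se_intercept=float("nan"),
    )


def residuals(records, fit: AllometricFit, mode: str = "perpendicular",
              *, trait: str = "gono_mm", units: str = "mm") -> ResidualSet:
    """Signed residuals of each male from ``fit``.

    vertical:       y - (a + b x)
    perpendicular:  (y - (a + b x)) / sqrt(1 + b^2)

    Both are positive above the line.  ``units`` states the units of the
    input lengths (mm for morph tables) and must match the fit's units tag.
    """
    if mode not in ("vertical", "perpendicular"):
        raise ValueError(f"unknown residual mode {mode!r}")
    if isinstance(records, pd.DataFrame):
        males = male_records(records)
        sl = males["sl_mm"].to_numpy()
        tr = males[trait].to_numpy()
        ids = males["fish_id"].to_numpy()
        units = "mm"
    else:
        sl, tr = records
        sl = np.asarray(sl, float)
        tr = np.asarray(tr, float)
        ids = np.arange(sl.size).astype(str)
    if units != fit.units:
        raise UnitMismatchError(
            f"records are in {units} but the fit is in {fit.units}"
        )
    x, y = _xy_log10(sl, tr, fit.units)
    vert = y - (fit.intercept + fit.slope * x)
    if mode == "perpendicular":
        vals = vert / np.sqrt(1.0 + fit.slope ** 2)
    else:
        vals = vert
    return ResidualSet(mode=mode, reference=fit, values=vals, ids=ids)


def predict_at(fit: AllometricFit, sl_ref_mm: float) -> float:
    """Predicted trait length in mm at a reference SL in mm.

    Evaluates 10^(a + b log10 SL) in the fit's units and converts back
    to mm, so the result is unit-tag independent.
    """
    if sl_ref_mm <= 0:
        raise ValueError("sl_ref_mm must be > 0")
    return float(10.0 ** fit.predict_log10(sl_ref_mm) / _UNIT_SCALE[fit.units])


def relative_percent(records, *, trait: str = "gono_mm"):
    """Per-fish relative trait size, 100 * trait / SL, with mean +/- s.e.

    Female rows are filtered with a logged warning.  Returns
    ``(per_fish, mean, sem)`` where ``per_fish`` is an ndarray of percents.
    """
    sl, tr = _extract(records, trait)
    if sl.size == 0:
        raise DegenerateInputError("no male records")
    pct = 100.0 * tr / sl
    sem = float(np.std(pct, ddof=1) / np.sqrt(pct.size)) if pct.size > 1 else float("nan")
    return pct, float(np.mean(pct)), sem


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def compare_allometries(groups: Mapping[str, object] | Iterable, *,
                        trait: str = "gono_mm", units: str = "mm") -> dict:
    """ANCOVA homogeneity tests across >= 2 groups on log10 data.

    Fits three nested least-squares models — separate slopes and
    intercepts; common slope, separate intercepts; single line — and
    compares them by full-vs-reduced F tests.  Both the slope test and the
    (given a common slope) intercept test use the separate-slopes residual
    mean square, giving df (k - 1, N - 2k).

    ``groups`` maps a label to a morph table or an ``(sl, trait)`` pair.
    Returns a dict with ``slope_F``, ``slope_p``, ``intercept_F``,
    ``intercept_p``, ``df_num``, ``df_den``, ``n_total``, ``k``.
    """
    if not isinstance(groups, Mapping):
        groups = {i: g for i, g in enumerate(groups)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    xs, ys, labels = [], [], []
    for name, g in groups.items():
        sl, tr = _extract(g, trait)
        if sl.size < 3:
            raise DegenerateGroupError(name, f"only {sl.size} point(s)")
        x, y = _xy_log10(sl, tr, units)
        if np.ptp(x) == 0:
            raise DegenerateGroupError(name, "zero variance in SL")
        xs.append(x)
        ys.append(y)
        labels.append(name)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    k = len(labels)
    n = x.size
    df_den = n - 2 * k
    if df_den <= 0:
        raise DegenerateInputError("too few points for the homogeneity test")

    # indicator block: one column per group
    idx = np.repeat(np.arange(k), [g.size for g in xs])
    D = np.zeros((n, k))
    D[np.arange(n), idx] = 1.0

    X_full = np.hstack([D, D * x[:, None]])        # separate slopes + intercepts
    X_common = np.hstack([D, x[:, None]])          # common slope, own intercepts
    X_single = np.column_stack([np.ones(n), x])    # one line

    rss_full = _rss(X_full, y)
    rss_common = _rss(X_common, y)
    rss_single = _rss(X_single, y)

    ms_err = rss_full / df_den
    df_num = k - 1
    slope_F = (rss_common - rss_full) / df_num / ms_err
    intercept_F = (rss_single - rss_common) / df_num / ms_err
    return {
        "slope_F": float(slope_F),
        "slope_p": float(stats.f.sf(slope_F, df_num, df_den)),
        "intercept_F": float(intercept_F),
        "intercept_p": float(stats.f.sf(intercept_F, df_num, df_den)),
        "df_num": df_num,
        "df_den": df_den,
        "n_total": int(n),
        "k": k,
    }
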