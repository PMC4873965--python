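"""Response to selection and realized heritability.

Generation-level environmental shocks move absolute body and trait sizes
for every line at once, so all response variables are measured as
*deviations from the same-replicate control line* in the same generation:

* predicted gonopodium length at a reference SL (22.18 mm by default),
  from the per-cell allometric fit, in mm and as a percent of the control
  prediction;
* mean SL;
* allometric (RMA) slope.

For realized heritability the focal trait is each male's residual from the
control-line allometric fit of his own replicate and generation.  The
per-generation response R_t is the mean of that residual over all measured
focal-line males, and the regressor is the cumulative effective selection
differential S_c accumulated over the selection rounds that produced
generation t.  Because only males were selected (dams were random), the
expected per-round gain is h^2 * S / 2, so

    h^2 = 2 * slope of the R-on-S_c regression.

The regime-level estimate is the mean of the three replicate estimates,
with s.e. = sd / sqrt(3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import AllometricFit, fit_ols, fit_rma, predict_at, residuals
from .errors import (
    AllomselError,
    MissingControlError,
    SingularRegressionError,
)
from .records import male_records
from .selection import SelectionRound, selection_differential

log = logging.getLogger(__name__)

#: reference standard length (mm) at which line means are compared
SL_REF_MM = 22.18

# residual_mode -> the fit method it is conventionally paired with:
# vertical residuals from least-squares control fits, or perpendicular
# residuals from RMA control fits.
_DEFAULT_FIT_METHOD = {"vertical": "OLS", "perpendicular": "RMA"}


@dataclass(frozen=True)
class ResponseSeries:
    """Aligned (generation, R_t, S_c,t) series for one selected line."""

    replicate: str
    line: str
    generations: np.ndarray
    R: np.ndarray                  # mean focal residual from the control fit
    S_c: np.ndarray                # cumulative S_eff *before* each generation
    residual_mode: str
    fit_method: str
    weighting: str                 # "unweighted" | "offspring"


@dataclass(frozen=True)
class HeritabilityEstimate:
    slope: float
    h2: float                      # exactly 2 * slope (male-only selection)
    se_slope: float
    r_squared: float
    generations_used: int
    residual_mode: str
    weighting_mode: str
    replicate: str = ""
    line: str = ""


def _fit(method: str):
    if method == "RMA":
        return fit_rma
    if method == "OLS":
        return fit_ols
    raise ValueError(f"unknown fit method {method!r}")


def control_reference_fits(records: pd.DataFrame, method: str = "RMA",
                           ) -> dict[tuple[str, int], AllometricFit]:
    """One control-line fit per (replicate, generation) cell.

    Every (replicate, generation) present anywhere in ``records`` must have
    control males; a missing cell raises
    :class:`~allomsel.errors.MissingControlError` naming it.
    """
    males = male_records(records, warn=False)
    fitter = _fit(method)
    fits: dict[tuple[str, int], AllometricFit] = {}
    cells = males[["replicate", "generation"]].drop_duplicates()
    ctrl = males[males["line"] == "control"]
    for rep, gen in cells.itertuples(index=False):
        sub = ctrl[(ctrl["replicate"] == rep) & (ctrl["generation"] == gen)]
        if len(sub) == 0:
            raise MissingControlError(rep, gen)
        fits[(rep, int(gen))] = fitter(sub)
    return fits


def line_deviation_table(records: pd.DataFrame, sl_ref_mm: float = SL_REF_MM,
                         method: str = "RMA") -> pd.DataFrame:
    """Per-cell deviations of each selected line from its control.

    Returns one row per (replicate, generation, line) with the cell's own
    allometric fit summarized and three deviation measures relative to the
    same-replicate control cell: predicted gonopodium at ``sl_ref_mm``
    (``dev_gono_mm`` and ``dev_gono_pct``), mean SL (``mean_sl_dev_mm``)
    and allometric slope (``rma_slope_dev``).  Control rows carry zeros.
    Cells with fewer than 3 males are excluded with a logged warning.
    """
    males = male_records(records, warn=False)
    fitter = _fit(method)
    cell_stats: dict[tuple, dict] = {}
    for (rep, gen, line), sub in males.groupby(
            ["replicate", "generation", "line"], sort=True):
        if len(sub) < 3:
            log.warning(
                "cell (%s, g%s, %s) has %d male(s); excluded", rep, gen, line,
                len(sub),
            )
            continue
        fit = fitter(sub)
        cell_stats[(rep, int(gen), line)] = {
            "n": len(sub),
            "pred_gono_mm": predict_at(fit, sl_ref_mm),
            "mean_sl_mm": float(sub["sl_mm"].mean()),
            "slope": fit.slope,
        }
    rows = []
    for (rep, gen, line), st in cell_stats.items():
        ctrl = cell_stats.get((rep, gen, "control"))
        if ctrl is None:
            raise MissingControlError(rep, gen)
        rows.append({
            "replicate": rep, "generation": gen, "line": line, "n": st["n"],
            "pred_gono_mm": st["pred_gono_mm"],
            "dev_gono_mm": st["pred_gono_mm"] - ctrl["pred_gono_mm"],
            "dev_gono_pct": 100.0 * (st["pred_gono_mm"] - ctrl["pred_gono_mm"])
                            / ctrl["pred_gono_mm"],
            "mean_sl_dev_mm": st["mean_sl_mm"] - ctrl["mean_sl_mm"],
            "rma_slope": st["slope"],
            "rma_slope_dev": st["slope"] - ctrl["slope"],
        })
    return pd.DataFrame(rows).sort_values(
        ["replicate", "generation", "line"]).reset_index(drop=True)


def divergence_range(deviation_table: pd.DataFrame) -> tuple[float, float]:
    """(min, max) across replicates of the combined up+down divergence.

    For each replicate the combined divergence is the up-line percent
    increase plus the down-line percent decrease (``up_pct - down_pct``
    with signed deviations).  The table must hold a single generation with
    up and down rows for all three replicates.  Endpoints are rounded to
    one decimal.
    """
    t = deviation_table
    if t["generation"].nunique() != 1:
        raise ValueError("deviation table must be restricted to one generation")
    combined = []
    for rep, sub in t.groupby("replicate"):
        by_line = sub.set_index("line")["dev_gono_pct"]
        if "up" not in by_line.index or "down" not in by_line.index:
            raise AllomselError(f"replicate {rep!r}: missing up or down line")
        combined.append(float(by_line["up"] - by_line["down"]))
    if len(combined) < 3:
        raise AllomselError("need all three replicates")
    return round(min(combined), 1), round(max(combined), 1)


def response_series(records: pd.DataFrame, rounds: Sequence[SelectionRound],
                    residual_mode: str = "vertical",
                    fit_method: str | None = None,
                    weighting: str = "unweighted",
                    ) -> dict[tuple[str, str], ResponseSeries]:
    """One aligned (R_t, S_c,t) series per selected line.

    The focal trait is the residual (``residual_mode``) from the
    *control-line* fit (``fit_method``, defaulting to the mode's
    conventional pairing) of the same replicate and generation.  R_t is the
    trait mean over all measured focal males in generation t; S_eff for the
    round at generation tau is recomputed on the same trait axis from the
    round's sire ids, so R and S are mode-consistent by construction.
    S_c,t sums S_eff over rounds with generation < t (selection acts on the
    parents), so R_1 pairs with S_c = 0.
    """
    if residual_mode not in _DEFAULT_FIT_METHOD:
        raise ValueError(f"unknown residual mode {residual_mode!r}")
    if weighting not in ("unweighted", "offspring"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if fit_method is None:
        fit_method = _DEFAULT_FIT_METHOD[residual_mode]
    males = male_records(records, warn=False)
    ctrl_fits = control_reference_fits(records, method=fit_method)

    rounds_by_line: dict[tuple[str, str], list[SelectionRound]] = {}
    for r in rounds:
        rounds_by_line.setdefault((r.replicate, r.line), []).append(r)
    for rs in rounds_by_line.values():
        rs.sort(key=lambda r: r.generation)

    out: dict[tuple[str, str], ResponseSeries] = {}
    for (rep, line), sub in males.groupby(["replicate", "line"]):
        if line == "control":
            continue
        gens = np.sort(sub["generation"].unique())
        R = np.empty(gens.size)
        trait_sets = {}
        for i, g in enumerate(gens):
            cohort = sub[sub["generation"] == g]
            rs = residuals(cohort, ctrl_fits[(rep, int(g))], residual_mode)
            trait_sets[int(g)] = rs
            R[i] = float(np.mean(rs.values))
        s_eff = {}
        for rnd in rounds_by_line.get((rep, line), []):
            g = int(rnd.generation)
            if g not in trait_sets:
                raise AllomselError(
                    f"selection round at generation {g} for ({rep}, {line}) "
                    "has no measured males in the morph table"
                )
            weights = rnd.offspring_counts if weighting == "offspring" else None
            _, se = selection_differential(
                trait_sets[g], rnd.selected_ids, rnd.sire_ids, weights)
            s_eff[g] = se
        S_c = np.array([
            sum(v for g0, v in s_eff.items() if g0 < g) for g in gens
        ])
        out[(rep, line)] = ResponseSeries(
            replicate=rep, line=line, generations=gens, R=R, S_c=S_c,
            residual_mode=residual_mode, fit_method=fit_method,
            weighting=weighting,
        )
    return out


def realized_h2(series: ResponseSeries,
                include_intercept: bool = True) -> HeritabilityEstimate:
    """Realized heritability from the R-on-S_c regression of one line.

    h^2 is exactly twice the regression slope (selection acted on sires
    only).  ``include_intercept=False`` forces the line through the origin.
    """
    S_c, R = series.S_c, series.R
    if S_c.size < 3:
        raise ValueError("need at least 3 generations")
    if np.ptp(S_c) == 0:
        raise SingularRegressionError("S_c is constant; slope undefined")
    if include_intercept:
        res = stats.linregress(S_c, R)
        slope, se, r2 = float(res.slope), float(res.stderr), float(res.rvalue**2)
    else:
        sxx = float(S_c @ S_c)
        slope = float(S_c @ R) / sxx
        resid = R - slope * S_c
        df = S_c.size - 1
        se = float(np.sqrt((resid @ resid) / df / sxx))
        ss_tot = float(R @ R)
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return HeritabilityEstimate(
        slope=slope, h2=2.0 * slope, se_slope=se, r_squared=r2,
        generations_used=int(S_c.size), residual_mode=series.residual_mode,
        weighting_mode=series.weighting, replicate=series.replicate,
        line=series.line,
    )


def aggregate_h2(estimates: Sequence[HeritabilityEstimate]) -> tuple[float, float]:
    """Mean +/- s.e. of h^2 over replicate estimates of one regime.

    The s.e. is the sd of the replicate estimates over sqrt(n); per-line
    regression s.e. understate the between-line variation.
    """
    vals = np.array([e.h2 for e in estimates], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two replicate estimates")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def _term_f(y, X_full, cols_drop, df_resid):
    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    rss_full = rss(X_full)
    keep = [j for j in range(X_full.shape[1]) if j not in cols_drop]
    rss_red = rss(X_full[:, keep])
    df_num = len(cols_drop)
    # clamp round-off: a perfectly fitting model leaves RSS ~ eps * ||y||^2
    tiny = 1e3 * np.finfo(float).eps * max(float(np.sum(y * y)), 1.0)
    num = max(rss_red - rss_full, 0.0)
    if num <= tiny:
        F = 0.0
    elif rss_full <= tiny:
        F = float("inf")
    else:
        F = num / df_num / (rss_full / df_resid)
    return F, float(stats.f.sf(F, df_num, df_resid)), df_num


def trend_test(deviation_series: pd.DataFrame,
               response: str = "dev_gono_pct") -> dict:
    """Linear-model F tests on one regime's deviation series.

    Fits ``response ~ generation + replicate + generation:replicate`` by
    least squares, with generation continuous and replicate a sum-to-zero
    factor, and tests each term by a full-vs-reduced F (partial,
    type-III-style).  With 3 replicates x 9 generations this gives the
    df pattern (1, 21) for generation and (2, 21) for replicate.

    Returns ``{"generation": {...}, "replicate": {...}, "interaction":
    {...}}`` each with keys ``F``, ``p``, ``df_num``, ``df_den``.
    """
    t = deviation_series
    if t["line"].nunique() > 1:
        raise ValueError("pass a single regime's deviation rows")
    y = t[response].to_numpy(dtype=float)
    gen = t["generation"].to_numpy(dtype=float)
    reps = sorted(t["replicate"].unique())
    k = len(reps)
    if k < 2 or t["generation"].nunique() < 3:
        raise ValueError("need >= 2 replicates and >= 3 generations")
    # sum-to-zero contrasts for replicate
    C = np.zeros((len(t), k - 1))
    rep_idx = t["replicate"].map({r: i for i, r in enumerate(reps)}).to_numpy()
    for j in range(k - 1):
        C[:, j] = np.where(rep_idx == j, 1.0, np.where(rep_idx == k - 1, -1.0, 0.0))
    X = np.column_stack([np.ones(len(t)), gen, C, C * gen[:, None]])
    df_resid = len(t) - X.shape[1]
    if df_resid <= 0 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise AllomselError(
            "rank-deficient trend model: generation, replicate or their "
            "interaction is aliased (too few distinct cells)"
        )
    terms = {
        "generation": [1],
        "replicate": list(range(2, 2 + (k - 1))),
        "interaction": list(range(2 + (k - 1), X.shape[1])),
    }
    out = {}
    for name, cols in terms.items():
        F, p, df_num = _term_f(y, X, cols, df_resid)
        out[name] = {"F": F, "p": p, "df_num": df_num, "df_den": df_resid}
    return out
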