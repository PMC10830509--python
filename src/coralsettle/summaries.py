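"""Species-level summaries downstream of TC50 estimation.

Precompetency classification, cross-species summary statistics, the
egg-size regression, passive-transport arithmetic, and the
competency-times-survival dispersal-potential curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import DispersalCurve, SpeciesSummaryRow

__all__ = [
    "classify_precompetency",
    "summarize_species_table",
    "egg_size_regression",
    "transport_distance",
    "dispersal_potential",
    "TableSummary",
    "RegressionFit",
    "DEFAULT_CLASS_BOUNDARIES",
    "DEFAULT_DECAY_RATE",
]

#: Class boundaries in days: short < 3, mid in [3, 5], long > 5.
DEFAULT_CLASS_BOUNDARIES = (3.0, 5.0)
DEFAULT_DECAY_RATE = 0.05

SECONDS_PER_DAY = 86_400
CM_PER_KM = 100_000


def classify_precompetency(
    tc50: float, boundaries: tuple[float, float] = DEFAULT_CLASS_BOUNDARIES
) -> str:
    """Classify a TC50 into short / mid / long precompetency.

    Boundary convention: short strictly below the lower boundary, mid on
    the closed interval between the boundaries, long strictly above the
    upper one.
    """
    if tc50 <= 0 or not np.isfinite(tc50):
        raise ValueError(f"tc50 must be a positive finite number, got {tc50}")
    lo, hi = boundaries
    if not lo < hi:
        raise ValueError("boundaries must be increasing")
    if tc50 < lo:
        return "short"
    if tc50 <= hi:
        return "mid"
    return "long"


@dataclass(frozen=True)
class TableSummary:
    """Cross-species summary of a TC50 table."""

    n_species: int
    mean_tc50: float  # rounded to 1 dp for display
    min_tc50: float
    min_species: str
    max_tc50: float
    max_species: str
    class_counts: dict
    class_percentages: dict  # whole percents


def summarize_species_table(
    rows: Sequence[SpeciesSummaryRow] | pd.DataFrame,
    boundaries: tuple[float, float] = DEFAULT_CLASS_BOUNDARIES,
) -> TableSummary:
    """Mean/min/max TC50 and precompetency class tallies across species."""
    df = _as_frame(rows)
    if df.empty:
        raise ValueError("empty species table")
    classes = df["tc50"].map(lambda t: classify_precompetency(t, boundaries))
    counts = {c: int((classes == c).sum()) for c in ("short", "mid", "long")}
    total = len(df)
    i_min = df["tc50"].idxmin()
    i_max = df["tc50"].idxmax()
    return TableSummary(
        n_species=total,
        mean_tc50=round(float(df["tc50"].mean()), 1),
        min_tc50=round(float(df.loc[i_min, "tc50"]), 1),
        min_species=str(df.loc[i_min, "species_id"]),
        max_tc50=round(float(df.loc[i_max, "tc50"]), 1),
        max_species=str(df.loc[i_max, "species_id"]),
        class_counts=counts,
        class_percentages={c: round(100.0 * k / total) for c, k in counts.items()},
    )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of TC50 on oocyte diameter."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float  # two-sided, slope t test
    n: int


def egg_size_regression(
    rows: Sequence[SpeciesSummaryRow] | pd.DataFrame,
) -> RegressionFit:
    """Gaussian-identity GLM (ordinary least squares) of TC50 on oocyte diameter.

    Adjusted R-squared uses the simple-regression form
    1 - (1 - R^2)(n - 1)/(n - 2); the slope p-value comes from a t
    statistic with n - 2 degrees of freedom.
    """
    df = _as_frame(rows).dropna(subset=["tc50", "oocyte_diameter_um"])
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 species with both fields, got {n}")
    x = df["oocyte_diameter_um"].to_numpy(dtype=float)
    y = df["tc50"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in oocyte diameter")
    # closed-form simple OLS via centred moments
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(yc @ yc)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if ss_res == 0:
        p = 0.0
    else:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return RegressionFit(
        slope=slope, intercept=intercept, r_squared=r2, adj_r_squared=adj,
        p_value=p, n=n,
    )


def transport_distance(current_speed_cm_s: float, duration_days: float) -> float:
    """Passive advection distance in km for a current speed and duration.

    Returns the exact value; round to the nearest km for display.
    """
    if current_speed_cm_s < 0 or duration_days < 0:
        raise ValueError("speed and duration must be >= 0")
    return current_speed_cm_s * SECONDS_PER_DAY * duration_days / CM_PER_KM


def dispersal_potential(
    competency: Sequence[float],
    age_grid: Sequence[float],
    decay_rate: float = DEFAULT_DECAY_RATE,
) -> DispersalCurve:
    """Overlay exponential survival on a competency curve and take the product.

    survival(t) = exp(-decay_rate * t); the product bounds realized
    dispersal potential by both competency and survival pointwise.
    """
    comp = np.asarray(competency, dtype=float)
    grid = np.asarray(age_grid, dtype=float)
    if comp.shape != grid.shape:
        raise ValueError("competency and age_grid must have the same shape")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    if comp.size and (comp.min() < 0 or comp.max() > 1):
        raise ValueError("competency values must lie in [0, 1]")
    if grid.size and grid.min() < 0:
        raise ValueError("ages must be >= 0")
    survival = np.exp(-decay_rate * grid)
    return DispersalCurve(
        age_grid=grid,
        competency=comp,
        survival=survival,
        product=comp * survival,
        decay_rate=decay_rate,
    )


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.reset_index(drop=True)
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "family": r.family,
                "species": r.species,
                "tc50": r.tc50,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "best_cue": r.best_cue,
                "precompetency_class": r.precompetency_class,
                "oocyte_diameter_um": r.oocyte_diameter_um,
            }
            for r in rows
        ]
    )
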