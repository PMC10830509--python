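"""Binomial spline GAM of settlement through time and AUC cue ranking.

The proportion settled is modelled against a cubic regression spline of
larval age, with separate spline coefficients per cue and a plate-level
varying intercept and age slope. Smoothness comes from a shared ridge prior
on the spline coefficients with a half-normal SD hyperprior; plate effects
get their own half-normal SD hyperpriors. Sampling is non-centred
throughout.

Fitted curves are summarized pointwise on the response scale; the area
under each cue's curve is computed per posterior draw by trapezoidal
integration on a uniform grid (default resolution 100) over the observed
age range, and cues are ranked by comparing the full AUC posteriors with
pairwise exceedance probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.interpolate import BSpline

from . import mcmc
from .competency import pairwise_exceedance
from .datatypes import CueRanking, PosteriorDraws, SamplerConfig

__all__ = [
    "SplineBasis",
    "GamPriorSpec",
    "AUCPosterior",
    "SettlementCurve",
    "build_spline_basis",
    "fit_settlement_gam",
    "curve_from_draws",
    "auc_per_draw",
    "rank_cues",
    "trapezoid_auc",
    "MAX_KNOTS",
    "DEFAULT_RESOLUTION",
]


def trapezoid_auc(values, grid) -> float:
    """Trapezoidal area under sampled curve values; exact for affine curves."""
    return float(np.trapezoid(np.asarray(values, float), np.asarray(grid, float)))

MAX_KNOTS = 5
DEFAULT_RESOLUTION = 100
_DEGREE = 3


@dataclass
class SplineBasis:
    """Cubic regression-spline basis over the observed age range."""

    knot_locations: np.ndarray  # interior knots, days
    knots_full: np.ndarray  # clamped knot vector incl. boundary repeats
    basis_matrix: np.ndarray  # rows = observations, cols = basis functions
    ages: np.ndarray
    degree: int = _DEGREE
    n_knots: int = 0

    @property
    def n_basis(self) -> int:
        return len(self.knots_full) - self.degree - 1

    @property
    def age_min(self) -> float:
        return float(self.knots_full[0])

    @property
    def age_max(self) -> float:
        return float(self.knots_full[-1])

    def evaluate(self, ages: Sequence[float]) -> np.ndarray:
        """Basis matrix at new ages; refuses extrapolation."""
        ages = np.asarray(ages, dtype=float)
        if ages.min() < self.age_min - 1e-12 or ages.max() > self.age_max + 1e-12:
            raise ValueError(
                f"ages outside the fitted range [{self.age_min}, {self.age_max}]; "
                "extrapolation is refused"
            )
        ages = np.clip(ages, self.age_min, self.age_max)
        return BSpline.design_matrix(
            ages, self.knots_full, self.degree, extrapolate=False
        ).toarray()


def build_spline_basis(ages: Sequence[float], n_knots: int = MAX_KNOTS) -> SplineBasis:
    """Cubic B-spline basis with interior knots at quantiles of distinct ages.

    At most :data:`MAX_KNOTS` interior knots by default (overfitting guard);
    a larger request is honoured with a warning. When the data cannot
    support the requested knots they are reduced with a warning; fewer than
    two distinct ages is an error.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0 or not np.isfinite(ages).all():
        raise ValueError("ages must be non-empty and finite")
    distinct = np.unique(ages)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct ages to build a spline basis")
    if n_knots > MAX_KNOTS:
        warnings.warn(
            f"n_knots={n_knots} exceeds the recommended maximum of {MAX_KNOTS}",
            stacklevel=2,
        )
    # keep n_basis = n_knots + degree + 1 <= number of distinct ages
    max_supported = max(0, distinct.size - (_DEGREE + 1))
    if n_knots > max_supported:
        warnings.warn(
            f"reducing interior knots from {n_knots} to {max_supported}: "
            f"only {distinct.size} distinct ages observed",
            stacklevel=2,
        )
        n_knots = max_supported
    lo, hi = float(distinct[0]), float(distinct[-1])
    if n_knots > 0:
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        interior = np.quantile(distinct, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)])
    design = BSpline.design_matrix(ages, t, _DEGREE, extrapolate=False).toarray()
    # guard against rank deficiency on the observed ages
    rank = np.linalg.matrix_rank(
        BSpline.design_matrix(distinct, t, _DEGREE, extrapolate=False).toarray()
    )
    while rank < len(t) - _DEGREE - 1 and n_knots > 0:
        warnings.warn(
            f"basis rank-deficient on observed ages; reducing knots to {n_knots - 1}",
            stacklevel=2,
        )
        n_knots -= 1
        return build_spline_basis(ages, n_knots)
    return SplineBasis(
        knot_locations=interior,
        knots_full=t,
        basis_matrix=design,
        ages=ages,
        n_knots=n_knots,
    )


@dataclass(frozen=True)
class GamPriorSpec:
    """Hyperprior scales for the spline GAM (all half-normal)."""

    ridge_scale: float = 3.0
    plate_intercept_scale: float = 1.0
    plate_slope_scale: float = 0.5

    def __post_init__(self) -> None:
        if min(self.ridge_scale, self.plate_intercept_scale, self.plate_slope_scale) <= 0:
            raise ValueError("prior scales must be > 0")


@dataclass
class SettlementCurve:
    """Pointwise posterior summary of one cue's settlement-vs-age curve."""

    cue: str
    age_grid: np.ndarray
    median: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


@dataclass
class AUCPosterior:
    """Posterior of the area under one cue's settlement curve."""

    cue: str
    areas: np.ndarray  # one value per retained draw, proportion x days
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.size == 0:
            raise ValueError("empty AUC posterior")


def _build_model(
    observations: pd.DataFrame, n_knots: int, prior_spec: GamPriorSpec
) -> dict:
    """Assemble the unconstrained log posterior and gradient for the sampler.

    Parameter layout: non-centred spline weights per cue (C x K), log ridge
    SD, then with >=2 plates the non-centred plate intercept and slope
    deviations and their two log SDs.
    """
    obs = observations.reset_index(drop=True)
    if obs["age_days"].nunique() < 3:
        raise ValueError("GAM requires observations spanning at least 3 timepoints")
    cues = sorted(obs["cue"].unique())
    plates = sorted(obs["plate_id"].unique())
    use_plates = len(plates) >= 2
    if not use_plates:
        warnings.warn("single plate: dropping plate-level varying effects", stacklevel=2)

    ages = obs["age_days"].to_numpy(dtype=float)
    basis = build_spline_basis(ages, n_knots)
    B = basis.basis_matrix
    K = basis.n_basis
    C = len(cues)
    P = len(plates) if use_plates else 0
    cue_idx = obs["cue"].map({c: i for i, c in enumerate(cues)}).to_numpy()
    plate_idx = (
        obs["plate_id"].map({p: i for i, p in enumerate(plates)}).to_numpy()
        if use_plates
        else None
    )
    n = obs["n_larvae"].to_numpy(dtype=float)
    y = obs["n_settled"].to_numpy(dtype=float)
    center = float(ages.mean())
    x = ages - center
    cue_rows = [np.flatnonzero(cue_idx == c) for c in range(C)]

    # parameters: w (C*K non-centred), zu (P), zv (P), log tau, log su, log sv
    dim = C * K + (2 * P + 2 if use_plates else 0) + 1
    rs2 = prior_spec.ridge_scale**2
    pu2 = prior_spec.plate_intercept_scale**2
    pv2 = prior_spec.plate_slope_scale**2

    def logp_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        w = q[: C * K].reshape(C, K)
        lt = q[C * K]
        tau = np.exp(lt)
        theta = tau * w
        eta = np.einsum("ik,ik->i", B, theta[cue_idx])
        if use_plates:
            zu = q[C * K + 1 : C * K + 1 + P]
            zv = q[C * K + 1 + P : C * K + 1 + 2 * P]
            lsu, lsv = q[-2], q[-1]
            su, sv = np.exp(lsu), np.exp(lsv)
            eta = eta + su * zu[plate_idx] + sv * zv[plate_idx] * x
        lp = float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))
        resid = y - n * expit(eta)
        grad = np.empty(dim)
        gw = np.zeros((C, K))
        smooth_dot = 0.0
        for c in range(C):
            rows = cue_rows[c]
            gc = B[rows].T @ resid[rows]
            gw[c] = tau * gc - w[c]
            smooth_dot += float(gc @ w[c])
        lp += float(-0.5 * np.sum(w * w))
        lp += -0.5 * tau**2 / rs2 + lt
        grad[: C * K] = gw.reshape(-1)
        grad[C * K] = tau * smooth_dot - tau**2 / rs2 + 1.0
        if use_plates:
            lp += float(-0.5 * np.sum(zu * zu) - 0.5 * np.sum(zv * zv))
            lp += -0.5 * su**2 / pu2 + lsu
            lp += -0.5 * sv**2 / pv2 + lsv
            grad[C * K + 1 : C * K + 1 + P] = (
                su * np.bincount(plate_idx, weights=resid, minlength=P) - zu
            )
            grad[C * K + 1 + P : C * K + 1 + 2 * P] = (
                sv * np.bincount(plate_idx, weights=resid * x, minlength=P) - zv
            )
            grad[-2] = su * float(np.sum(resid * zu[plate_idx])) - su**2 / pu2 + 1.0
            grad[-1] = (
                sv * float(np.sum(resid * x * zv[plate_idx])) - sv**2 / pv2 + 1.0
            )
        return lp, grad

    return {
        "logp_grad": logp_grad,
        "dim": dim,
        "cues": cues,
        "plates": plates,
        "use_plates": use_plates,
        "basis": basis,
        "age_center": center,
        "K": K,
        "C": C,
        "P": P,
    }


def fit_settlement_gam(
    observations: pd.DataFrame,
    n_knots: int = MAX_KNOTS,
    config: SamplerConfig = SamplerConfig(),
    prior_spec: GamPriorSpec = GamPriorSpec(),
) -> PosteriorDraws:
    """Sample the binomial spline GAM; returns natural-scale coefficient draws.

    Reported parameters: ``theta[cue][k]`` spline coefficients,
    plate deviations ``plate_u``/``plate_v`` (when >=2 plates), and the
    hyper-SDs ``tau_ridge``, ``sigma_plate_int``, ``sigma_plate_slope``.
    """
    model = _build_model(observations, n_knots, prior_spec)
    cues, plates = model["cues"], model["plates"]
    use_plates = model["use_plates"]
    basis, K, C, P = model["basis"], model["K"], model["C"], model["P"]
    center = model["age_center"]

    draws, stats = mcmc.run_nuts(model["logp_grad"], np.zeros(model["dim"]), config)

    # transform to natural scale for reporting
    nc, nr, _ = draws.shape
    tau = np.exp(draws[:, :, C * K])
    out_cols = [tau[:, :, None] * draws[:, :, : C * K], tau[:, :, None]]
    names = [f"theta[{c}][{k}]" for c in cues for k in range(K)] + ["tau_ridge"]
    if use_plates:
        su = np.exp(draws[:, :, -2])
        sv = np.exp(draws[:, :, -1])
        zu = draws[:, :, C * K + 1 : C * K + 1 + P]
        zv = draws[:, :, C * K + 1 + P : C * K + 1 + 2 * P]
        out_cols += [su[:, :, None] * zu, sv[:, :, None] * zv, su[:, :, None], sv[:, :, None]]
        names += (
            [f"plate_u[{p}]" for p in plates]
            + [f"plate_v[{p}]" for p in plates]
            + ["sigma_plate_int", "sigma_plate_slope"]
        )
    out = np.concatenate(out_cols, axis=2)
    return PosteriorDraws(
        parameter_names=names,
        draws=out,
        model_tag="settlement-gam",
        meta={
            "cues": cues,
            "plates": plates,
            "basis": basis,
            "age_center": center,
            "n_basis": K,
            "sampler_stats": stats,
            "prior_spec": prior_spec,
        },
    )


def _cue_theta(draws: PosteriorDraws, cue: str) -> np.ndarray:
    """(n_draws, K) spline coefficients for one cue, flattened over chains."""
    K = draws.meta["n_basis"]
    if cue not in draws.meta["cues"]:
        raise KeyError(f"cue {cue!r} not in fitted model: {draws.meta['cues']}")
    cols = [draws.index(f"theta[{cue}][{k}]") for k in range(K)]
    return draws.draws[:, :, cols].reshape(-1, K)


def curve_from_draws(
    draws: PosteriorDraws, cue: str, age_grid: Sequence[float]
) -> SettlementCurve:
    """Population-level settlement curve for one cue with 95% credible ribbon.

    Plate effects are marginalized at zero; the grid must lie inside the
    observed age range (extrapolation is refused by the basis).
    """
    basis: SplineBasis = draws.meta["basis"]
    grid = np.asarray(age_grid, dtype=float)
    Bg = basis.evaluate(grid)
    theta = _cue_theta(draws, cue)
    p = expit(theta @ Bg.T)  # (n_draws, n_grid)
    return SettlementCurve(
        cue=cue,
        age_grid=grid,
        median=np.quantile(p, 0.5, axis=0),
        ci_lower=np.quantile(p, 0.025, axis=0),
        ci_upper=np.quantile(p, 0.975, axis=0),
    )


def auc_per_draw(
    draws: PosteriorDraws,
    cue: str,
    age_range: tuple[float, float] | None = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> AUCPosterior:
    """Trapezoidal area under the response-scale curve, one value per draw."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    basis: SplineBasis = draws.meta["basis"]
    lo, hi = age_range if age_range is not None else (basis.age_min, basis.age_max)
    grid = np.linspace(lo, hi, resolution)
    Bg = basis.evaluate(grid)
    theta = _cue_theta(draws, cue)
    p = expit(theta @ Bg.T)
    areas = np.trapezoid(p, grid, axis=1)  # same rule as trapezoid_auc, batched
    return AUCPosterior(cue=cue, areas=areas, resolution=resolution)


def rank_cues(
    auc_posteriors: Mapping[str, AUCPosterior] | Mapping[str, np.ndarray],
    cutoff: float = 0.95,
) -> CueRanking:
    """Rank cues strongest-to-weakest by posterior AUC with exceedance grouping.

    Cues are sorted by median area; adjacent cues whose pairwise exceedance
    falls below ``cutoff`` are joined into an equivalence group with ``=``
    (chained transitively), otherwise separated by ``>``.
    """
    areas: dict[str, np.ndarray] = {}
    for cue, v in auc_posteriors.items():
        areas[cue] = np.asarray(v.areas if isinstance(v, AUCPosterior) else v, float)
    if len(areas) < 2:
        raise ValueError("need at least 2 cues to rank")
    order = sorted(areas, key=lambda c: -float(np.median(areas[c])))
    exc = pairwise_exceedance(areas, direction="greater")
    groups: list[list[str]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if float(exc.loc[prev, cur]) >= cutoff:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    display = " > ".join(" = ".join(g) for g in groups)
    return CueRanking(
        ordered_groups=[frozenset(g) for g in groups],
        display=display,
        exceedance_cutoff=cutoff,
    )
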