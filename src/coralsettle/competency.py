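"""Cohort competency binarization and Bayesian logistic TC50 estimation.

Settlement counts are collapsed to a per-well binary competency outcome at a
settlement threshold (default 0.3), then modelled as

    competent ~ Bernoulli(logistic(alpha_cue + beta_cue * age))

with weakly-informative normal priors (intercepts N(0,5), age slopes
N(0,2.5) after centring age) and, when a species has two or more cohorts, a
non-centred cohort-level intercept deviation with a half-normal SD prior.
TC50 for a cue is the per-draw root of the linear predictor, -alpha/beta,
summarized by its posterior median and central 95% interval; draws with a
non-positive slope never cross 0.5 and map to +infinity, surfacing as the
truncation flag rather than an invented value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import mcmc
from .datatypes import PosteriorDraws, SamplerConfig, TC50Estimate

__all__ = [
    "PriorSpec",
    "binarize_competency",
    "competency_log_posterior",
    "fit_competency_model",
    "tc50_from_draws",
    "tc50_draws",
    "threshold_sweep",
    "cue_tc50_contrasts",
    "pairwise_exceedance",
    "convergence_diagnostics",
    "DEFAULT_THRESHOLD",
    "THRESHOLD_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.3
THRESHOLD_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))

COMPETENCY_COLUMNS = (
    "species_id",
    "cohort_id",
    "age_days",
    "cue",
    "plate_id",
    "well_id",
    "competent",
)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative prior scales for the logistic competency model."""

    intercept_sd: float = 5.0
    slope_sd: float = 2.5
    cohort_sd_scale: float = 2.0

    def __post_init__(self) -> None:
        if min(self.intercept_sd, self.slope_sd, self.cohort_sd_scale) <= 0:
            raise ValueError("prior scales must be > 0")


def binarize_competency(
    observations: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Collapse settled counts to a binary competency outcome per well.

    ``competent`` is 1 when the settled proportion reaches the threshold
    (``>=`` by default; set ``inclusive=False`` for a strict ``>``). Wells
    with zero larvae cannot be scored and are dropped with a warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    obs = observations.copy()
    empty = obs["n_larvae"] < 1
    if empty.any():
        logger.warning(
            "dropping %d assay rows with n_larvae < 1 (rows %s)",
            int(empty.sum()),
            list(obs.index[empty]),
        )
        obs = obs[~empty]
    frac = obs["n_settled"] / obs["n_larvae"]
    competent = frac >= threshold if inclusive else frac > threshold
    out = obs[list(COMPETENCY_COLUMNS[:-1])].copy()
    out["competent"] = competent.astype(int)
    return out.reset_index(drop=True)


def competency_log_posterior(
    params: Mapping[str, tuple[float, float]],
    records: pd.DataFrame,
    prior_spec: PriorSpec | None = PriorSpec(),
) -> float:
    """Log posterior of cue-wise (alpha, beta) pairs given competency records.

    ``params`` maps each cue to its (intercept, age slope) on the raw age
    scale. Passing ``prior_spec=None`` returns the bare log likelihood.
    """
    total = 0.0
    for row in records.itertuples(index=False):
        if row.cue not in params:
            raise KeyError(f"no parameters supplied for cue {row.cue!r}")
        alpha, beta = params[row.cue]
        eta = alpha + beta * row.age_days
        # log Bernoulli pmf via numerically safe log-sigmoid
        total += eta * row.competent - np.logaddexp(0.0, eta)
    if prior_spec is not None:
        for alpha, beta in params.values():
            total += -0.5 * (alpha / prior_spec.intercept_sd) ** 2
            total += -0.5 * (beta / prior_spec.slope_sd) ** 2
    return float(total)


def _check_design(records: pd.DataFrame) -> None:
    for cue, grp in records.groupby("cue"):
        if grp["age_days"].nunique() < 2 or grp["competent"].nunique() < 2:
            warnings.warn(
                f"cue {cue!r}: fewer than 2 distinct ages with both outcomes; "
                "the age slope is weakly identified",
                stacklevel=3,
            )
            continue
        ages0 = grp.loc[grp["competent"] == 0, "age_days"]
        ages1 = grp.loc[grp["competent"] == 1, "age_days"]
        if len(ages0) and len(ages1) and ages0.max() < ages1.min():
            warnings.warn(
                f"cue {cue!r}: complete separation in age; "
                "the posterior is regularized by the priors",
                stacklevel=3,
            )


def _build_model(records: pd.DataFrame, prior_spec: PriorSpec) -> dict:
    """Assemble the unconstrained log-posterior-and-gradient for the sampler.

    Parameter vector layout: cue intercepts (centred age), cue slopes, then
    for multi-cohort data the non-centred cohort deviations and the log of
    their SD.
    """
    cues = sorted(records["cue"].unique())
    cohorts = sorted(records["cohort_id"].unique())
    hierarchical = len(cohorts) >= 2
    n_cues = len(cues)

    cue_idx = records["cue"].map({c: i for i, c in enumerate(cues)}).to_numpy()
    coh_idx = records["cohort_id"].map({c: i for i, c in enumerate(cohorts)}).to_numpy()
    age = records["age_days"].to_numpy(dtype=float)
    center = float(age.mean())
    x = age - center
    y = records["competent"].to_numpy(dtype=float)

    n_coh = len(cohorts)
    # parameter vector: [a_0..a_C-1, b_0..b_C-1, (z_0..z_J-1, log_sigma)]
    dim = 2 * n_cues + (n_coh + 1 if hierarchical else 0)
    sa2 = prior_spec.intercept_sd**2
    sb2 = prior_spec.slope_sd**2
    sc2 = prior_spec.cohort_sd_scale**2

    def logp_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        a = q[:n_cues]
        b = q[n_cues : 2 * n_cues]
        eta = a[cue_idx] + b[cue_idx] * x
        if hierarchical:
            z = q[2 * n_cues : 2 * n_cues + n_coh]
            ls = q[-1]
            sigma = np.exp(ls)
            eta = eta + sigma * z[coh_idx]
        lp = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        resid = y - expit(eta)
        grad = np.empty(dim)
        grad[:n_cues] = np.bincount(cue_idx, weights=resid, minlength=n_cues)
        grad[n_cues : 2 * n_cues] = np.bincount(
            cue_idx, weights=resid * x, minlength=n_cues
        )
        lp += float(-0.5 * np.sum(a * a) / sa2 - 0.5 * np.sum(b * b) / sb2)
        grad[:n_cues] -= a / sa2
        grad[n_cues : 2 * n_cues] -= b / sb2
        if hierarchical:
            lp += float(-0.5 * np.sum(z * z))
            lp += -0.5 * sigma**2 / sc2 + ls  # half-normal on sigma + Jacobian
            grad[2 * n_cues : 2 * n_cues + n_coh] = (
                sigma * np.bincount(coh_idx, weights=resid, minlength=n_coh) - z
            )
            grad[-1] = (
                sigma * float(np.sum(resid * z[coh_idx])) - sigma**2 / sc2 + 1.0
            )
        return lp, grad

    return {
        "logp_grad": logp_grad,
        "dim": dim,
        "cues": cues,
        "cohorts": cohorts,
        "hierarchical": hierarchical,
        "age_center": center,
        "max_age": float(age.max()),
    }


def fit_competency_model(
    records: pd.DataFrame,
    config: SamplerConfig = SamplerConfig(),
    prior_spec: PriorSpec = PriorSpec(),
) -> PosteriorDraws:
    """Sample the hierarchical logistic competency model with NUTS.

    Returns draws of ``alpha[cue]`` and ``beta[cue]`` on the raw
    (uncentred) age scale, plus ``cohort_sd`` and per-cohort deviations
    when the records span two or more cohorts.
    """
    records = records.reset_index(drop=True)
    _check_design(records)
    model = _build_model(records, prior_spec)
    cues = model["cues"]
    cohorts = model["cohorts"]
    hierarchical = model["hierarchical"]
    n_cues = len(cues)
    center = model["age_center"]

    draws, stats = mcmc.run_nuts(model["logp_grad"], np.zeros(model["dim"]), config)

    # report on the raw age scale: alpha_raw = a - b * center
    out = draws.copy()
    out[:, :, :n_cues] = draws[:, :, :n_cues] - draws[:, :, n_cues : 2 * n_cues] * center
    names = [f"alpha[{c}]" for c in cues] + [f"beta[{c}]" for c in cues]
    if hierarchical:
        out[:, :, -1] = np.exp(draws[:, :, -1])  # report sigma, not log sigma
        names += [f"cohort_offset_z[{c}]" for c in cohorts] + ["cohort_sd"]
    return PosteriorDraws(
        parameter_names=names,
        draws=out,
        model_tag="competency-logistic",
        meta={
            "cues": cues,
            "cohorts": cohorts,
            "age_center": center,
            "max_age": model["max_age"],
            "sampler_stats": stats,
            "prior_spec": prior_spec,
        },
    )


def tc50_draws(draws: PosteriorDraws, cue: str) -> np.ndarray:
    """Per-draw TC50 for one cue; draws with beta <= 0 map to +inf."""
    alpha = draws.extract(f"alpha[{cue}]")
    beta = draws.extract(f"beta[{cue}]")
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(beta > 0, -alpha / beta, np.inf)
    return tc


def tc50_from_draws(
    draws: PosteriorDraws,
    cue: str,
    max_age: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> TC50Estimate:
    """Posterior median and 95% credible interval of TC50 for one cue.

    The truncation flag marks medians beyond the experimental extent
    (``max_age``), including the all-draws-non-increasing case where every
    per-draw TC50 is +inf.
    """
    tc = tc50_draws(draws, cue)
    med = _inf_safe_quantile(tc, 0.5)
    lo = _inf_safe_quantile(tc, 0.025)
    hi = _inf_safe_quantile(tc, 0.975)
    truncated = (not np.isfinite(med)) or med > max_age
    species = _single_species_tag(draws)
    return TC50Estimate(
        species_id=species,
        cue=cue,
        threshold=threshold,
        tc50_median=med,
        ci_lower=lo,
        ci_upper=hi,
        truncated=truncated,
    )


def _inf_safe_quantile(values: np.ndarray, q: float) -> float:
    """Quantile that returns +inf (not NaN) when interpolating between infinities."""
    with np.errstate(invalid="ignore"):
        out = float(np.quantile(values, q))
    if np.isnan(out) and np.isinf(values).any():
        return float("inf")
    return out


def _single_species_tag(draws: PosteriorDraws) -> str:
    return str(draws.meta.get("species_id", "unknown"))


def threshold_sweep(
    observations: pd.DataFrame,
    thresholds: Sequence[float] = THRESHOLD_GRID,
    config: SamplerConfig = SamplerConfig(),
    prior_spec: PriorSpec = PriorSpec(),
    control_cue: str = "control",
) -> list[TC50Estimate]:
    """Re-binarize and refit at each settlement threshold.

    Produces one estimate per threshold x cue plus a ``best`` pseudo-cue:
    the non-control cue with the earliest posterior median at that
    threshold. Per-threshold seeds are derived from ``config.seed`` so the
    grid can be reordered or subset without changing any single fit.
    """
    for t in thresholds:
        if not any(abs(t - g) < 1e-9 for g in THRESHOLD_GRID):
            raise ValueError(f"threshold {t} outside the supported grid {THRESHOLD_GRID}")
    species = str(observations["species_id"].iloc[0])
    max_age = float(observations["age_days"].max())
    estimates: list[TC50Estimate] = []
    for t in thresholds:
        sub_seed = int(
            np.random.SeedSequence((config.seed, int(round(t * 10)))).generate_state(1)[0]
        )
        cfg = SamplerConfig(
            n_chains=config.n_chains,
            n_iterations=config.n_iterations,
            warmup=config.warmup,
            thin=config.thin,
            seed=sub_seed,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        )
        records = binarize_competency(observations, threshold=t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate thresholds are expected here
            draws = fit_competency_model(records, cfg, prior_spec)
        draws.meta["species_id"] = species
        per_cue = [
            tc50_from_draws(draws, cue, max_age, threshold=t)
            for cue in draws.meta["cues"]
        ]
        estimates.extend(per_cue)
        candidates = [e for e in per_cue if e.cue != control_cue]
        if candidates:
            best = min(candidates, key=lambda e: e.tc50_median)
            estimates.append(
                TC50Estimate(
                    species_id=species,
                    cue=f"best[{best.cue}]",
                    threshold=t,
                    tc50_median=best.tc50_median,
                    ci_lower=best.ci_lower,
                    ci_upper=best.ci_upper,
                    truncated=best.truncated,
                )
            )
    return estimates


def pairwise_exceedance(
    samples: Mapping[str, np.ndarray], direction: str = "less"
) -> pd.DataFrame:
    """Matrix of P(sample_A <op> sample_B) over paired draws, ties counted 0.5.

    ``direction="less"`` asks "is A smaller" (earlier TC50 is better);
    ``direction="greater"`` asks "is A larger" (bigger AUC is better).
    Complementarity M[A,B] + M[B,A] = 1 holds exactly under the tie rule.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    labels = list(samples)
    lengths = {k: len(np.asarray(v)) for k, v in samples.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"mismatched draw counts: {lengths}")
    mat = np.full((len(labels), len(labels)), 0.5)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            va = np.asarray(samples[a], dtype=float)
            vb = np.asarray(samples[b], dtype=float)
            if direction == "less":
                p = np.mean((va < vb) + 0.5 * (va == vb))
            else:
                p = np.mean((va > vb) + 0.5 * (va == vb))
            mat[i, j] = p
            mat[j, i] = 1.0 - p
    return pd.DataFrame(mat, index=labels, columns=labels)


def cue_tc50_contrasts(tc50_samples: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Exceedance matrix over cues: entry (A, B) = P(TC50_A earlier than TC50_B)."""
    if len(tc50_samples) < 2:
        raise ValueError("need at least 2 cues for contrasts")
    return pairwise_exceedance(tc50_samples, direction="less")


def convergence_diagnostics(
    draws: PosteriorDraws, rhat_max: float = 1.01, ess_min: float = 400.0
) -> mcmc.DiagnosticsReport:
    """Split R-hat and effective sample size per parameter with a pass flag."""
    return mcmc.diagnose(draws, rhat_max=rhat_max, ess_min=ess_min)
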