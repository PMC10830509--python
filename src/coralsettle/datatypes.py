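"""Shared record types for the settlement-competency pipeline.

Plain dataclasses; tabular collections of these records move through the
pipeline as pandas DataFrames with canonical column names (see
:data:`ASSAY_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Canonical column order for assay observation tables (CSV and DataFrame).
ASSAY_COLUMNS = (
    "species_id",
    "cohort_id",
    "age_days",
    "cue",
    "plate_id",
    "well_id",
    "n_larvae",
    "n_settled",
)

#: Label used for the filtered-seawater negative control throughout.
CONTROL_CUE = "control"


@dataclass(frozen=True)
class AssayObservation:
    """One well at one assay timepoint: settled count out of loaded larvae."""

    species_id: str
    cohort_id: str
    age_days: float
    cue: str
    plate_id: str
    well_id: str
    n_larvae: int
    n_settled: int

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise ValueError(f"age_days must be >= 0, got {self.age_days}")
        if not (0 <= self.n_settled <= self.n_larvae):
            raise ValueError(
                f"n_settled must satisfy 0 <= n_settled <= n_larvae, got "
                f"{self.n_settled}/{self.n_larvae}"
            )


@dataclass(frozen=True)
class TemporalMode:
    """One Gaussian activity bump multiplying the latent settlement curve."""

    center: float  # days
    width: float  # days (> 0)
    amplitude: float  # unitless, >= -1 so the envelope stays non-negative

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("temporal mode width must be > 0")


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth generating parameters for one synthetic species."""

    species_id: str
    onset_age_tc50_true: float  # days, latent age at 50% cohort competency
    onset_slope_true: float  # logit-units per day, > 0
    cue_effects: Mapping[str, float]  # cue -> additive logit shift
    asymptote: float = 1.0  # max settlement proportion, in (0, 1]
    temporal_modes: Sequence[TemporalMode] = ()
    plate_sd: float = 0.0  # logit-scale SD of plate intercepts
    plate_slope_sd: float = 0.0  # logit-scale SD of plate-by-age deviations

    def __post_init__(self) -> None:
        if self.onset_slope_true <= 0:
            raise ValueError("onset_slope_true must be > 0")
        if not (0.0 < self.asymptote <= 1.0):
            raise ValueError("asymptote must be in (0, 1]")
        if self.plate_sd < 0 or self.plate_slope_sd < 0:
            raise ValueError("plate SDs must be >= 0")
        if CONTROL_CUE not in self.cue_effects:
            raise ValueError(
                f"cue_effects must include a {CONTROL_CUE!r} cue"
            )


@dataclass(frozen=True)
class AssayDesign:
    """Layout of a repeated settlement assay: who gets tested when."""

    timepoints: Sequence[float]  # ages in days after fertilization
    cues: Sequence[str]
    wells_per_treatment: int = 6
    larvae_per_well: int = 10
    poisson_larvae: bool = False  # jitter larvae counts around the nominal

    def __post_init__(self) -> None:
        ages = list(self.timepoints)
        if any(a < 0 for a in ages):
            raise ValueError("timepoints must be >= 0")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.wells_per_treatment < 1 or self.larvae_per_well < 1:
            raise ValueError("counts must be >= 1")
        if not self.cues:
            raise ValueError("at least one cue is required")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; defaults follow the published sampler configuration."""

    n_chains: int = 3
    n_iterations: int = 6000
    warmup: int = 2000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.warmup < self.n_iterations):
            raise ValueError("need 0 < warmup < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain after warmup and thinning."""
        return (self.n_iterations - self.warmup) // self.thin


@dataclass
class PosteriorDraws:
    """Labelled MCMC output: draws indexed (chain, retained iteration, parameter)."""

    parameter_names: Sequence[str]
    draws: np.ndarray  # shape (n_chains, n_retained, n_parameters)
    model_tag: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must have shape (chain, iteration, parameter)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names length must match draws last axis")
        if not np.isfinite(self.draws).all():
            raise ValueError("posterior draws contain non-finite values")

    def index(self, name: str) -> int:
        try:
            return list(self.parameter_names).index(name)
        except ValueError:
            raise KeyError(f"parameter {name!r} not in posterior") from None

    def extract(self, name: str) -> np.ndarray:
        """All draws of one parameter, flattened across chains."""
        return self.draws[:, :, self.index(name)].reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]


@dataclass(frozen=True)
class TC50Estimate:
    """Posterior summary of age-to-competency for one species x cue x threshold."""

    species_id: str
    cue: str
    threshold: float
    tc50_median: float
    ci_lower: float
    ci_upper: float
    truncated: bool


@dataclass(frozen=True)
class CueRanking:
    """Partial order over cues: earlier group = stronger inducer."""

    ordered_groups: Sequence[frozenset]
    display: str
    exceedance_cutoff: float

    def __post_init__(self) -> None:
        seen: set = set()
        for group in self.ordered_groups:
            if seen & set(group):
                raise ValueError("a cue appears in more than one ranking group")
            seen |= set(group)


@dataclass(frozen=True)
class SpeciesSummaryRow:
    """One species in the cross-species summary table."""

    species_id: str
    family: str
    species: str
    tc50: float
    ci_lower: float
    ci_upper: float
    best_cue: str
    precompetency_class: str
    oocyte_diameter_um: float

    def __post_init__(self) -> None:
        if self.tc50 <= 0:
            raise ValueError("tc50 must be > 0")


@dataclass(frozen=True)
class DispersalCurve:
    """Competency and exponential survival through age, and their product."""

    age_grid: np.ndarray
    competency: np.ndarray
    survival: np.ndarray
    product: np.ndarray
    decay_rate: float
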