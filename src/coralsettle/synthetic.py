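"""Synthetic settlement-assay generation with known ground truth.

The latent settlement probability for a species is

    p(age, cue) = asymptote * clip01( logistic(slope * (age - onset) + shift)
                                      * (1 + sum of Gaussian bumps) )

where ``shift`` is the cue-specific logit offset (0 for the strongest
baseline interpretation: the control carries a negative shift so induced
cues sit above it). Plate dependency enters at simulation time as a random
intercept plus a random age slope on the logit scale, drawn once per plate.

Also houses the packaged 21-species summary table used by the downstream
summary statistics.
"""

from __future__ import annotations

import importlib.resources
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ASSAY_COLUMNS,
    AssayDesign,
    SpeciesProfile,
    SpeciesSummaryRow,
)

__all__ = [
    "true_settlement_probability",
    "true_cohort_tc50",
    "simulate_assays",
    "table1_fixture",
    "default_profile",
]


def _logistic(x):
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def true_settlement_probability(
    profile: SpeciesProfile, age: float, cue: str
) -> float:
    """Latent per-larva settlement probability at ``age`` under ``cue``.

    Monotone non-decreasing in age when the profile carries no temporal
    modes; never exceeds the profile asymptote and never goes negative.
    """
    age = float(age)
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    try:
        shift = profile.cue_effects[cue]
    except KeyError:
        raise KeyError(
            f"unknown cue {cue!r}; profile defines "
            f"{sorted(profile.cue_effects)}"
        ) from None
    onset = _logistic(
        profile.onset_slope_true * (age - profile.onset_age_tc50_true) + shift
    )
    envelope = 1.0
    for mode in profile.temporal_modes:
        envelope += mode.amplitude * np.exp(
            -0.5 * ((age - mode.center) / mode.width) ** 2
        )
    p = float(np.clip(onset * envelope, 0.0, 1.0)) * profile.asymptote
    return p


def simulate_assays(
    profile: SpeciesProfile,
    design: AssayDesign,
    seed: int,
    cohort_id: str = "c1",
) -> pd.DataFrame:
    """Simulate one cohort's repeated assays; returns an observation table.

    One row per well per timepoint. Wells are grouped into six-well plates
    within each timepoint (mirroring six-well culture plates); each plate
    receives a logit-scale intercept and age-slope deviation drawn once.
    Identical arguments and seed give byte-identical tables.
    """
    rng = np.random.default_rng(seed)
    rows = []
    wells_per_plate = 6
    n_wells_tp = len(design.cues) * design.wells_per_treatment
    n_plates_tp = -(-n_wells_tp // wells_per_plate)

    for t_idx, age in enumerate(design.timepoints):
        # fresh plates each timepoint: assays are independent 24-h runs
        intercepts = rng.normal(0.0, profile.plate_sd, size=n_plates_tp)
        slopes = rng.normal(0.0, profile.plate_slope_sd, size=n_plates_tp)
        well_counter = 0
        for cue in design.cues:
            p_true = true_settlement_probability(profile, age, cue)
            for rep in range(design.wells_per_treatment):
                plate_idx = well_counter // wells_per_plate
                if design.poisson_larvae:
                    n_larvae = max(1, int(rng.poisson(design.larvae_per_well)))
                else:
                    n_larvae = design.larvae_per_well
                # plate deviation acts on the logit of the latent p
                if profile.plate_sd > 0 or profile.plate_slope_sd > 0:
                    eta = _logit_clipped(p_true) + intercepts[plate_idx]
                    eta += slopes[plate_idx] * (age - np.mean(design.timepoints))
                    p = float(_logistic(eta))
                else:
                    p = p_true
                n_settled = int(rng.binomial(n_larvae, p))
                rows.append(
                    (
                        profile.species_id,
                        cohort_id,
                        float(age),
                        cue,
                        f"t{t_idx}_p{plate_idx}",
                        f"t{t_idx}_w{well_counter}",
                        n_larvae,
                        n_settled,
                    )
                )
                well_counter += 1
    return pd.DataFrame(rows, columns=list(ASSAY_COLUMNS))


def true_cohort_tc50(
    profile: SpeciesProfile,
    cue: str,
    n_larvae: int = 10,
    threshold: float = 0.3,
    inclusive: bool = True,
    max_search_age: float = 1000.0,
) -> float:
    """Ground-truth cohort-level TC50 implied by the generating profile.

    The cohort competency outcome is a thresholded binomial, so the age at
    which a well is as likely competent as not solves

        P( Binomial(n_larvae, p_true(age)) >= ceil(threshold * n) ) = 0.5.

    Only defined for monotone profiles (no temporal modes). This is the
    correct recovery target for the binarized model: it differs from the
    latent per-larva onset age by the binomial thresholding.
    """
    from math import ceil, floor

    from scipy.optimize import brentq
    from scipy.stats import binom

    if profile.temporal_modes:
        raise ValueError("cohort TC50 is only defined for monotone profiles")
    k = ceil(threshold * n_larvae) if inclusive else floor(threshold * n_larvae) + 1

    def half_prob(age: float) -> float:
        p = true_settlement_probability(profile, age, cue)
        return float(binom.sf(k - 1, n_larvae, p)) - 0.5

    if half_prob(0.0) >= 0:
        return 0.0
    if half_prob(max_search_age) <= 0:
        raise ValueError(
            "cohort competency probability never reaches 0.5; "
            "check asymptote and threshold"
        )
    return float(brentq(half_prob, 0.0, max_search_age, xtol=1e-10))


def _logit_clipped(p: float, eps: float = 1e-9) -> float:
    p = min(max(p, eps), 1.0 - eps)
    return float(np.log(p / (1.0 - p)))


def default_profile(
    species_id: str = "synthetic",
    onset: float = 4.0,
    slope: float = 1.5,
    cues: Sequence[str] = ("control", "cca", "extract", "peptide", "disc", "rubble"),
    control_shift: float = -3.0,
    induced_shift: float = 0.0,
    **kwargs,
) -> SpeciesProfile:
    """A profile mirroring the nominal assay design: one control plus inducers.

    The control gets a small non-zero settlement baseline (spontaneous
    settlement occurs but is rare), induced cues share ``induced_shift``
    unless overridden via ``cue_effects`` in ``kwargs``.
    """
    effects = kwargs.pop(
        "cue_effects",
        {c: (control_shift if c == "control" else induced_shift) for c in cues},
    )
    return SpeciesProfile(
        species_id=species_id,
        onset_age_tc50_true=onset,
        onset_slope_true=slope,
        cue_effects=effects,
        **kwargs,
    )


def table1_fixture() -> list[SpeciesSummaryRow]:
    """The packaged 21-species competency summary table, exactly as printed."""
    df = table1_frame()
    return [
        SpeciesSummaryRow(
            species_id=r.species_id,
            family=r.family,
            species=r.species,
            tc50=r.tc50,
            ci_lower=r.ci_lower,
            ci_upper=r.ci_upper,
            best_cue=r.best_cue,
            precompetency_class=r.precompetency_class,
            oocyte_diameter_um=r.oocyte_diameter_um,
        )
        for r in df.itertuples(index=False)
    ]


def table1_frame() -> pd.DataFrame:
    """The packaged species table as a DataFrame (one row per species)."""
    resource = importlib.resources.files("coralsettle.data") / "table1.csv"
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path)
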