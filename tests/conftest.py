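import numpy as np
import pytest

from coralsettle.datatypes import AssayDesign, SamplerConfig, SpeciesProfile
from coralsettle.synthetic import default_profile, simulate_assays


@pytest.fixture
def simple_profile() -> SpeciesProfile:
    """Monotone two-cue profile with a rare spontaneous control baseline."""
    return default_profile(
        species_id="sp1",
        onset=4.0,
        slope=1.5,
        cues=("control", "rubble"),
        cue_effects={"control": -3.0, "rubble": 0.0},
    )


@pytest.fixture
def six_cue_profile() -> SpeciesProfile:
    """Full nominal design: control plus five inducers with distinct shifts."""
    return default_profile(
        species_id="sp6",
        onset=4.0,
        slope=1.5,
        cue_effects={
            "control": -3.0,
            "cca": 0.5,
            "extract": -0.5,
            "peptide": 0.0,
            "disc": 0.25,
            "rubble": 1.0,
        },
    )


@pytest.fixture
def dense_design() -> AssayDesign:
    return AssayDesign(
        timepoints=[2, 3, 4, 5, 6, 8, 10], cues=("control", "rubble")
    )


@pytest.fixture
def fast_sampler() -> SamplerConfig:
    """Short chains for unit tests; thinning keeps draws nearly independent."""
    return SamplerConfig(n_chains=2, n_iterations=700, warmup=300, thin=2, seed=123)


@pytest.fixture
def two_cue_observations(simple_profile, dense_design):
    return simulate_assays(simple_profile, dense_design, seed=42)


@pytest.fixture
def point_mass_draws():
    """Factory for degenerate posteriors used in closed-form checks."""

    def make(names, values, n_chains=2, n_draws=50, meta=None):
        values = np.asarray(values, dtype=float)
        draws = np.tile(values, (n_chains, n_draws, 1))
        from coralsettle.datatypes import PosteriorDraws

        return PosteriorDraws(
            parameter_names=list(names),
            draws=draws,
            model_tag="test",
            meta=meta or {},
        )

    return make
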