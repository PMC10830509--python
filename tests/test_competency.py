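import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import bernoulli

from coralsettle import competency as cm
from coralsettle.datatypes import SamplerConfig
from coralsettle.synthetic import default_profile, simulate_assays
from coralsettle.datatypes import AssayDesign


def make_obs(rows):
    cols = ["species_id", "cohort_id", "age_days", "cue", "plate_id", "well_id",
            "n_larvae", "n_settled"]
    return pd.DataFrame(rows, columns=cols)


class TestBinarize:
    def test_boundary_inclusive(self):
        obs = make_obs([("s", "c", 4.0, "rubble", "p1", "w1", 10, 3)])
        out = cm.binarize_competency(obs, 0.3)
        assert out.loc[0, "competent"] == 1

    def test_strict_mode(self):
        obs = make_obs([("s", "c", 4.0, "rubble", "p1", "w1", 10, 3)])
        out = cm.binarize_competency(obs, 0.3, inclusive=False)
        assert out.loc[0, "competent"] == 0

    def test_zero_settled(self):
        obs = make_obs([("s", "c", 4.0, "rubble", "p1", "w1", 10, 0)])
        assert cm.binarize_competency(obs, 0.05).loc[0, "competent"] == 0

    def test_two_of_nine_below_threshold(self):
        obs = make_obs([("s", "c", 4.0, "rubble", "p1", "w1", 9, 2)])
        assert cm.binarize_competency(obs, 0.3).loc[0, "competent"] == 0

    def test_empty_well_rejected_with_warning(self, caplog):
        obs = make_obs([
            ("s", "c", 4.0, "rubble", "p1", "w1", 0, 0),
            ("s", "c", 4.0, "rubble", "p1", "w2", 10, 5),
        ])
        with caplog.at_level("WARNING"):
            out = cm.binarize_competency(obs, 0.3)
        assert len(out) == 1
        assert "n_larvae" in caplog.text

    def test_one_output_per_input(self, two_cue_observations):
        out = cm.binarize_competency(two_cue_observations, 0.3)
        assert len(out) == len(two_cue_observations)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_threshold(self, threshold):
        obs = make_obs([("s", "c", 4.0, "rubble", "p1", "w1", 10, 3)])
        with pytest.raises(ValueError):
            cm.binarize_competency(obs, threshold)


class TestLogPosterior:
    def test_single_record_eta_zero(self):
        recs = pd.DataFrame({"cue": ["a"], "age_days": [0.0], "competent": [1]})
        ll = cm.competency_log_posterior({"a": (0.0, 0.0)}, recs, prior_spec=None)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_symmetric_pair_maximized_at_zero(self):
        recs = pd.DataFrame({"cue": ["a", "a"], "age_days": [0.0, 0.0],
                             "competent": [1, 0]})
        at_zero = cm.competency_log_posterior({"a": (0.0, 0.0)}, recs, prior_spec=None)
        for alpha in (-1.0, -0.3, 0.4, 2.0):
            assert cm.competency_log_posterior({"a": (alpha, 0.0)}, recs,
                                               prior_spec=None) < at_zero
        assert at_zero == pytest.approx(2 * np.log(0.5))

    def test_brute_force_oracle_eight_records(self):
        rng = np.random.default_rng(11)
        cues = ["a", "b"]
        recs = pd.DataFrame({
            "cue": [cues[i % 2] for i in range(8)],
            "age_days": rng.uniform(1, 10, 8),
            "competent": rng.integers(0, 2, 8),
        })
        params = {"a": (-2.0, 0.7), "b": (0.5, -0.2)}
        # independent oracle: sum of scipy Bernoulli log-pmfs
        expected = 0.0
        for r in recs.itertuples(index=False):
            a, b = params[r.cue]
            expected += bernoulli.logpmf(r.competent, expit(a + b * r.age_days))
        got = cm.competency_log_posterior(params, recs, prior_spec=None)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_prior_contribution(self):
        recs = pd.DataFrame({"cue": ["a"], "age_days": [0.0], "competent": [1]})
        spec = cm.PriorSpec(intercept_sd=5.0, slope_sd=2.5)
        bare = cm.competency_log_posterior({"a": (1.0, 2.0)}, recs, prior_spec=None)
        full = cm.competency_log_posterior({"a": (1.0, 2.0)}, recs, prior_spec=spec)
        assert full == pytest.approx(bare - 0.5 * (1 / 25) - 0.5 * (4 / 6.25))

    def test_missing_cue_errors(self):
        recs = pd.DataFrame({"cue": ["mystery"], "age_days": [1.0], "competent": [0]})
        with pytest.raises(KeyError, match="mystery"):
            cm.competency_log_posterior({"a": (0.0, 0.0)}, recs)


class TestFit:
    def test_determinism(self, two_cue_observations, fast_sampler):
        recs = cm.binarize_competency(two_cue_observations, 0.3)
        d1 = cm.fit_competency_model(recs, fast_sampler)
        d2 = cm.fit_competency_model(recs, fast_sampler)
        assert np.array_equal(d1.draws, d2.draws)
        assert d1.parameter_names == d2.parameter_names

    def test_retained_draw_contract(self, two_cue_observations, fast_sampler):
        recs = cm.binarize_competency(two_cue_observations, 0.3)
        d = cm.fit_competency_model(recs, fast_sampler)
        assert d.draws.shape[0] == fast_sampler.n_chains
        assert d.draws.shape[1] == fast_sampler.n_retained

    def test_null_data_beta_ci_covers_zero(self, fast_sampler):
        # competency independent of age: a fair coin at every age
        rng = np.random.default_rng(21)
        rows = []
        for age in [2, 4, 6, 8, 10]:
            for w in range(12):
                rows.append(("s", "c", age, "rubble", "p", f"w{age}_{w}",
                             10, int(rng.integers(0, 2)) * 10))
        recs = cm.binarize_competency(make_obs(rows), 0.3)
        d = cm.fit_competency_model(recs, fast_sampler)
        beta = d.extract("beta[rubble]")
        lo, hi = np.quantile(beta, [0.025, 0.975])
        assert lo < 0 < hi

    def test_separation_warning(self, fast_sampler):
        rows = [("s", "c", a, "rubble", "p", f"w{a}", 10, 10 if a > 5 else 0)
                for a in [2, 3, 4, 7, 8, 9]]
        recs = cm.binarize_competency(make_obs(rows), 0.3)
        with pytest.warns(UserWarning, match="separation"):
            cm.fit_competency_model(recs, fast_sampler)

    def test_degenerate_design_warning(self, fast_sampler):
        rows = [("s", "c", 4.0, "rubble", "p", f"w{i}", 10, 10) for i in range(6)]
        rows += [("s", "c", 5.0, "rubble", "p", "w9", 10, 10)]
        recs = cm.binarize_competency(make_obs(rows), 0.3)
        with pytest.warns(UserWarning, match="weakly identified"):
            cm.fit_competency_model(recs, fast_sampler)

    def test_large_n_agrees_with_mle_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        prof = default_profile(onset=4.0, slope=1.2, cues=("control", "rubble"),
                               cue_effects={"control": -2.0, "rubble": 0.5})
        design = AssayDesign(timepoints=[2, 3, 4, 5, 6, 8, 10],
                             cues=("control", "rubble"), wells_per_treatment=75)
        obs = simulate_assays(prof, design, seed=31)  # 525 wells per cue
        recs = cm.binarize_competency(obs, 0.3)
        cfg = SamplerConfig(n_chains=2, n_iterations=900, warmup=400, thin=2, seed=17)
        d = cm.fit_competency_model(recs, cfg)
        for cue in ("control", "rubble"):
            sub = recs[recs["cue"] == cue]
            X = np.column_stack([np.ones(len(sub)), sub["age_days"].to_numpy()])
            mle = sm.Logit(sub["competent"].to_numpy(), X).fit(disp=0)
            a_draws = d.extract(f"alpha[{cue}]")
            b_draws = d.extract(f"beta[{cue}]")
            assert abs(np.median(a_draws) - mle.params[0]) < 2 * a_draws.std()
            assert abs(np.median(b_draws) - mle.params[1]) < 2 * b_draws.std()


class TestTC50:
    def test_point_mass_closed_form(self, point_mass_draws):
        d = point_mass_draws(["alpha[rubble]", "beta[rubble]"], [-4.0, 1.0])
        est = cm.tc50_from_draws(d, "rubble", max_age=20)
        assert est.tc50_median == pytest.approx(4.0)
        assert est.ci_lower == est.ci_upper == pytest.approx(4.0)
        assert not est.truncated

    def test_all_negative_slope_truncated(self, point_mass_draws):
        d = point_mass_draws(["alpha[rubble]", "beta[rubble]"], [-4.0, -1.0])
        est = cm.tc50_from_draws(d, "rubble", max_age=20)
        assert est.truncated
        assert np.isinf(est.tc50_median)

    def test_median_beyond_extent_truncated(self, point_mass_draws):
        d = point_mass_draws(["alpha[rubble]", "beta[rubble]"], [-40.0, 1.0])
        est = cm.tc50_from_draws(d, "rubble", max_age=20)
        assert est.tc50_median == pytest.approx(40.0)
        assert est.truncated

    def test_closed_form_matches_root_finding_oracle(self):
        rng = np.random.default_rng(41)
        alpha = rng.normal(-4.0, 0.1, 1000)
        beta = rng.normal(1.0, 0.05, 1000)
        from coralsettle.datatypes import PosteriorDraws

        draws = PosteriorDraws(
            parameter_names=["alpha[r]", "beta[r]"],
            draws=np.stack([alpha, beta], axis=1)[None, :, :],
            model_tag="t",
        )
        tc = cm.tc50_draws(draws, "r")
        for a, b, t in zip(alpha, beta, tc):
            root = brentq(lambda x: expit(a + b * x) - 0.5, -100, 100, xtol=1e-12)
            assert abs(t - root) < 1e-8
        est = cm.tc50_from_draws(draws, "r", max_age=50)
        assert est.tc50_median == pytest.approx(np.median(tc))

    def test_unknown_cue(self, point_mass_draws):
        d = point_mass_draws(["alpha[rubble]", "beta[rubble]"], [-4.0, 1.0])
        with pytest.raises(KeyError):
            cm.tc50_from_draws(d, "cca", max_age=20)


class TestExceedance:
    def test_identical_vectors_half(self):
        v = np.array([1.0, 2.0, 3.0])
        m = cm.pairwise_exceedance({"a": v, "b": v.copy()})
        assert m.loc["a", "b"] == pytest.approx(0.5)

    def test_point_masses(self):
        m = cm.cue_tc50_contrasts({"a": np.full(10, 3.0), "b": np.full(10, 5.0)})
        assert m.loc["a", "b"] == 1.0
        assert m.loc["b", "a"] == 0.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(51)
        a = rng.normal(3, 1, 1000)
        b = rng.normal(3.5, 2, 1000)
        m = cm.cue_tc50_contrasts({"a": a, "b": b})
        brute = sum(1.0 if x < y else (0.5 if x == y else 0.0) for x, y in zip(a, b)) / 1000
        assert abs(m.loc["a", "b"] - brute) < 1e-12

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            cm.pairwise_exceedance({"a": np.ones(5), "b": np.ones(6)})

    def test_single_cue_error(self):
        with pytest.raises(ValueError):
            cm.cue_tc50_contrasts({"a": np.ones(5)})

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=30),
           st.lists(st.floats(-50, 50), min_size=3, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_complementarity_property(self, xs, ys):
        n = min(len(xs), len(ys))
        m = cm.pairwise_exceedance({"a": np.array(xs[:n]), "b": np.array(ys[:n])})
        assert m.loc["a", "b"] + m.loc["b", "a"] == pytest.approx(1.0, abs=0)


class TestThresholdSweep:
    def test_single_threshold_matches_direct_fit(self, two_cue_observations):
        cfg = SamplerConfig(n_chains=2, n_iterations=500, warmup=250, thin=2, seed=61)
        ests = cm.threshold_sweep(two_cue_observations, [0.3], cfg)
        # rebuild the same derived seed and fit directly
        sub_seed = int(np.random.SeedSequence((61, 3)).generate_state(1)[0])
        direct_cfg = SamplerConfig(n_chains=2, n_iterations=500, warmup=250, thin=2,
                                   seed=sub_seed)
        recs = cm.binarize_competency(two_cue_observations, 0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = cm.fit_competency_model(recs, direct_cfg)
        max_age = float(two_cue_observations["age_days"].max())
        for est in ests:
            if est.cue in ("control", "rubble"):
                ref = cm.tc50_from_draws(d, est.cue, max_age, threshold=0.3)
                assert est.tc50_median == pytest.approx(ref.tc50_median, abs=1e-12)

    def test_best_is_argmin_over_inducers(self, two_cue_observations):
        cfg = SamplerConfig(n_chains=2, n_iterations=500, warmup=250, thin=2, seed=62)
        ests = cm.threshold_sweep(two_cue_observations, [0.3], cfg)
        by_cue = {e.cue: e for e in ests}
        best = next(e for e in ests if e.cue.startswith("best["))
        assert best.cue == "best[rubble]"  # only non-control cue present
        assert best.tc50_median == by_cue["rubble"].tc50_median

    def test_impossible_threshold_truncates_not_crashes(self):
        rows = [("s", "c", a, cue, "p", f"w{a}{cue}{i}", 10, 0)
                for a in [2, 4, 6] for cue in ("control", "rubble") for i in range(3)]
        obs = make_obs(rows)
        cfg = SamplerConfig(n_chains=2, n_iterations=400, warmup=200, thin=2, seed=63)
        ests = cm.threshold_sweep(obs, [0.9], cfg)
        assert all(e.truncated for e in ests)

    def test_off_grid_threshold_rejected(self, two_cue_observations, fast_sampler):
        with pytest.raises(ValueError, match="grid"):
            cm.threshold_sweep(two_cue_observations, [0.35], fast_sampler)
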