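"""Linear predictors, probabilities, odds ratios and the Bernoulli likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rpslogit.model import (
    CrashDataset,
    ModelSpec,
    ParameterState,
    expand_random_coefficients,
    fatality_probability,
    linear_predictor,
    log_likelihood,
    odds_ratio,
)
from rpslogit.spatial import LerouxParams, chain_network


class TestLinearPredictor:
    def test_zero_parameters_give_zero(self, toy_dataset, toy_spec):
        ds, _ = toy_dataset
        state = ParameterState(beta0=0.0, beta={c: 0.0 for c in toy_spec.covariates})
        assert np.all(linear_predictor(ds, state, toy_spec) == 0.0)

    def test_published_logistic_arithmetic(self):
        # intercept -5.99 and EMS coefficient 0.021 (the plain-logistic
        # column of the reference fit) at 10 minutes give eta = -5.78
        ds = CrashDataset(
            outcome=np.array([0]),
            covariates=pd.DataFrame({"ems_response_time": [10.0]}),
            section_id=np.array(["S1"], dtype=object),
        )
        spec = ModelSpec(family="logistic", covariates=("ems_response_time",),
                         random_set=frozenset())
        state = ParameterState(beta0=-5.99, beta={"ems_response_time": 0.021})
        assert linear_predictor(ds, state, spec)[0] == pytest.approx(-5.78)

    def test_random_deviation_cancels_mean(self, toy_dataset):
        ds, net = toy_dataset
        spec = ModelSpec(
            family="rp_spatial_logistic",
            covariates=("ems_response_time", "truck"),
            random_set=frozenset({"truck"}),
        )
        mu = np.array([-0.5, 0.0, -0.5])  # = -beta_bar where truck is active
        state = ParameterState(
            beta0=0.0,
            beta={"ems_response_time": 0.0},
            beta_bar={"truck": 0.5},
            mu={"truck": mu},
            phi=np.zeros(2),
            leroux=LerouxParams(0.5, 1.0),
        )
        eta = linear_predictor(ds, state, spec, net)
        assert np.allclose(eta, 0.0)

    def test_missing_coefficient_rejected(self, toy_dataset, toy_spec):
        ds, _ = toy_dataset
        state = ParameterState(beta0=0.0, beta={"truck": 1.0})
        with pytest.raises(ValueError, match="missing coefficient"):
            linear_predictor(ds, state, toy_spec)

    def test_spatial_family_requires_phi(self, toy_dataset):
        ds, net = toy_dataset
        spec = ModelSpec(family="spatial_logistic", covariates=("truck",),
                         random_set=frozenset())
        state = ParameterState(beta0=0.0, beta={"truck": 0.2})
        with pytest.raises(ValueError, match="phi"):
            linear_predictor(ds, state, spec, net)


class TestFatalityProbability:
    def test_symmetry_at_zero(self):
        p1, p0 = fatality_probability(0.0)
        assert p1 == 0.5 and p0 == 0.5

    def test_reference_intercept_value(self):
        # logistic function at the reference RP intercept -7.10
        p1, _ = fatality_probability(-7.10)
        assert p1 == pytest.approx(8.2446e-4, rel=1e-4)

    def test_complement_and_odds_identity(self):
        rng = np.random.default_rng(0)
        eta = np.concatenate([rng.normal(0, 3, 100), [-50.0, 50.0, -700.0, 700.0]])
        p1, p0 = fatality_probability(eta)
        assert np.allclose(p1 + p0, 1.0)
        assert np.isfinite(p1).all() and np.isfinite(p0).all()
        mid = np.abs(eta) < 20  # avoid p0 underflow in the ratio
        assert np.allclose(p1[mid] / p0[mid], np.exp(eta[mid]), rtol=1e-12)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "beta, expected_or, expected_pct",
        [
            (0.026, 1.026, 2.6),  # per-minute EMS response time effect
            (0.0, 1.0, 0.0),
            (0.71, 2.03, 103.0),  # other-vehicle involvement
        ],
    )
    def test_printed_values(self, beta, expected_or, expected_pct):
        orv, pct = odds_ratio(beta)
        assert round(float(orv), 3 if beta == 0.026 else 2) == expected_or
        assert round(float(pct), 1) == pytest.approx(expected_pct, abs=0.5)

    def test_vectorized(self):
        orv, pct = odds_ratio(np.array([0.0, np.log(2.0)]))
        assert np.allclose(orv, [1.0, 2.0])
        assert np.allclose(pct, [0.0, 100.0])


class TestLogLikelihood:
    def test_flat_predictor_value(self, toy_dataset, toy_spec):
        ds, _ = toy_dataset
        state = ParameterState(beta0=0.0, beta={c: 0.0 for c in toy_spec.covariates})
        assert log_likelihood(ds, state, toy_spec) == pytest.approx(-3 * np.log(2))

    def test_matches_per_observation_brute_force(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 0, 1, 1, 0])
        x = rng.normal(size=5)
        ds = CrashDataset(
            outcome=y,
            covariates=pd.DataFrame({"x": x}),
            section_id=np.array(["S1"] * 5, dtype=object),
        )
        spec = ModelSpec(family="logistic", covariates=("x",), random_set=frozenset())
        state = ParameterState(beta0=-0.7, beta={"x": 1.3})
        eta = -0.7 + 1.3 * x
        expected = sum(
            np.log(expit(e)) if yi == 1 else np.log(expit(-e)) for yi, e in zip(y, eta)
        )
        assert log_likelihood(ds, state, spec) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_eta_for_fatal_outcome(self):
        ds = CrashDataset(
            outcome=np.array([1]),
            covariates=pd.DataFrame({"x": [1.0]}),
            section_id=np.array(["S1"], dtype=object),
        )
        spec = ModelSpec(family="logistic", covariates=("x",), random_set=frozenset())
        values = [
            log_likelihood(ds, ParameterState(beta0=0.0, beta={"x": b}), spec)
            for b in (-1.0, 0.0, 1.0, 3.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_stable_at_extreme_predictors(self):
        ds = CrashDataset(
            outcome=np.array([1, 0]),
            covariates=pd.DataFrame({"x": [1.0, 1.0]}),
            section_id=np.array(["S1", "S1"], dtype=object),
        )
        spec = ModelSpec(family="logistic", covariates=("x",), random_set=frozenset())
        ll = log_likelihood(ds, ParameterState(beta0=0.0, beta={"x": 800.0}), spec)
        assert np.isfinite(ll)  # one term ~0, the other ~-800


class TestRandomCoefficients:
    def test_degenerate_spread_returns_mean(self):
        out = expand_random_coefficients(0.51, 0.0, np.zeros(5))
        assert np.all(out == 0.51)

    def test_generative_moments_match_mixing_law(self):
        # Truck row of the reference fit: mean 0.51, SD 1.23
        rng = np.random.default_rng(2)
        draws = expand_random_coefficients(0.51, 1.23, 200_000, rng=rng)
        assert draws.mean() == pytest.approx(0.51, abs=0.01)
        assert draws.std() == pytest.approx(1.23, abs=0.02)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            expand_random_coefficients(0.0, -1.0, 5)


class TestNesting:
    def test_spatial_with_zero_phi_equals_plain_logistic(self, toy_dataset):
        ds, net = toy_dataset
        covs = ("ems_response_time", "truck")
        beta = {"ems_response_time": 0.02, "truck": 0.5}
        plain = ModelSpec(family="logistic", covariates=covs, random_set=frozenset())
        spatial = ModelSpec(family="spatial_logistic", covariates=covs,
                            random_set=frozenset())
        s_plain = ParameterState(beta0=-3.0, beta=beta)
        s_spatial = ParameterState(beta0=-3.0, beta=beta, phi=np.zeros(2),
                                   leroux=LerouxParams(0.5, 1.0))
        assert log_likelihood(ds, s_plain, plain) == pytest.approx(
            log_likelihood(ds, s_spatial, spatial, net), rel=1e-14
        )

    def test_rp_with_zero_deviations_equals_spatial(self, toy_dataset):
        ds, net = toy_dataset
        covs = ("ems_response_time", "truck")
        spatial = ModelSpec(family="spatial_logistic", covariates=covs,
                            random_set=frozenset())
        rp = ModelSpec(family="rp_spatial_logistic", covariates=covs,
                       random_set=frozenset({"truck"}))
        phi = np.array([0.4, -0.2])
        lx = LerouxParams(0.3, 0.8)
        s_sp = ParameterState(beta0=-3.0, beta={"ems_response_time": 0.02, "truck": 0.5},
                              phi=phi, leroux=lx)
        s_rp = ParameterState(
            beta0=-3.0,
            beta={"ems_response_time": 0.02},
            beta_bar={"truck": 0.5},
            sigma={"truck": 1e-12},
            mu={"truck": np.zeros(3)},
            phi=phi,
            leroux=lx,
        )
        assert log_likelihood(ds, s_sp, spatial, net) == pytest.approx(
            log_likelihood(ds, s_rp, rp, net), rel=1e-14
        )


class TestDatasetValidation:
    def test_non_binary_outcome_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            CrashDataset(
                outcome=np.array([0, 2]),
                covariates=pd.DataFrame({"x": [1.0, 2.0]}),
                section_id=np.array(["a", "a"], dtype=object),
            )

    def test_nonpositive_ems_rejected(self):
        with pytest.raises(ValueError, match="ems_response_time"):
            CrashDataset(
                outcome=np.array([0]),
                covariates=pd.DataFrame({"ems_response_time": [0.0]}),
                section_id=np.array(["a"], dtype=object),
            )

    def test_double_active_indicator_group_rejected(self):
        with pytest.raises(ValueError, match="more than one active indicator"):
            CrashDataset(
                outcome=np.array([0]),
                covariates=pd.DataFrame(
                    {"coach": [1], "truck": [1], "other_vehicle": [0]}
                ),
                section_id=np.array(["a"], dtype=object),
            )

    def test_random_set_must_be_subset(self):
        with pytest.raises(ValueError, match="random_set"):
            ModelSpec(family="rp_spatial_logistic", covariates=("a",),
                      random_set=frozenset({"b"}))

    def test_unknown_section_id_rejected(self, toy_dataset):
        ds, _ = toy_dataset
        net = chain_network(2, prefix="Z")
        with pytest.raises(KeyError, match="unknown section id"):
            ds.section_index(net)
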