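import math

import numpy as np
import pandas as pd
import pytest

from streamsync.cjs import (DetectionParameters, ModelSpec, PriorSpec,
                            SurvivalParameters, build_marray,
                            individual_log_likelihood, interval_survival,
                            log_prior, marray_log_likelihood,
                            sixty_day_survival, survival_probability,
                            total_log_likelihood)
from streamsync.data_model import (CaptureHistoryMatrix, OccasionCalendar,
                                   SpeciesStreamIndex)

from .oracles import enumerate_cjs_loglik


class TestIntervalSurvival:
    def test_square_root_case(self):
        assert interval_survival(0.81, 30) == pytest.approx(0.9)

    def test_sixty_days_identity(self, rng):
        s = rng.random(20)
        np.testing.assert_allclose(interval_survival(s, 60), s)

    def test_certain_survival(self):
        assert interval_survival(1.0, 123) == 1.0

    def test_inverse_round_trip(self, rng):
        s = rng.random(20)
        nd = rng.integers(40, 80, 20)
        np.testing.assert_allclose(
            sixty_day_survival(interval_survival(s, nd), nd), s, atol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            interval_survival(1.2, 30)
        with pytest.raises(ValueError):
            interval_survival(0.5, 0)


class TestSurvivalProbability:
    def test_intercept_at_zero(self):
        params = SurvivalParameters(mu=np.zeros((1, 1)))
        spec = ModelSpec(variant="intercept_only")
        assert survival_probability(params, spec, None, 0, 0, 0, 60) == \
            pytest.approx(0.5)

    def test_covariate_closed_form(self):
        params = SurvivalParameters(mu=np.zeros((1, 1)),
                                    beta=np.array([-0.5]))
        spec = ModelSpec(variant="covariate", covariate="mean_temp",
                         scaling_mode="posthoc")
        x = np.array([2.0])
        got = survival_probability(params, spec, x, 0, 0, 0, 60)
        assert got == pytest.approx(1 / (1 + math.exp(1)), abs=1e-12)

    def test_zero_random_effects_reduce_to_intercept(self, rng):
        params = SurvivalParameters.zeros(2, 2, 5)
        params.mu += rng.normal(size=(2, 2))
        spec_re = ModelSpec(variant="random_effects")
        spec_int = ModelSpec(variant="intercept_only")
        for j in range(2):
            for s in range(2):
                assert survival_probability(params, spec_re, None, j, s, 2, 50) == \
                    pytest.approx(
                        survival_probability(params, spec_int, None, j, s, 2, 50))

    def test_missing_covariate_is_error(self):
        params = SurvivalParameters(mu=np.zeros((1, 1)), beta=np.array([1.0]))
        spec = ModelSpec(variant="covariate", covariate="mean_temp")
        with pytest.raises(ValueError):
            survival_probability(params, spec, None, 0, 0, 0, 60)


class TestIndividualLogLikelihood:
    def test_history_101(self):
        ll = individual_log_likelihood([1, 0, 1], [0.8, 0.8], [0.5, 0.5])
        assert math.exp(ll) == pytest.approx(0.16)

    def test_history_100(self):
        # chi recursion: 0.2 + 0.8*0.5*(0.2 + 0.8*0.5)
        ll = individual_log_likelihood([1, 0, 0], [0.8, 0.8], [0.5, 0.5])
        assert math.exp(ll) == pytest.approx(0.44)

    def test_first_capture_at_final_occasion(self):
        assert individual_log_likelihood([0, 0, 1], [0.8, 0.8], [0.5, 0.5]) == 0.0

    def test_no_detection_rejected(self):
        with pytest.raises(ValueError):
            individual_log_likelihood([0, 0, 0], [0.8, 0.8], [0.5, 0.5])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_enumeration(self, trial):
        """chi-recursion equals exhaustive latent-state enumeration."""
        rng = np.random.default_rng(100 + trial)
        T = int(rng.integers(2, 7))
        phi = rng.uniform(0.05, 0.95, T - 1)
        p = rng.uniform(0.05, 0.95, T - 1)
        first = int(rng.integers(0, T))
        y = np.zeros(T, dtype=int)
        y[first] = 1
        y[first + 1:] = rng.integers(0, 2, T - 1 - first)
        assert individual_log_likelihood(y, phi, p) == pytest.approx(
            enumerate_cjs_loglik(y, phi, p), abs=1e-10)

    def test_monotone_in_survival(self):
        """Higher survival raises the likelihood of an all-detected history."""
        y = [1, 1, 1, 1]
        p = [0.5, 0.5, 0.5]
        lls = [individual_log_likelihood(y, [phi] * 3, p)
               for phi in (0.2, 0.5, 0.8, 0.95)]
        assert all(a < b for a, b in zip(lls, lls[1:]))


def _tiny_matrix(histories, species, streams, index, calendar):
    y = np.asarray(histories, dtype=np.int8)
    first = np.argmax(y == 1, axis=1) + 1
    meta = pd.DataFrame({
        "id": [f"i{k}" for k in range(len(histories))],
        "species": species, "stream": streams,
        "first_capture": first, "terminal_only": first == y.shape[1]})
    return CaptureHistoryMatrix(y, meta, calendar, index)


class TestTotalLogLikelihood:
    def test_two_identical_individuals(self, calendar3, small_index):
        m1 = _tiny_matrix([[1, 0, 1]], ["BHC"], ["Indian"], small_index, calendar3)
        m2 = _tiny_matrix([[1, 0, 1], [1, 0, 1]], ["BHC"] * 2, ["Indian"] * 2,
                          small_index, calendar3)
        params = SurvivalParameters(mu=np.full((2, 1), 0.3))
        det = DetectionParameters(p=np.full((2, 1, 2), 0.4))
        spec = ModelSpec(variant="intercept_only")
        ll1 = total_log_likelihood(m1, params, det, spec)
        ll2 = total_log_likelihood(m2, params, det, spec)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-10)

    def test_permutation_invariance(self, calendar3, small_index, rng):
        hists = [[1, 0, 1], [0, 1, 0], [1, 1, 1], [0, 1, 1]]
        species = ["BHC", "CRC", "BHC", "CRC"]
        params = SurvivalParameters(mu=rng.normal(size=(2, 1)))
        det = DetectionParameters(p=rng.uniform(0.2, 0.6, (2, 1, 2)))
        spec = ModelSpec(variant="intercept_only")
        perm = rng.permutation(4)
        a = total_log_likelihood(
            _tiny_matrix(hists, species, ["Indian"] * 4, small_index, calendar3),
            params, det, spec)
        b = total_log_likelihood(
            _tiny_matrix([hists[i] for i in perm], [species[i] for i in perm],
                         ["Indian"] * 4, small_index, calendar3),
            params, det, spec)
        assert a == pytest.approx(b, abs=1e-12)

    def test_perfect_detection_certain_survival(self, calendar3, small_index):
        m = _tiny_matrix([[1, 1, 1]], ["BHC"], ["Indian"], small_index, calendar3)
        params = SurvivalParameters(mu=np.full((2, 1), 40.0))  # phi ~ 1
        det = DetectionParameters(p=np.full((2, 1, 2), 1 - 1e-12))
        spec = ModelSpec(variant="intercept_only", scaling_mode="posthoc")
        assert total_log_likelihood(m, params, det, spec) == pytest.approx(
            0.0, abs=1e-6)

    def test_marray_equals_individual_sum(self, default_dataset):
        """The m-array factorization is exactly the per-individual likelihood."""
        d = default_dataset
        matrix, truth = d["matrix"], d["truth"]
        spec = ModelSpec(variant="random_effects_plus_covariate",
                         covariate="mean_temp")
        ll_m = total_log_likelihood(matrix, truth.params, truth.detection,
                                    spec, x=truth.x)
        nd = d["calendar"].n_days
        sc, st = matrix.species_codes(), matrix.stream_codes()
        ll_i = 0.0
        for i in range(matrix.n_individuals):
            j, s = sc[i], st[i]
            phi = truth.survival60[j, s] ** (nd / 60.0)
            ll_i += individual_log_likelihood(matrix.detections[i], phi,
                                              truth.detection.p[j, s])
        assert ll_m == pytest.approx(ll_i, abs=1e-8)

    def test_zero_effects_match_intercept_model(self, calendar3, small_index):
        m = _tiny_matrix([[1, 0, 1], [0, 1, 1]], ["BHC", "CRC"], ["Indian"] * 2,
                         small_index, calendar3)
        params = SurvivalParameters.zeros(2, 1, 3)
        params.mu += 0.7
        params.beta = np.array([0.0])
        det = DetectionParameters(p=np.full((2, 1, 2), 0.4))
        x = np.array([0.3, -1.2])
        ll_int = total_log_likelihood(m, params, det,
                                      ModelSpec(variant="intercept_only"))
        ll_re = total_log_likelihood(
            m, params, det, ModelSpec(variant="random_effects_plus_covariate",
                                      covariate="mean_temp"), x=x)
        assert ll_re == pytest.approx(ll_int, abs=1e-12)


class TestLogPrior:
    def test_normal_density_at_zero(self):
        params = SurvivalParameters(mu=np.zeros((1, 1)))
        spec = ModelSpec(variant="intercept_only")
        expected = -math.log(10 * math.sqrt(2 * math.pi))
        assert log_prior(params, None, spec) == pytest.approx(expected)

    def test_negative_variance_gives_neg_inf(self):
        params = SurvivalParameters.zeros(1, 1, 3)
        params.sigma2_t = -0.1
        spec = ModelSpec(variant="random_effects")
        assert log_prior(params, None, spec) == -np.inf

    def test_modes_are_finite(self):
        params = SurvivalParameters.zeros(2, 2, 5)
        params.sigma2_t = 0.25
        params.sigma2_j += 0.25
        params.sigma2_s += 0.25
        params.sigma2_js += 0.25
        det = DetectionParameters(p=np.full((2, 2, 4), 0.5))
        spec = ModelSpec(variant="random_effects")
        assert np.isfinite(log_prior(params, det, spec))

    def test_sd_above_upper_bound(self):
        params = SurvivalParameters.zeros(1, 1, 3)
        params.sigma2_t = 150.0  # sd > 10
        params.sigma2_j += 0.25
        params.sigma2_s += 0.25
        params.sigma2_js += 0.25
        spec = ModelSpec(variant="random_effects",
                         priors=PriorSpec(sd_upper=10.0))
        assert log_prior(params, None, spec) == -np.inf


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(variant="covariate")  # missing covariate name
    with pytest.raises(ValueError):
        ModelSpec(variant="intercept_only", covariate="mean_temp")
    with pytest.raises(ValueError):
        ModelSpec(variant="nope")


def test_marray_counts_consistency(default_dataset):
    matrix = default_dataset["matrix"]
    m, never = build_marray(matrix)
    # every release cohort splits into next-capture cells + never-seen
    releases = m.sum(axis=2) + never
    # total releases = total captures at occasions 1..T-1
    y = matrix.detections
    G = matrix.index.n_groups
    g = matrix.group_codes()
    for gi in range(G):
        caps = y[g == gi, :-1].sum(axis=0)
        np.testing.assert_array_equal(releases[gi], caps)
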