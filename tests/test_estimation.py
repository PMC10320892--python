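"""Hierarchical estimation: MAP objective, empirical Bayes, SAEM fitting."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from sessiondose.estimation import (DEFAULT_TYPICAL, IndividualParameters,
                                    PopulationParameters, SaemConfig,
                                    SessionDoseModel, empirical_bayes,
                                    fit_population, individual_objective)
from sessiondose.model import (PatientRecord, ServiceType, SessionEvent,
                               SeverityObservation, ValidationError,
                               simulate_trajectory)
from sessiondose.synth import CohortConfig, generate_cohort


def _simple_record(pid="p1", obs=None, events=None):
    obs = obs if obs is not None else [SeverityObservation(0.0, 1.0)]
    events = events or []
    return PatientRecord(pid, events, obs)


def _pop(omega=0.0, sigma=1.0, typical=DEFAULT_TYPICAL):
    return PopulationParameters(typical=typical,
                                omega=np.full(5, float(omega)), sigma=sigma)


class TestIndividualObjective:
    def test_single_zero_residual_standard_normal(self):
        # -2 log N(0 | 0, 1) = log(2 pi)
        rec = _simple_record()
        indiv = IndividualParameters.from_eta(np.zeros(5), DEFAULT_TYPICAL)
        val = individual_objective(rec, indiv, _pop(omega=0.0, sigma=1.0))
        assert val == pytest.approx(math.log(2 * math.pi), abs=1e-9)
        assert val == pytest.approx(1.837877, abs=1e-6)

    def test_two_zero_residuals_add(self):
        # untreated severe patient: prediction is 1 at all times
        rec = _simple_record(obs=[SeverityObservation(0.0, 1.0),
                                  SeverityObservation(30.0, 1.0)])
        indiv = IndividualParameters.from_eta(np.zeros(5), DEFAULT_TYPICAL)
        val = individual_objective(rec, indiv, _pop(omega=0.0, sigma=1.0))
        assert val == pytest.approx(2 * math.log(2 * math.pi), abs=1e-9)

    def test_matches_density_product_oracle(self):
        rng = np.random.default_rng(21)
        events = [SessionEvent(5.0, ServiceType.THERAPY),
                  SessionEvent(25.0, ServiceType.PSYCHIATRY)]
        times = np.array([0.0, 20.0, 50.0, 90.0])
        for _ in range(5):
            eta = 0.3 * rng.standard_normal(5)
            indiv = IndividualParameters.from_eta(eta, DEFAULT_TYPICAL)
            sev = np.clip(rng.uniform(0.2, 1.0, times.size), 0, 1)
            sev[0] = 1.0
            rec = _simple_record(
                obs=[SeverityObservation(float(t), float(s))
                     for t, s in zip(times, sev)], events=events)
            pop = _pop(omega=0.4, sigma=0.12)
            pred = simulate_trajectory(events, indiv.realized, times,
                                       method="exact")
            expected = -2.0 * (
                np.sum(norm.logpdf(sev, loc=pred, scale=pop.sigma))
                + np.sum(norm.logpdf(eta, loc=0.0, scale=0.4)))
            got = individual_objective(rec, indiv, pop)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_sigma_rejected(self):
        rec = _simple_record()
        indiv = IndividualParameters.from_eta(np.zeros(5), DEFAULT_TYPICAL)
        with pytest.raises(ValidationError):
            individual_objective(rec, indiv, _bad_sigma_pop())

    def test_nonzero_eta_with_zero_omega_rejected(self):
        rec = _simple_record()
        indiv = IndividualParameters.from_eta(
            np.array([0.1, 0, 0, 0, 0]), DEFAULT_TYPICAL)
        with pytest.raises(ValidationError, match="omega"):
            individual_objective(rec, indiv, _pop(omega=0.0))


def _bad_sigma_pop():
    # bypass the dataclass validation to exercise the operation's own check
    pop = _pop(omega=0.0, sigma=1.0)
    object.__setattr__(pop, "sigma", -1.0)
    return pop


class TestEmpiricalBayes:
    def test_zero_omega_pins_eta_at_zero(self):
        rec = _simple_record(obs=[SeverityObservation(0.0, 1.0),
                                  SeverityObservation(40.0, 0.4)],
                             events=[SessionEvent(10.0, ServiceType.THERAPY)])
        eb = empirical_bayes(rec, _pop(omega=0.0, sigma=0.1))
        assert np.all(eb.eta == 0.0)
        assert eb.realized.to_dict() == DEFAULT_TYPICAL.to_dict()

    def test_no_post_baseline_data_returns_prior_mode(self):
        # a lone baseline report carries zero residual whatever eta is
        rec = _simple_record(obs=[SeverityObservation(0.0, 1.0)])
        eb = empirical_bayes(rec, _pop(omega=2.0, sigma=0.1), seed=1)
        assert np.all(np.abs(eb.eta) < 1e-4)

    def test_dense_noiseless_record_recovers_true_eta(self):
        eta_star = np.array([0.3, -0.2, 0.4, -0.3, 0.2])
        indiv = IndividualParameters.from_eta(eta_star, DEFAULT_TYPICAL)
        events = sorted(
            [SessionEvent(float(t), ServiceType.THERAPY)
             for t in range(0, 300, 20)]
            + [SessionEvent(float(t), ServiceType.COACHING)
               for t in range(5, 300, 45)]
            + [SessionEvent(float(t), ServiceType.PSYCHIATRY)
               for t in range(10, 300, 60)], key=lambda e: e.time)
        grid = np.arange(0.0, 301.0, 5.0)
        dep = simulate_trajectory(events, indiv.realized, grid, method="exact")
        rec = _simple_record(obs=[SeverityObservation(float(t), float(v))
                                  for t, v in zip(grid, dep)], events=events)
        eb = empirical_bayes(rec, _pop(omega=2.0, sigma=0.01), seed=3)
        assert np.all(np.abs(eb.eta - eta_star) < 0.05)

    def test_map_dominance_over_prior_mode(self):
        # the optimum can never be worse than eta = 0
        pop = _pop(omega=0.4, sigma=0.1)
        cfg = CohortConfig(n_patients=6, seed=9)
        cohort, _ = generate_cohort(cfg)
        zero = IndividualParameters.from_eta(np.zeros(5), pop.typical)
        for rec in cohort:
            eb = empirical_bayes(rec, pop, seed=4)
            assert (individual_objective(rec, eb, pop)
                    <= individual_objective(rec, zero, pop) + 1e-9)

    def test_shrinkage_toward_prior_as_noise_grows(self):
        # one free parameter (the turnover rate r): |eta_r| must shrink
        # monotonically as sigma grows
        omega = np.array([0.0, 0.0, 0.0, 0.0, 0.6])
        events = [SessionEvent(float(t), ServiceType.THERAPY)
                  for t in range(0, 120, 14)]
        true_indiv = IndividualParameters.from_eta(
            np.array([0, 0, 0, 0, 0.5]), DEFAULT_TYPICAL)
        grid = np.arange(0.0, 121.0, 15.0)
        dep = simulate_trajectory(events, true_indiv.realized, grid,
                                  method="exact")
        rec = _simple_record(obs=[SeverityObservation(float(t), float(v))
                                  for t, v in zip(grid, dep)], events=events)
        magnitudes = []
        for sigma in (0.02, 0.1, 0.3, 1.0, 3.0):
            pop = PopulationParameters(typical=DEFAULT_TYPICAL, omega=omega,
                                       sigma=sigma)
            eb = empirical_bayes(rec, pop, seed=5)
            magnitudes.append(abs(eb.eta[4]))
        assert all(b <= a + 1e-6 for a, b in zip(magnitudes, magnitudes[1:]))
        assert magnitudes[0] > 0.2          # informative at low noise
        assert magnitudes[-1] < 0.05        # shrunk at high noise


class TestFitPopulation:
    def test_undersized_cohort_rejected(self):
        rec = _simple_record(obs=[SeverityObservation(0.0, 1.0),
                                  SeverityObservation(40.0, 0.4)],
                             events=[SessionEvent(10.0, ServiceType.THERAPY)])
        with pytest.raises(ValidationError):
            fit_population([rec], seed=1)

    def test_degenerate_noise_recovers_typical_values(self):
        # omega = 0 and near-zero residual noise: the typical values are the
        # only free quantities and must come back within 1%
        pop0 = PopulationParameters(typical=DEFAULT_TYPICAL,
                                    omega=np.zeros(5), sigma=1e-4)
        cfg = CohortConfig(n_patients=60, seed=5, population=pop0,
                           snap_to_grid=False,
                           archetype_mix={"response": 0.6, "saturated": 0.4})
        cohort, _ = generate_cohort(cfg)
        fit = fit_population(
            cohort, SaemConfig(n_burnin=250, n_smooth=250, annealing=0.90),
            seed=2)
        est = fit.population.typical.as_array()
        true = DEFAULT_TYPICAL.as_array()
        assert np.all(np.abs(est - true) / true < 0.01)

    def test_saem_running_average_stabilises(self):
        # after burn-in, the cumulative average of every population
        # parameter moves by <1% over the final 20% of iterations
        pop0 = PopulationParameters(typical=DEFAULT_TYPICAL,
                                    omega=np.zeros(5), sigma=1e-4)
        cfg = CohortConfig(n_patients=30, seed=6, population=pop0,
                           snap_to_grid=False,
                           archetype_mix={"response": 0.6, "saturated": 0.4})
        cohort, _ = generate_cohort(cfg)
        fit = fit_population(
            cohort, SaemConfig(n_burnin=100, n_smooth=200, annealing=0.90),
            seed=3)
        smooth = fit.trace["typical"][100:]
        cum = np.cumsum(smooth, axis=0) / np.arange(1, len(smooth) + 1)[:, None]
        drift = np.abs(cum[-1] - cum[int(0.8 * len(smooth))]) / cum[-1]
        assert np.all(drift < 0.01)

    def test_patient_order_does_not_change_estimates(self):
        cfg = CohortConfig(n_patients=12, seed=8)
        cohort, _ = generate_cohort(cfg)
        sc = SaemConfig(n_burnin=30, n_smooth=50)
        fit_a = fit_population(list(cohort), sc, seed=7)
        fit_b = fit_population(list(reversed(cohort)), sc, seed=7)
        assert np.array_equal(fit_a.population.typical.as_array(),
                              fit_b.population.typical.as_array())
        assert np.array_equal(fit_a.population.omega, fit_b.population.omega)
        assert fit_a.population.sigma == fit_b.population.sigma

    def test_estimator_api_and_alignment(self):
        cfg = CohortConfig(n_patients=10, seed=12)
        cohort, _ = generate_cohort(cfg)
        est = SessionDoseModel(n_burnin=20, n_smooth=30, seed=3)
        assert est.get_params()["n_burnin"] == 20
        est.fit(cohort)
        assert hasattr(est, "population_")
        result = est.result_
        assert len(result.patients) == len(cohort)
        for pf in result.patients:
            rec = next(r for r in cohort if r.id == pf.patient_id)
            assert pf.ipred.shape == (len(rec.observations),)
            assert np.allclose(pf.residuals, pf.observed - pf.ipred)
            # baseline prediction anchored at the severe entry level
            assert pf.ipred[0] == pytest.approx(1.0, abs=1e-9)
        pred = est.predict(cohort[0])
        assert pred.shape == (len(cohort[0].observations),)
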