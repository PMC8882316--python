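"""Trial simulator: accrual, interim analyses, enrichment, replication."""

import numpy as np
import pytest

from bayesenrich.decision import Thresholds
from bayesenrich.scenarios import balanced_q_b, k2_scenario, k3_pattern, k3_scenario
from bayesenrich.simulate import (
    ENTIRE_POPULATION,
    Scenario,
    generate_cohort,
    generate_patient,
    replicate,
    run_trial,
)

MILLEN = Thresholds(rule="millen", gamma=0.9, tau=0.9, eta=1.1)
UNREACHABLE = Thresholds(rule="millen", gamma=1.0, tau=1.0, eta=1.0)
PERMISSIVE = Thresholds(rule="millen", gamma=0.05, tau=0.05, eta=1.0)


class TestScenarioCatalog:
    def test_k2_scenario_4_cells(self):
        sc = k2_scenario(4)
        assert sc.p1.tolist() == [0.20, 0.40] and sc.p0.tolist() == [0.50, 0.40]
        np.testing.assert_allclose(sc.theta, [0.4, 1.0])

    def test_k2_null_flag(self):
        assert k2_scenario(1).null and not k2_scenario(3).null

    def test_k3_patterns_sum_to_one(self):
        for i in range(1, 6):
            assert sum(k3_pattern(i)) == pytest.approx(1.0)

    def test_k3_scenario_7_thetas(self):
        sc = k3_scenario(7)
        np.testing.assert_allclose(sc.theta, [1.0, 0.4, 1.25])
        assert sc.sensitive == ("B",)

    def test_balanced_q_b(self):
        assert balanced_q_b(0.5, 0.1) == pytest.approx(0.9)
        with pytest.raises(ValueError):
            balanced_q_b(0.8, 0.1)  # would need q_B > 1

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            Scenario(("A", "B"), pi=[0.6, 0.6], q=[0.5, 0.5], p1=[0.3, 0.3], p0=[0.4, 0.4])
        with pytest.raises(ValueError):
            Scenario(("A", "B"), pi=[0.5, 0.5], q=[0.5, 0.5], p1=[0.3, 0.3], p0=[0.0, 0.4])


class TestAccrual:
    def test_prevalence_law_of_large_numbers(self, rng):
        sc = k2_scenario(1, pi_a=0.3)
        ks, _, _ = generate_cohort(sc, sc.subsets, 20_000, rng)
        assert np.mean(ks == 0) == pytest.approx(0.3, abs=0.015)

    def test_restriction_renormalizes(self, rng):
        sc = k3_scenario(1)
        ks, _, _ = generate_cohort(sc, ("B",), 500, rng)
        assert set(ks.tolist()) == {1}

    def test_scenario4_experimental_death_rate(self, rng):
        sc = k2_scenario(4)
        ks, arm, outcome = generate_cohort(sc, sc.subsets, 100_000, rng)
        sel = (ks == 0) & (arm == 1)
        assert outcome[sel].mean() == pytest.approx(0.20, abs=0.01)

    def test_generate_patient_record(self, rng):
        sc = k2_scenario(2)
        rec = generate_patient(sc, sc.subsets, rng, index=7)
        assert rec.index == 7 and rec.subset in sc.subsets
        assert rec.arm in (0, 1) and rec.outcome in (0, 1)


class TestRunTrial:
    def test_conservation_and_no_enrichment(self):
        res = run_trial(k2_scenario(1), UNREACHABLE, n_total=800, n_analyses=4,
                        n_draws=1000, master_seed=1)
        assert res.final_action == ENTIRE_POPULATION
        assert res.n_enrolled.sum() == 800
        assert res.enrichment_look is None
        assert len(res.looks) == 4 and all(l.evaluated for l in res.looks)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            run_trial(k2_scenario(1), MILLEN, n_total=801, n_analyses=4, n_draws=100)

    def test_enrichment_redirects_accrual(self):
        sc = k2_scenario(4)
        res = run_trial(sc, PERMISSIVE, n_total=400, n_analyses=4, n_draws=2000, master_seed=3)
        assert res.final_action == "enrich:A"
        assert res.n_enrolled.sum() == 400
        # enrichment at look 0 leaves only the first segment shared
        assert res.enrichment_look == 0
        assert res.n_enrolled[0] > 400 * sc.pi[0]
        # frozen after enrichment: later looks not evaluated
        assert not any(l.evaluated for l in res.looks[1:])

    def test_bitwise_reproducible(self):
        a = run_trial(k2_scenario(3), MILLEN, n_total=400, n_analyses=4,
                      n_draws=2000, master_seed=9)
        b = run_trial(k2_scenario(3), MILLEN, n_total=400, n_analyses=4,
                      n_draws=2000, master_seed=9)
        assert a.final_action == b.final_action
        np.testing.assert_array_equal(a.n_enrolled, b.n_enrolled)
        assert a.theta_hat == b.theta_hat

    def test_keep_patients_matches_counts(self):
        res = run_trial(k2_scenario(2), UNREACHABLE, n_total=200, n_analyses=4,
                        n_draws=500, master_seed=4, keep_patients=True)
        ks, arm, outcome = res.patients
        assert len(ks) == 200
        for k in (0, 1):
            assert (ks == k).sum() == res.n_enrolled[k]


class TestReplicate:
    def test_single_replication_point_mass(self):
        oc = replicate(k2_scenario(1), UNREACHABLE, n_total=200, n_analyses=4,
                       n_draws=500, N=1, master_seed=5)
        assert oc.proportion(ENTIRE_POPULATION) == 1.0

    def test_proportions_sum_and_conservation(self):
        oc, results = replicate(k2_scenario(3), MILLEN, n_total=400, n_analyses=4,
                                n_draws=2000, N=40, master_seed=6, keep_results=True)
        assert sum(oc.decision_proportions.values()) == pytest.approx(1.0)
        for r in results:
            assert r.n_enrolled.sum() == 400
        assert sum(oc.mean_n.values()) == pytest.approx(400.0)

    def test_serial_parallel_identical(self):
        kw = dict(n_total=400, n_analyses=4, n_draws=1000, N=12, master_seed=7)
        serial = replicate(k2_scenario(4), MILLEN, n_jobs=1, **kw)
        parallel = replicate(k2_scenario(4), MILLEN, n_jobs=2, **kw)
        assert serial.decision_proportions == parallel.decision_proportions
        assert serial.mean_n == parallel.mean_n
        assert serial.mean_bias_theta == parallel.mean_bias_theta

    def test_parameter_recovery_bias_shrinks_with_n(self):
        # no enrichment: the posterior mean of theta_k converges to truth
        biases = []
        for n_total in (200, 1600):
            oc = replicate(k2_scenario(2), UNREACHABLE, n_total=n_total, n_analyses=4,
                           n_draws=4000, N=60, master_seed=8)
            biases.append(np.mean(np.abs(list(oc.mean_bias_theta.values()))))
        assert biases[1] < biases[0]
        assert biases[1] < 0.05

    def test_false_positive_definitions(self):
        null_oc = replicate(k2_scenario(1), PERMISSIVE, n_total=200, n_analyses=2,
                            n_draws=1000, N=30, master_seed=10)
        assert null_oc.false_positive_rate == pytest.approx(null_oc.any_enrichment_rate())
        eff_oc = replicate(k2_scenario(4), PERMISSIVE, n_total=200, n_analyses=2,
                           n_draws=1000, N=30, master_seed=11)
        # under an effect scenario the FPR counts only wrong-subset enrichment
        assert eff_oc.false_positive_rate == pytest.approx(
            sum(p for k, p in eff_oc.decision_proportions.items()
                if "B" in k and k != ENTIRE_POPULATION)
        )

    def test_null_fpr_decreases_with_larger_looks(self):
        # bigger per-look samples make the null rules harder to trip
        fprs = []
        for n_total in (240, 960):
            oc = replicate(k2_scenario(1), MILLEN.replace(gamma=0.8, tau=0.8),
                           n_total=n_total, n_analyses=4, n_draws=3000, N=150,
                           master_seed=12)
            fprs.append(oc.false_positive_rate)
        se = np.sqrt(max(fprs[0], 0.02) * (1 - fprs[0]) / 150)
        assert fprs[1] <= fprs[0] + 3 * se
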