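"""Survival counting, rate fitting and the curve-shift tension estimate."""

import math

import numpy as np
import pytest

import guvpore as g
from conftest import make_records, simulate_exponential_records


class TestEmpiricalSurvival:
    def test_partial_rupture_fraction(self):
        # 7 ruptures among 18 vesicles in the 60 s window
        times = list(np.linspace(5, 55, 7)) + [None] * 11
        curve = g.empirical_survival(make_records(times))
        assert round(curve.p_pore_end, 2) == 0.39

    def test_all_ruptured(self):
        curve = g.empirical_survival(make_records(np.linspace(1, 59, 18)))
        assert curve.p_pore_end == pytest.approx(1.0)

    def test_none_ruptured(self):
        curve = g.empirical_survival(make_records([None] * 10))
        assert curve.p_pore_end == 0.0
        assert np.all(curve.evaluate([0.0, 30.0, 60.0]) == 1.0)

    def test_counts_conserved_at_every_time(self):
        rng = np.random.default_rng(7)
        records = simulate_exponential_records(0.05, 40, rng)
        curve = g.empirical_survival(records)
        n_censored = sum(r.censored for r in records)
        for t in np.linspace(0, 60, 13):
            intact_frac = float(curve.evaluate(t))
            ruptured = round((1 - intact_frac) * curve.n_total)
            still_running = curve.n_total - ruptured
            assert ruptured + still_running == curve.n_total
        assert curve.p_intact[-1] * curve.n_total == pytest.approx(n_censored)

    def test_ties_drop_by_tied_count(self):
        curve = g.empirical_survival(make_records([10.0, 10.0, 20.0, None]))
        assert curve.evaluate(10.0) == pytest.approx(0.5)

    def test_survival_is_monotone_from_one(self):
        rng = np.random.default_rng(3)
        curve = g.empirical_survival(simulate_exponential_records(0.1, 30, rng))
        values = np.concatenate(([1.0], curve.p_intact))
        assert np.all(np.diff(values) <= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            g.empirical_survival([])

    def test_inconsistent_windows_rejected(self):
        records = make_records([10.0], window=60.0) + make_records(
            [20.0], window=30.0
        )
        with pytest.raises(ValueError, match="window"):
            g.empirical_survival(records)


class TestFitRateConstant:
    @pytest.mark.parametrize("method", ["survival-lsq", "censored-mle"])
    def test_recovers_rate_at_large_n(self, method):
        rng = np.random.default_rng(11)
        records = simulate_exponential_records(0.1, 10_000, rng)
        est = g.fit_rate_constant(records, method=method)
        assert est.k_p == pytest.approx(0.1, abs=0.005)

    def test_single_event_mle_closed_form(self):
        records = make_records([10.0])
        est = g.fit_rate_constant(records, method="censored-mle")
        assert est.k_p == pytest.approx(0.1)

    def test_mle_exposure_includes_censored_windows(self):
        records = make_records([10.0, None])  # 1 event, 10 + 60 s exposure
        est = g.fit_rate_constant(records, method="censored-mle")
        assert est.k_p == pytest.approx(1.0 / 70.0)

    def test_zero_ruptures_is_flagged_lower_bound(self):
        est = g.fit_rate_constant(make_records([None] * 18))
        assert est.k_p == 0.0
        assert est.status == "lower-bound"

    def test_consistency_with_sample_size(self):
        # estimate converges to the truth as n grows
        errors = []
        for n in (100, 1000, 10_000):
            rng = np.random.default_rng(5)
            est = g.fit_rate_constant(simulate_exponential_records(0.05, n, rng))
            errors.append(abs(est.k_p - 0.05))
        assert errors[2] < errors[0]
        assert errors[2] < 0.002

    def test_paper_scale_replicate_average_within_factor_two(self):
        # protocol scale: 18 GUVs x 3 replicates, truth k_p = 1.0e-2
        rng = np.random.default_rng(2)
        hits = 0
        n_runs = 500
        for _ in range(n_runs):
            ests = [
                g.fit_rate_constant(simulate_exponential_records(0.01, 18, rng))
                for _ in range(3)
            ]
            mean_k, _ = g.average_rates(ests)
            hits += 0.005 < mean_k < 0.02
        assert hits / n_runs >= 0.95

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            g.fit_rate_constant(make_records([10.0]), method="km")


class TestAverageRates:
    def test_mean_and_sample_sd(self):
        ests = [
            g.RateEstimate(k, 0.0, "survival-lsq", 5, 18) for k in (0.09, 0.11, 0.13)
        ]
        mean, sd = g.average_rates(ests)
        assert mean == pytest.approx(0.11)
        assert sd == pytest.approx(0.02)

    def test_identical_replicates_zero_sd(self):
        ests = [g.RateEstimate(0.1, 0.0, "survival-lsq", 5, 18)] * 3
        _, sd = g.average_rates(ests)
        assert sd == pytest.approx(0.0)

    def test_single_estimate_has_no_sd(self):
        mean, sd = g.average_rates([g.RateEstimate(0.1, 0.0, "survival-lsq", 5, 18)])
        assert mean == pytest.approx(0.1)
        assert sd is None


class TestFitKineticModel:
    @pytest.mark.parametrize(
        "preset_name, sigmas_mN",
        [
            ("DOPG/DOPC/chol(46/39/15)", (7.3, 8.2, 9.0)),
            ("DOPG/DOPC(40/60)", (5.3, 6.1, 6.8)),
        ],
    )
    def test_noiseless_self_consistency_fixed_B(self, preset_name, sigmas_mN):
        truth = g.KINETIC_PRESETS[preset_name]
        points = [
            (s * 1e-3, g.rate_constant(s * 1e-3, truth)) for s in sigmas_mN
        ]
        fitted, diag = g.fit_kinetic_model(points, fixed_B=truth.electrostatic_term)
        assert fitted.line_tension == pytest.approx(truth.line_tension, rel=0.01)
        assert fitted.prefactor == pytest.approx(truth.prefactor, rel=0.01)
        assert diag["rms_log_residual"] < 1e-6

    def test_free_B_recovers_all_three(self, chol_kinetics):
        sigmas = np.linspace(6e-3, 10e-3, 6)
        points = [(s, g.rate_constant(s, chol_kinetics)) for s in sigmas]
        fitted, _ = g.fit_kinetic_model(points, fixed_B=None)
        assert fitted.electrostatic_term == pytest.approx(
            chol_kinetics.electrostatic_term, rel=0.05
        )
        assert fitted.line_tension == pytest.approx(chol_kinetics.line_tension, rel=0.02)

    def test_underdetermined_rejected(self, chol_kinetics):
        point = [(7e-3, g.rate_constant(7e-3, chol_kinetics))]
        with pytest.raises(ValueError):
            g.fit_kinetic_model(point, fixed_B=chol_kinetics.electrostatic_term)
        with pytest.raises(ValueError):
            g.fit_kinetic_model(point * 2, fixed_B=None)


class TestEstimateShiftTension:
    def test_cholesterol_arm_reproduces_reported_mean(self, chol_kinetics):
        points = [(5.0e-3, 1.0e-2), (6.0e-3, 4.0e-2), (6.5e-3, 1.1e-1)]
        est = g.estimate_shift_tension(points, chol_kinetics)
        assert round(est.mean_shift * 1e3, 1) == 2.3
        assert round(est.sd_shift * 1e3, 1) == 0.2
        # reproduction tolerance on the equivalent-tension column
        for (sc, kp, eq, sh), expected_eq in zip(est.per_point, (7.3, 8.2, 9.0)):
            assert eq * 1e3 == pytest.approx(expected_eq, abs=0.1)

    def test_two_component_arm_reproduces_reported_mean(self, dopg_dopc_kinetics):
        points = [(2.0e-3, 0.9e-2), (2.5e-3, 3.7e-2), (3.0e-3, 1.1e-1)]
        est = g.estimate_shift_tension(points, dopg_dopc_kinetics)
        assert round(est.mean_shift * 1e3, 1) == 3.5
        assert round(est.sd_shift * 1e3, 1) == 0.1

    def test_points_from_baseline_have_zero_shift(self, chol_kinetics):
        points = [
            (s, g.rate_constant(s, chol_kinetics)) for s in (6e-3, 7e-3, 8e-3)
        ]
        est = g.estimate_shift_tension(points, chol_kinetics)
        assert abs(est.mean_shift) < 1e-9
        assert est.sd_shift < 1e-9

    def test_exact_additivity_of_constant_shift(self, dopg_dopc_kinetics):
        shift = 2.7e-3
        points = [
            (s, g.rate_constant(s + shift, dopg_dopc_kinetics))
            for s in (3e-3, 4e-3, 5e-3)
        ]
        est = g.estimate_shift_tension(points, dopg_dopc_kinetics)
        assert est.mean_shift == pytest.approx(shift, rel=1e-6)
        assert est.sd_shift == pytest.approx(0.0, abs=1e-9)

    def test_theory_column_attached_when_inputs_given(self, chol_membrane, chol_kinetics):
        cond = g.OsmoticCondition(C_in0=388.0, C_out=373.0)
        est = g.estimate_shift_tension(
            [(6.5e-3, 1.1e-1)], chol_kinetics, membrane=chol_membrane, condition=cond
        )
        assert round(est.theory * 1e3, 1) == 4.1
        assert est.theory_error is not None

    def test_nonpositive_rate_rejected(self, chol_kinetics):
        with pytest.raises(ValueError):
            g.estimate_shift_tension([(5e-3, 0.0)], chol_kinetics)


class TestLeakagePrediction:
    @pytest.mark.parametrize(
        "sigma_os_mN, expected",
        [(8.0, True), (0.0, False), (7.0, True), (4.1, False)],
    )
    def test_threshold_convention(self, sigma_os_mN, expected):
        assert g.leakage_prediction(sigma_os_mN * 1e-3) is expected
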