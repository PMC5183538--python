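"""Two-step stress estimation: objective, PCSA scaling, recovery, bounds."""

import numpy as np
import pytest
from sklearn.base import clone

from elbowext.errors import ValidationError
from elbowext.optimize import (MaxStressEstimator, OptimizationConfig,
                               fit_step1_common_stress, fit_two_step,
                               objective, optimization_grid, scale_pcsa,
                               torque_basis)
from elbowext.torque import TorqueAngleCurve, predict_extension_torque


class TestObjective:
    def test_grid_has_46_points(self):
        grid = optimization_grid()
        assert grid.size == 46
        assert grid[0] == 10.0 and grid[-1] == 100.0
        assert np.all(np.diff(grid) == 2.0)

    def test_identical_curves_zero(self, grid46):
        c = TorqueAngleCurve(grid46, np.linspace(5, 20, 46))
        assert objective(c, c) == 0.0

    def test_constant_offset_closed_form(self, grid46):
        a = TorqueAngleCurve(grid46, np.full(46, 10.0))
        b = TorqueAngleCurve(grid46, np.full(46, 11.0))
        assert objective(a, b) == pytest.approx(1.0)

    def test_matches_loop_summed_oracle(self, grid46):
        rng = np.random.default_rng(3)
        x, y = rng.normal(10, 3, 46), rng.normal(10, 3, 46)
        total = 0.0
        for xi, yi in zip(x, y):
            total += (xi - yi) ** 2
        assert objective(TorqueAngleCurve(grid46, x),
                         TorqueAngleCurve(grid46, y)) == pytest.approx(total / 46)

    def test_grid_mismatch_rejected(self, grid46):
        a = TorqueAngleCurve(grid46, np.zeros(46))
        b = TorqueAngleCurve(grid46 + 1.0, np.zeros(46))
        with pytest.raises(ValidationError):
            objective(a, b)


class TestScalePCSA:
    def test_equal_circumference_identity(self):
        pcsa = {"MHT": 6.1, "LatHT": 6.0}
        assert scale_pcsa(pcsa, 29.4, 29.4) == pytest.approx(pcsa)

    def test_linear_in_ratio(self):
        out = scale_pcsa({"MHT": 6.1}, 29.4, 29.4 * 1.2)
        assert out["MHT"] == pytest.approx(6.1 * 1.2)

    def test_hand_calculation(self):
        out = scale_pcsa({"LngHT": 6.7}, 29.4, 31.0)
        assert out["LngHT"] == pytest.approx(6.7 * 31.0 / 29.4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            scale_pcsa({"MHT": 6.1}, 0.0, 30.0)
        with pytest.raises(ValidationError):
            scale_pcsa({"MHT": -1.0}, 29.4, 30.0)


class TestBasisLinearity:
    def test_basis_reproduces_forward_model(self, reference_model, reference_subject,
                                            grid46):
        # the forward torque is exactly linear in the per-muscle forces
        _, truth = reference_subject
        G = torque_basis(reference_model, grid46)
        F = np.array([truth.F_z[m] for m in reference_model.muscles])
        direct = predict_extension_torque(reference_model.with_forces(truth.F_z), grid46)
        assert np.max(np.abs(G @ F - direct.torque)) < 1e-10


class TestTwoStepFit:
    def test_step1_recovers_common_stress(self, reference_model, reference_subject,
                                          reference_curve, grid46):
        _, truth = reference_subject
        sigma = fit_step1_common_stress(
            reference_model,
            TorqueAngleCurve(grid46, reference_curve.torque, "measured"),
        )
        true_sigma = np.mean(list(truth.sigma_m.values()))
        assert abs(sigma - true_sigma) / true_sigma < 0.01

    def test_step1_linearity_in_measured_torque(self, reference_model, reference_curve,
                                                grid46):
        s1 = fit_step1_common_stress(
            reference_model, TorqueAngleCurve(grid46, reference_curve.torque, "measured"))
        s2 = fit_step1_common_stress(
            reference_model,
            TorqueAngleCurve(grid46, 2.0 * reference_curve.torque, "measured"))
        assert s2 == pytest.approx(2.0 * s1, rel=1e-4)

    def test_step1_beats_bracket_endpoints(self, reference_model, reference_curve,
                                           grid46):
        est = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        G = est.basis_
        pcsa = np.array([reference_model.params[m].PCSA for m in reference_model.muscles])

        def mse(sigma):
            r = reference_curve.torque - G @ (sigma * pcsa)
            return r @ r / r.size

        assert mse(est.sigma_common_) <= mse(0.5 * est.sigma_common_)
        assert mse(est.sigma_common_) <= mse(2.0 * est.sigma_common_)

    def test_heterogeneous_forces_recovered_noise_free(self, reference_model,
                                                       reference_subject, grid46):
        _, truth = reference_subject
        forces = {m: f * c for (m, f), c in
                  zip(truth.F_z.items(), (1.10, 0.92, 1.05))}
        curve = predict_extension_torque(reference_model.with_forces(forces), grid46)
        est = MaxStressEstimator(reference_model, group="control").fit(grid46, curve.torque)
        for m in reference_model.muscles:
            assert abs(est.forces_[m] - forces[m]) / forces[m] < 0.05

    def test_equal_forces_step2_matches_step1(self, reference_model, reference_curve,
                                              grid46):
        est = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        for m in reference_model.muscles:
            expected = est.sigma_common_ * reference_model.params[m].PCSA
            assert abs(est.forces_[m] - expected) / expected < 0.01

    def test_step2_never_worse_than_step1(self, reference_model, reference_curve,
                                          grid46):
        rng = np.random.default_rng(5)
        noisy = reference_curve.torque + rng.normal(0, 1.0, 46)
        est = MaxStressEstimator(reference_model).fit(grid46, noisy)
        assert est.objective_ <= est.objective_step1_ + 1e-12
        assert est.rms_ == pytest.approx(np.sqrt(est.objective_))

    def test_truth_far_outside_box_pins_at_bound(self, reference_model,
                                                 reference_subject, grid46):
        # one muscle 40% strong: with 15% bounds the fit must ride its
        # upper bound for that muscle
        _, truth = reference_subject
        forces = dict(truth.F_z)
        forces["LngHT"] = truth.F_z["LngHT"] * 1.4
        curve = predict_extension_torque(reference_model.with_forces(forces), grid46)
        est = MaxStressEstimator(reference_model, group="control").fit(grid46, curve.torque)
        lo, hi = est.bounds_["LngHT"]
        assert est.forces_["LngHT"] > lo
        assert est.forces_["LngHT"] == pytest.approx(hi, rel=0.02)

    def test_deterministic_given_inputs(self, reference_model, reference_curve, grid46):
        e1 = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        e2 = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        assert e1.forces_ == e2.forces_
        assert e1.sigma_common_ == e2.sigma_common_

    def test_stroke_group_widens_bounds(self, reference_model, reference_curve, grid46):
        ec = MaxStressEstimator(reference_model, group="control").fit(
            grid46, reference_curve.torque)
        es = MaxStressEstimator(reference_model, group="stroke").fit(
            grid46, reference_curve.torque)
        for m in reference_model.muscles:
            lo_c, hi_c = ec.bounds_[m]
            lo_s, hi_s = es.bounds_[m]
            assert lo_s < lo_c and hi_s > hi_c

    def test_sigma_is_force_over_pcsa(self, reference_model, reference_curve, grid46):
        est = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        for m in reference_model.muscles:
            assert est.sigma_m_[m] == pytest.approx(
                est.forces_[m] / reference_model.params[m].PCSA)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            OptimizationConfig().bounds_fraction("sham")


class TestSklearnInterface:
    def test_get_params_and_clone(self, reference_model):
        est = MaxStressEstimator(reference_model, group="stroke")
        params = est.get_params()
        assert params["group"] == "stroke"
        cloned = clone(est)  # deep-copies non-estimator params
        assert cloned.group == "stroke"
        assert cloned.model.muscles == reference_model.muscles

    def test_predict_matches_fit_grid(self, reference_model, reference_curve, grid46):
        est = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        pred = est.predict(grid46)
        assert np.max(np.abs(pred - reference_curve.torque)) < 1e-6

    def test_result_record_mirrors_estimator(self, reference_model, reference_curve,
                                             grid46):
        res = fit_two_step(
            reference_model,
            TorqueAngleCurve(grid46, reference_curve.torque, "measured"),
        )
        est = MaxStressEstimator(reference_model).fit(grid46, reference_curve.torque)
        assert res.sigma_common == pytest.approx(est.sigma_common_)
        assert res.rms == pytest.approx(est.rms_)
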