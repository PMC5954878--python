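"""Calibration chain evaluation, residuals, and the six-parameter solver."""

import dataclasses

import numpy as np
import pytest

from probecal.calibration import (
    CalibrationParams,
    Observation,
    ProbeCalibration,
    calibrate,
    closed_form_init,
    map_image_to_phantom,
    residual_error,
)
from probecal.geometry import (
    DegenerateConfigurationError,
    EulerZYX,
    RigidTransform,
    euler_zyx_to_transform,
)
from probecal.simulate import (
    AcquisitionPlan,
    NoiseModel,
    simulate_observations,
)

I = RigidTransform.identity()
ZERO_CALIB = CalibrationParams(EulerZYX(0, 0, 0), np.zeros(3))


def make_obs(pixel, scale=(0.1, 0.1), wph=I, pw=I, truth=(0, 0, 0),
             target_id="t"):
    return Observation(target_id=target_id, pixel=np.asarray(pixel, float),
                       scale=np.asarray(scale, float), world_to_phantom=wph,
                       probe_to_world=pw, truth_phantom=np.asarray(truth, float))


class TestObservation:
    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError, match="scale"):
            make_obs((1, 1), scale=(0.1, 0.0))

    def test_rejects_negative_pixel(self):
        with pytest.raises(ValueError, match="pixel"):
            make_obs((-1, 1))

    def test_image_point_scales_to_mm(self):
        obs = make_obs((10, 20), scale=(0.1, 0.2))
        assert np.allclose(obs.image_point_mm, [1.0, 4.0, 0.0])


class TestCalibrationParams:
    def test_transform_round_trip(self, rng):
        # beta drawn within the canonical extraction branch (-pi/2, pi/2)
        for _ in range(10):
            a, g = rng.uniform(-3, 3, 2)
            b = rng.uniform(-1.4, 1.4)
            p = CalibrationParams(EulerZYX(a, b, g), rng.uniform(-50, 50, 3))
            back = CalibrationParams.from_transform(p.as_transform())
            assert np.allclose(back.as_vector(), p.as_vector(), atol=1e-9)
            assert back.as_transform().almost_equal(p.as_transform())

    def test_dict_round_trip_uses_degrees(self):
        p = CalibrationParams(EulerZYX.from_degrees(93, -2, 87.5),
                              np.array([3.7, -21.4, 12.9]))
        d = p.to_dict()
        assert d["alpha_deg"] == pytest.approx(93.0)
        back = CalibrationParams.from_dict(d)
        assert np.allclose(back.as_vector(), p.as_vector(), atol=1e-12)


class TestMapImageToPhantom:
    def test_pure_scaling(self):
        obs = make_obs((10, 20))
        assert np.allclose(map_image_to_phantom(obs, ZERO_CALIB),
                           [1.0, 2.0, 0.0])

    def test_phantom_translation_adds(self):
        obs = make_obs((10, 20),
                       wph=RigidTransform.from_translation([0, 0, 5]))
        assert np.allclose(map_image_to_phantom(obs, ZERO_CALIB),
                           [1.0, 2.0, 5.0])

    def test_matches_sequential_apply_oracle(self, rng):
        for _ in range(10):
            def rand_T():
                return euler_zyx_to_transform(EulerZYX(*rng.uniform(-3, 3, 3)),
                                              rng.uniform(-80, 80, 3))
            calib = CalibrationParams(EulerZYX(*rng.uniform(-3, 3, 3)),
                                      rng.uniform(-40, 40, 3))
            obs = make_obs(rng.uniform(0, 400, 2), scale=(0.12, 0.15),
                           wph=rand_T(), pw=rand_T())
            expected = obs.world_to_phantom.apply(obs.probe_to_world.apply(
                calib.as_transform().apply(obs.image_point_mm)))
            assert np.allclose(map_image_to_phantom(obs, calib), expected,
                               atol=1e-9)


class TestResidualError:
    def test_single_offset_observation(self):
        obs = make_obs((10, 20), truth=(1.0, 2.0, 1.0))  # mapped = (1, 2, 0)
        assert residual_error([obs], ZERO_CALIB) == pytest.approx(1.0)

    def test_mean_of_distances(self):
        obs = [make_obs((0, 0), truth=(d, 0, 0)) for d in (1.0, 2.0, 3.0)]
        assert residual_error(obs, ZERO_CALIB) == pytest.approx(2.0)

    def test_zero_at_ground_truth(self, truth, noiseless_obs):
        assert residual_error(noiseless_obs, truth.true_calib) <= 1e-9

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            residual_error([], ZERO_CALIB)


class TestClosedFormInit:
    def test_recovers_truth_on_noiseless_data(self, truth, noiseless_obs):
        init = closed_form_init(noiseless_obs)
        err = np.abs(init.as_vector() - truth.true_calib.as_vector())
        assert np.all(err[:3] < 1e-6) and np.all(err[3:] < 1e-6)

    def test_within_2x_of_refined_optimum_under_noise(self, truth):
        plan = AcquisitionPlan("cross_wire", "full_fov")
        noise = NoiseModel(seg_sigma_px=0.5 / 0.1875, diode_sigma_mm=0.0,
                           seed=11)
        obs = simulate_observations(truth, plan, noise)
        d_init = residual_error(obs, closed_form_init(obs))
        d_opt = calibrate(obs).residual_mm
        assert d_init <= 2.0 * d_opt

    def test_collinear_image_points_raise(self):
        obs = [make_obs((10 * k, 20 * k), truth=(k, 0, 0), target_id=str(k))
               for k in range(5)]
        with pytest.raises(DegenerateConfigurationError):
            closed_form_init(obs)

    def test_too_few_observations_raise(self):
        with pytest.raises(DegenerateConfigurationError):
            closed_form_init([make_obs((1, 1)), make_obs((2, 1))])


class TestCalibrate:
    def test_noiseless_recovery(self, truth, noiseless_obs):
        res = calibrate(noiseless_obs)
        err = np.abs(res.params.as_vector() - truth.true_calib.as_vector())
        assert np.all(err[:3] < 1e-6)      # rad
        assert np.all(err[3:] < 1e-3)      # mm
        assert res.residual_mm <= 1e-6
        assert res.converged and res.n_targets == 40

    def test_agrees_with_closed_form_on_noiseless_data(self, noiseless_obs):
        res = calibrate(noiseless_obs)
        init = closed_form_init(noiseless_obs)
        assert np.allclose(res.params.as_vector(), init.as_vector(),
                           atol=1e-6)

    def test_basin_robustness_to_perturbed_start(self, noiseless_obs):
        res0 = calibrate(noiseless_obs)
        shift = np.concatenate([np.radians([5.0, 5.0, 5.0]), [5.0, 5.0, 5.0]])
        start = CalibrationParams.from_vector(res0.params.as_vector() + shift)
        res1 = ProbeCalibration(noiseless_obs).fit(start=start)
        assert np.allclose(res1.params.as_vector(), res0.params.as_vector(),
                           atol=1e-8)

    def test_deterministic_given_identical_inputs(self, noiseless_obs):
        a = calibrate(noiseless_obs)
        b = calibrate(noiseless_obs)
        assert np.array_equal(a.params.as_vector(), b.params.as_vector())

    def test_local_optimality_on_coarse_grid(self, truth):
        noise = NoiseModel(seg_sigma_px=2.0, diode_sigma_mm=0.1, seed=5)
        obs = simulate_observations(
            truth, AcquisitionPlan("cross_wire", "full_fov"), noise)
        model = ProbeCalibration(obs)
        res = model.fit()
        d_opt = res.residual_mm
        v = res.params.as_vector()
        steps = np.concatenate([np.radians([0.5] * 3), [0.5] * 3])
        for j in range(6):
            for s in (-1.0, 1.0):
                v2 = v.copy()
                v2[j] += s * steps[j]
                assert model.residual_mm(
                    CalibrationParams.from_vector(v2)) >= d_opt

    def test_equivariant_under_phantom_frame_change(self, noiseless_obs):
        G = euler_zyx_to_transform(EulerZYX.from_degrees(20, 10, -30),
                                   (50.0, -20.0, 80.0))
        moved = [dataclasses.replace(
            o, world_to_phantom=G @ o.world_to_phantom,
            truth_phantom=G.apply(o.truth_phantom)) for o in noiseless_obs]
        res0, res1 = calibrate(noiseless_obs), calibrate(moved)
        assert np.allclose(res0.params.as_vector(), res1.params.as_vector(),
                           atol=1e-9)

    def test_translation_rmse_degrades_monotonically_with_noise(self, truth):
        plan = AcquisitionPlan("cross_wire", "full_fov")
        t_true = truth.true_calib.translation
        rmses = []
        for sigma_mm in (0.0, 0.25, 0.5, 1.0):
            sq = []
            for rep in range(20):
                noise = NoiseModel(seg_sigma_px=sigma_mm / 0.1875,
                                   diode_sigma_mm=0.0, seed=900 + rep)
                obs = simulate_observations(truth, plan, noise)
                res = ProbeCalibration(obs).fit()
                sq.append(np.sum((res.params.translation - t_true) ** 2))
            rmses.append(np.sqrt(np.mean(sq)))
        assert all(a <= b for a, b in zip(rmses, rmses[1:]))

    def test_requires_three_observations(self):
        with pytest.raises(DegenerateConfigurationError):
            ProbeCalibration([make_obs((1, 1)), make_obs((2, 2))])


class TestResultObject:
    def test_summary_reports_parameters_and_diagnostics(self, noiseless_obs):
        res = calibrate(noiseless_obs)
        text = res.summary()
        for token in ("alpha (deg)", "z (mm)", "residual D", "n targets"):
            assert token in text

    def test_standard_errors_positive_under_noise(self, truth):
        noise = NoiseModel(seg_sigma_px=2.0, diode_sigma_mm=0.1, seed=3)
        obs = simulate_observations(
            truth, AcquisitionPlan("cross_wire", "full_fov"), noise)
        res = calibrate(obs)
        assert np.all(res.bse > 0) and np.all(np.isfinite(res.bse))

    def test_to_dict_round_trips_transform(self, noiseless_obs):
        res = calibrate(noiseless_obs)
        d = res.to_dict()
        T = RigidTransform.from_flat(d["matrix_row_major"])
        assert T.almost_equal(res.params.as_transform(), atol=1e-9)
        assert d["n_targets"] == 40
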