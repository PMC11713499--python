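import numpy as np
import pytest

from sctqa import (
    BeamSpec,
    BinaryMask,
    ErrorModel,
    PhantomSpec,
    ScalarVolume,
    apply_error_model,
    build_anatomy,
    compute_mae,
    compute_me,
    compute_toy_dose,
    generate_case,
)


class TestAnatomy:
    def test_head_center_is_soft_tissue(self, small_spec):
        ct, _ = build_anatomy(PhantomSpec(grid_shape=(32, 36, 32),
                                          spacing=(5, 5, 5),
                                          air_cavity_radii=()))
        center = tuple(n // 2 for n in ct.shape)
        assert ct.values[center] == pytest.approx(40.0)

    def test_body_excludes_background_air(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        background = ct.values <= small_spec.hu_air + 50
        assert not np.any(structs["BODY"].values & background)

    def test_skull_shell_entirely_bone(self, small_spec):
        ct, _ = build_anatomy(small_spec)
        shell = (ct.values > 200)
        assert np.all(ct.values[shell] == small_spec.hu_bone)
        assert shell.any()

    def test_structures_present(self, small_spec):
        _, structs = build_anatomy(small_spec)
        assert {"BODY", "PTV", "brainstem", "lens"} <= set(structs)
        assert all(m.voxel_count > 0 for m in structs.values())

    def test_target_outside_body_rejected(self, small_spec):
        bad = PhantomSpec(grid_shape=(32, 36, 32), spacing=(5, 5, 5),
                          target_offset=(0, 0, 200))
        with pytest.raises(ValueError):
            build_anatomy(bad)

    def test_invalid_hu_ordering_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(hu_soft=1000, hu_bone=900)


class TestErrorModel:
    def test_identity_model_is_noop(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        out = apply_error_model(ct, structs["BODY"], ErrorModel(), seed=1)
        assert np.array_equal(out.values, ct.values)

    def test_bias_recovered_exactly_as_me(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        out = apply_error_model(ct, structs["BODY"],
                                ErrorModel(global_bias=25.0), seed=1)
        assert compute_me(ct, out, structs["BODY"]) == pytest.approx(25.0)

    def test_outside_body_unchanged(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        model = ErrorModel(global_bias=100.0, noise_sigma=30.0,
                           contour_shift=4.0)
        out = apply_error_model(ct, structs["BODY"], model, seed=1)
        outside = ~structs["BODY"].values
        assert np.array_equal(out.values[outside], ct.values[outside])

    def test_noise_mae_matches_half_normal_mean(self):
        # |N(0, sigma)| has mean sigma * sqrt(2/pi)
        spec = PhantomSpec(grid_shape=(72, 80, 72), spacing=(2.5, 2.5, 2.5),
                           seed=11)
        ct, structs = build_anatomy(spec)
        body = structs["BODY"]
        assert body.voxel_count > 100_000
        out = apply_error_model(ct, body, ErrorModel(noise_sigma=50.0), seed=5)
        expected = 50.0 * np.sqrt(2 / np.pi)
        assert compute_mae(ct, out, body) == pytest.approx(expected, rel=0.01)

    def test_mae_monotone_in_bias(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        maes = []
        for bias in (0.0, 10.0, 25.0, 60.0, 120.0):
            out = apply_error_model(ct, structs["BODY"],
                                    ErrorModel(global_bias=bias), seed=1)
            maes.append(compute_mae(ct, out, structs["BODY"]))
        assert all(b > a for a, b in zip(maes, maes[1:]))

    def test_bone_dilation_grows_bone_compartment(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        out = apply_error_model(ct, structs["BODY"],
                                ErrorModel(bone_dilation=6.0), seed=1)
        assert np.count_nonzero(out.values > 200) > np.count_nonzero(
            ct.values > 200)

    def test_metal_artifact_carves_void(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        model = ErrorModel(metal_artifact=((0.0, 0.0, 0.0), 15.0, -950.0))
        out = apply_error_model(ct, structs["BODY"], model, seed=1)
        center = tuple(n // 2 for n in ct.shape)
        assert out.values[center] == -950.0

    def test_deterministic_given_seed(self, small_spec):
        ct, structs = build_anatomy(small_spec)
        model = ErrorModel(global_bias=10, noise_sigma=30)
        a = apply_error_model(ct, structs["BODY"], model, seed=9)
        b = apply_error_model(ct, structs["BODY"], model, seed=9)
        assert np.array_equal(a.values, b.values)


class TestToyDose:
    def test_vacuum_ray_no_attenuation(self):
        # a body of pure air attenuates nothing: dose stays at entrance
        values = np.full((10, 3, 3), -1000.0)
        ct = ScalarVolume(values, spacing=(5, 5, 5), origin=(0, 0, 0))
        body = BinaryMask("BODY", np.ones(ct.shape, dtype=bool), ct.spacing,
                          ct.origin)
        dose = compute_toy_dose(ct, BeamSpec(direction=0, entrance_dose=60.0),
                                body=body)
        assert np.allclose(dose.values, 60.0)

    def test_water_exponential_closed_form(self):
        # water body, mu = 0.005/mm: at 100 mm depth dose = D0 * e^-0.5
        values = np.zeros((16, 3, 3))
        ct = ScalarVolume(values, spacing=(8, 8, 8), origin=(0, 0, 0))
        body = BinaryMask("BODY", np.ones(ct.shape, dtype=bool), ct.spacing,
                          ct.origin)
        beam = BeamSpec(direction=0, entrance_dose=60.0,
                        attenuation_scale=0.005)
        dose = compute_toy_dose(ct, beam, body=body)
        # midpoint rule: voxel 12 sits at radiological depth 12.5 * 8 = 100
        assert dose.values[12, 1, 1] == pytest.approx(60.0 * np.exp(-0.5))

    def test_hu_offset_dose_ratio_closed_form(self):
        shape = (16, 3, 3)
        spacing = (8.0, 8.0, 8.0)
        body = BinaryMask("BODY", np.ones(shape, dtype=bool), spacing,
                          (0, 0, 0))
        beam = BeamSpec(direction=0, entrance_dose=60.0,
                        attenuation_scale=0.005)
        d0 = compute_toy_dose(ScalarVolume(np.zeros(shape), spacing,
                                           (0, 0, 0)), beam, body=body)
        d1 = compute_toy_dose(ScalarVolume(np.full(shape, 1000.0), spacing,
                                           (0, 0, 0)), beam, body=body)
        # +1000 HU doubles density: extra attenuation e^(-mu * depth)
        i = 12
        depth = (i + 0.5) * 8.0
        ratio = d1.values[i, 1, 1] / d0.values[i, 1, 1]
        assert ratio == pytest.approx(np.exp(-0.005 * depth))

    def test_monotone_nonincreasing_along_ray_in_body(self, identity_case):
        dose = identity_case.dose_reference.values
        body = identity_case.structures["BODY"].values
        for j, k in [(18, 16), (14, 20)]:
            ray = dose[:, j, k]
            inside = body[:, j, k]
            vals = ray[inside]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_dose_zero_outside_body(self, identity_case):
        outside = ~identity_case.structures["BODY"].values
        assert np.all(identity_case.dose_reference.values[outside] == 0.0)


class TestGenerateCase:
    def test_identity_model_equal_doses(self, identity_case):
        assert np.array_equal(identity_case.dose_reference.values,
                              identity_case.dose_evaluated.values)

    def test_bit_identical_regeneration(self, small_spec):
        model = ErrorModel(global_bias=20, noise_sigma=35, bone_dilation=4)
        a = generate_case(small_spec, model, BeamSpec())
        b = generate_case(small_spec, model, BeamSpec())
        assert np.array_equal(a.synthetic_ct.values, b.synthetic_ct.values)
        assert np.array_equal(a.dose_evaluated.values, b.dose_evaluated.values)
        assert a.prescription_dose == b.prescription_dose

    def test_prescription_defaults_to_ptv_mean(self, identity_case):
        ptv = identity_case.structures["PTV"].values
        expected = identity_case.dose_reference.values[ptv].mean()
        assert identity_case.prescription_dose == pytest.approx(expected)
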