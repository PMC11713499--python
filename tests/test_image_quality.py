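import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sctqa import (
    ScalarVolume,
    SSIMConstants,
    compute_mae,
    compute_me,
    compute_psnr,
    compute_rmse,
    compute_ssim,
    quality_report,
)
from sctqa.grids import BinaryMask
from sctqa.image_quality import EmptyROIError


def _pair_from_lists(p, s):
    """Two-voxel-wide volumes holding the given value lists."""
    arr_p = np.asarray(p, dtype=float).reshape(-1, 1, 1)
    arr_s = np.asarray(s, dtype=float).reshape(-1, 1, 1)
    grid = dict(spacing=(1, 1, 1), origin=(0, 0, 0))
    return ScalarVolume(arr_p, **grid), ScalarVolume(arr_s, **grid)


class TestErrorMetrics:
    def test_identical_inputs_all_zero(self, unit_volume):
        assert compute_me(unit_volume, unit_volume) == 0.0
        assert compute_mae(unit_volume, unit_volume) == 0.0
        assert compute_rmse(unit_volume, unit_volume) == 0.0

    def test_constant_offset(self, unit_volume):
        sct = unit_volume.with_values(unit_volume.values + 10.0)
        assert compute_me(unit_volume, sct) == pytest.approx(10.0)
        assert compute_rmse(unit_volume, sct) == pytest.approx(10.0)

    def test_two_voxel_enumeration(self):
        # pct = (0, 100), sct = (10, -30):
        #   ME  = (10 - 130) / 2 = -60
        #   MAE = (10 + 130) / 2 = 70
        #   RMSE = sqrt((100 + 16900) / 2) = sqrt(8500)
        pct, sct = _pair_from_lists([0, 100], [10, -30])
        assert compute_me(pct, sct) == pytest.approx(-60.0)
        assert compute_mae(pct, sct) == pytest.approx(70.0)
        assert compute_rmse(pct, sct) == pytest.approx(math.sqrt(8500))

    def test_me_antisymmetric_mae_rmse_symmetric(self):
        rng = np.random.default_rng(4)
        pct, sct = _pair_from_lists(rng.normal(0, 50, 40),
                                    rng.normal(10, 80, 40))
        assert compute_me(pct, sct) == pytest.approx(-compute_me(sct, pct))
        assert compute_mae(pct, sct) == pytest.approx(compute_mae(sct, pct))
        assert compute_rmse(pct, sct) == pytest.approx(compute_rmse(sct, pct))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_ordering_chain(self, seed):
        rng = np.random.default_rng(seed)
        pct, sct = _pair_from_lists(rng.normal(0, 100, 30),
                                    rng.normal(20, 100, 30))
        me = compute_me(pct, sct)
        mae = compute_mae(pct, sct)
        rmse = compute_rmse(pct, sct)
        assert rmse + 1e-12 >= mae >= abs(me) - 1e-12

    def test_empty_roi_rejected(self, unit_volume):
        roi = BinaryMask("ROI", np.zeros(unit_volume.shape, dtype=bool),
                         unit_volume.spacing, unit_volume.origin)
        with pytest.raises(EmptyROIError):
            compute_me(unit_volume, unit_volume, roi)

    def test_roi_restricts_computation(self, unit_volume):
        sct = unit_volume.with_values(unit_volume.values.copy())
        sct.values[0, 0, 0] += 1000.0
        roi_vals = np.ones(unit_volume.shape, dtype=bool)
        roi_vals[0, 0, 0] = False
        roi = BinaryMask("ROI", roi_vals, unit_volume.spacing,
                         unit_volume.origin)
        assert compute_mae(unit_volume, sct, roi) == 0.0


class TestPSNR:
    def test_identical_inputs_infinite_sentinel(self, unit_volume):
        assert compute_psnr(unit_volume, unit_volume) == math.inf

    def test_closed_form_20db(self):
        # peak 1000, RMSE 100 -> 10 log10(1000^2 / 100^2) = 20 dB
        pct, sct = _pair_from_lists([0, 0], [100, -100])
        assert compute_psnr(pct, sct, peak=1000.0) == pytest.approx(20.0)

    def test_doubling_rmse_drops_about_6db(self):
        pct1, sct1 = _pair_from_lists([0, 0], [100, -100])
        pct2, sct2 = _pair_from_lists([0, 0], [200, -200])
        drop = (compute_psnr(pct1, sct1, peak=1000.0)
                - compute_psnr(pct2, sct2, peak=1000.0))
        assert drop == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_default_peak_is_sct_max(self):
        pct, sct = _pair_from_lists([0, 0, 0], [500, 100, -100])
        mse = np.mean([500.0**2, 100.0**2, 100.0**2])
        expected = 10 * math.log10(500.0**2 / mse)
        assert compute_psnr(pct, sct) == pytest.approx(expected)

    def test_strictly_decreasing_in_mse(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 30, 50)
        psnrs = [
            compute_psnr(*_pair_from_lists(base, base + delta), peak=1000.0)
            for delta in (rng.normal(0, s, 50) for s in (10, 40, 160))
        ]
        assert psnrs[0] > psnrs[1] > psnrs[2]


class TestSSIM:
    def test_identical_inputs_unity(self, unit_volume):
        assert compute_ssim(unit_volume, unit_volume) == pytest.approx(1.0)

    def test_equal_constant_volumes_unity(self):
        pct, sct = _pair_from_lists([50.0] * 8, [50.0] * 8)
        assert compute_ssim(pct, sct) == pytest.approx(1.0)

    def test_anticorrelated_limit_approaches_minus_one(self):
        # sct = -pct, zero mean, variance >> C2: formula tends to -1
        x = np.linspace(-500, 500, 64)
        pct, sct = _pair_from_lists(x, -x)
        val = compute_ssim(pct, sct,
                           constants=SSIMConstants(dynamic_range=1.0))
        assert val == pytest.approx(-1.0, abs=1e-3)

    def test_result_within_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            pct, sct = _pair_from_lists(rng.normal(0, 100, 60),
                                        rng.normal(0, 100, 60))
            assert -1.0 <= compute_ssim(pct, sct) <= 1.0

    def test_windowed_mode_shift_invariance_under_normalization(self):
        # min-max pre-normalisation removes a common additive constant, so
        # windowed SSIM computed on normalised inputs is shift-invariant
        # (raw SSIM is not: its luminance term depends on absolute means)
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 50, size=(12, 12, 12))
        grid = dict(spacing=(1, 1, 1), origin=(0, 0, 0))
        pct = ScalarVolume(vals, **grid)
        sct = ScalarVolume(vals + rng.normal(0, 10, size=vals.shape), **grid)
        a = compute_ssim(pct, sct, mode="windowed", normalize=True)
        b = compute_ssim(pct.with_values(pct.values + 300.0),
                         sct.with_values(sct.values + 300.0),
                         mode="windowed", normalize=True)
        assert a == pytest.approx(b, abs=1e-9)

    def test_windowed_less_than_one_for_noisy_pair(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 50, size=(10, 10, 10))
        grid = dict(spacing=(1, 1, 1), origin=(0, 0, 0))
        pct = ScalarVolume(vals, **grid)
        sct = ScalarVolume(vals + rng.normal(0, 25, size=vals.shape), **grid)
        assert compute_ssim(pct, sct, mode="windowed") < 1.0


class TestQualityReport:
    def test_bias_only_phantom_recovery(self, bias_case):
        body = bias_case.structures["BODY"]
        report = quality_report(bias_case.planning_ct, bias_case.synthetic_ct,
                                roi=body)
        assert report.me == pytest.approx(25.0)
        assert report.mae == pytest.approx(25.0)
        assert report.rmse == pytest.approx(25.0)
        assert report.roi_voxels == body.voxel_count

    def test_identity_report(self, identity_case):
        report = quality_report(identity_case.planning_ct,
                                identity_case.synthetic_ct)
        assert (report.me, report.mae, report.rmse) == (0.0, 0.0, 0.0)
        assert report.psnr == math.inf
        assert report.ssim == pytest.approx(1.0)

    def test_report_invariants(self, small_spec):
        from sctqa import BeamSpec, ErrorModel, generate_case

        case = generate_case(small_spec,
                             ErrorModel(global_bias=20, noise_sigma=40),
                             BeamSpec())
        r = quality_report(case.planning_ct, case.synthetic_ct,
                           roi=case.structures["BODY"])
        assert r.rmse >= r.mae >= abs(r.me)
        assert r.roi_voxels > 0
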