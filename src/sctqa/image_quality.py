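"""HU-based image-quality metrics for a planning/synthetic CT pair.

Five voxel-wise summaries over a stated ROI: mean error (ME, signed, HU),
mean absolute error (MAE, HU), root-mean-squared error (RMSE, HU), peak
signal-to-noise ratio (PSNR, dB) and the structural similarity index (SSIM,
dimensionless in [-1, 1]).  Sign convention: ME > 0 means the synthetic CT
is on average *higher* in HU than the planning CT.

PSNR uses ``10*log10(peak^2 / MSE)`` with the peak defaulting to the
maximum synthetic-CT value inside the ROI.  SSIM is offered in two modes:
``global`` evaluates the index once from ROI-wide moments (one scalar per
case); ``windowed`` averages local-window SSIM (scikit-image) over the ROI,
the convention of the image-processing literature.  An optional min-max
normalisation of both images to [0, 1] before PSNR/SSIM is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .grids import BinaryMask, ScalarVolume


class EmptyROIError(ValueError):
    """The ROI selects no voxels."""


@dataclass
class SSIMConstants:
    """Stabilisation constants for SSIM: C1 = (k1*L)^2, C2 = (k2*L)^2.

    ``dynamic_range`` (L) defaults to the observed planning-CT range over
    the ROI when left as None.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")
        if self.dynamic_range is not None and self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")

    def c1c2(self, observed_range: float):
        L = self.dynamic_range if self.dynamic_range is not None else observed_range
        if L <= 0:
            L = 1.0  # two constant equal images; constants only stabilise
        return (self.k1 * L) ** 2, (self.k2 * L) ** 2


@dataclass
class QualityReport:
    """One case's image-quality summary."""

    me: float
    mae: float
    rmse: float
    psnr: float
    ssim: float
    roi_voxels: int

    def as_dict(self) -> dict:
        return {
            "me_hu": self.me,
            "mae_hu": self.mae,
            "rmse_hu": self.rmse,
            "psnr_db": self.psnr,
            "ssim": self.ssim,
            "roi_voxels": self.roi_voxels,
        }


def _roi_values(pct: ScalarVolume, sct: ScalarVolume, roi: BinaryMask | None):
    if not pct.same_grid(sct):
        raise ValueError("planning and synthetic CT must share one grid")
    if roi is None:
        return pct.values.ravel(), sct.values.ravel()
    roi.check_compatible(pct)
    if roi.voxel_count == 0:
        raise EmptyROIError("ROI selects no voxels")
    sel = roi.values
    return pct.values[sel], sct.values[sel]


def compute_me(pct, sct, roi=None) -> float:
    """Mean signed error (sCT - pCT) in HU over the ROI."""
    p, s = _roi_values(pct, sct, roi)
    return float(np.mean(s - p))


def compute_mae(pct, sct, roi=None) -> float:
    """Mean absolute error in HU over the ROI."""
    p, s = _roi_values(pct, sct, roi)
    return float(np.mean(np.abs(s - p)))


def compute_rmse(pct, sct, roi=None) -> float:
    """Root-mean-squared error in HU over the ROI."""
    p, s = _roi_values(pct, sct, roi)
    return float(np.sqrt(np.mean((s - p) ** 2)))


def compute_psnr(pct, sct, roi=None, peak: float | None = None,
                 normalize: bool = False) -> float:
    """Peak signal-to-noise ratio in dB.

    ``peak`` defaults to the maximum synthetic-CT value over the ROI (or to
    1 when ``normalize`` is set).  Identical inputs have zero MSE and return
    ``math.inf`` — callers should treat the infinity as the 'identical
    inputs' sentinel.
    """
    p, s = _roi_values(pct, sct, roi)
    if normalize:
        p, s = _minmax_pair(p, s)
        if peak is None:
            peak = 1.0
    if peak is None:
        peak = float(np.max(s))
    mse = float(np.mean((s - p) ** 2))
    if mse == 0.0:
        return math.inf
    if peak <= 0:
        raise ValueError("PSNR peak must be positive")
    return float(10.0 * np.log10(peak**2 / mse))


def _minmax_pair(p: np.ndarray, s: np.ndarray):
    lo = min(p.min(), s.min())
    hi = max(p.max(), s.max())
    if hi == lo:
        return np.zeros_like(p), np.zeros_like(s)
    return (p - lo) / (hi - lo), (s - lo) / (hi - lo)


def compute_ssim(pct, sct, roi=None, constants: SSIMConstants | None = None,
                 mode: str = "global", normalize: bool = False) -> float:
    """Structural similarity between the CT pair over the ROI.

    global mode
        One evaluation of the SSIM formula from ROI-wide means, standard
        deviations and cross-covariance — a single scalar per case.
    windowed mode
        Mean of local-window SSIM (7-voxel 3D windows via scikit-image)
        restricted to the ROI.
    """
    constants = constants or SSIMConstants()
    p, s = _roi_values(pct, sct, roi)
    if normalize:
        p, s = _minmax_pair(p, s)

    if mode == "global":
        observed = float(max(p.max(), s.max()) - min(p.min(), s.min()))
        c1, c2 = constants.c1c2(observed)
        mu_p, mu_s = float(p.mean()), float(s.mean())
        var_p, var_s = float(p.var()), float(s.var())
        cov = float(np.mean((p - mu_p) * (s - mu_s)))
        num = (2 * mu_s * mu_p + c1) * (2 * cov + c2)
        den = (mu_s**2 + mu_p**2 + c1) * (var_s + var_p + c2)
        return float(num / den)
    if mode == "windowed":
        pv, sv = pct.values, sct.values
        if normalize:
            flat_p, flat_s = _minmax_pair(pv.ravel(), sv.ravel())
            pv, sv = flat_p.reshape(pv.shape), flat_s.reshape(sv.shape)
        observed = float(max(pv.max(), sv.max()) - min(pv.min(), sv.min()))
        c1_ref, _ = constants.c1c2(observed)
        L = math.sqrt(c1_ref) / constants.k1
        _, ssim_map = structural_similarity(
            pv, sv, data_range=L, K1=constants.k1, K2=constants.k2,
            full=True,
        )
        if roi is None:
            return float(ssim_map.mean())
        return float(ssim_map[roi.values].mean())
    raise ValueError(f"unknown SSIM mode {mode!r}")


def quality_report(pct, sct, roi=None, constants: SSIMConstants | None = None,
                   ssim_mode: str = "global", psnr_peak: float | None = None,
                   normalize: bool = False) -> QualityReport:
    """All five metrics for one CT pair over one ROI."""
    p, _ = _roi_values(pct, sct, roi)  # validates grids and ROI once
    return QualityReport(
        me=compute_me(pct, sct, roi),
        mae=compute_mae(pct, sct, roi),
        rmse=compute_rmse(pct, sct, roi),
        psnr=compute_psnr(pct, sct, roi, peak=psnr_peak, normalize=normalize),
        ssim=compute_ssim(pct, sct, roi, constants=constants, mode=ssim_mode,
                          normalize=normalize),
        roi_voxels=int(p.size),
    )
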