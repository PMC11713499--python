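"""Digital head phantom: paired CT volumes, a controlled conversion-error
model, and a toy parallel-beam dose engine.

The generator produces :class:`~sctqa.grids.CaseBundle` objects with the
statistical structure the QA pipeline assumes: a planning-CT-like head
(ellipsoidal soft tissue, a skull shell, air cavities), a "synthetic CT"
derived from it by an explicit error model (global HU bias, Gaussian noise,
bone-interface misclassification, facial-contour distortion, optional
signal-void artifact), and dose grids computed on each CT so that HU errors
propagate to dose errors.  The dose engine is a declared toy — exponential
attenuation of a parallel beam along an axis, with radiological depth
integrating relative electron density ``rho(HU) = max(0, 1 + HU/1000)`` — not
a clinical algorithm; it preserves exactly the property the pipeline must
detect, namely that HU perturbations along the beam path perturb dose.

All randomness is driven by explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, CaseBundle, GridMismatchError, ScalarVolume

#: HU threshold above which a voxel counts as bone for morphology purposes
BONE_HU_THRESHOLD = 200.0
#: margin above background air used to derive the BODY mask
BODY_HU_MARGIN = 50.0


@dataclass
class PhantomSpec:
    """Geometry and tissue HU of the digital head.

    Defaults give a ~14 x 17 x 15 cm head on a 4 mm grid — coarse enough for
    desk-scale runs while keeping >= 2 voxels across the skull shell.
    """

    grid_shape: tuple = (48, 56, 48)
    spacing: tuple = (4.0, 4.0, 4.0)
    head_radii: tuple = (70.0, 85.0, 75.0)
    skull_thickness: float = 8.0
    air_cavity_radii: tuple = (12.0,)
    hu_soft: float = 40.0
    hu_bone: float = 900.0
    hu_air: float = -1000.0
    target_offset: tuple = (0.0, 0.0, 15.0)   # PTV center relative to head center, mm
    target_radius: float = 18.0
    oar_offsets: dict = field(default_factory=lambda: {
        "brainstem": ((0.0, -30.0, -25.0), 12.0),
        "lens": ((25.0, 55.0, 10.0), 6.0),
    })
    seed: int = 0

    def __post_init__(self):
        if not (self.hu_air <= -900):
            raise ValueError("hu_air must be <= -900")
        if not (self.hu_bone > self.hu_soft > self.hu_air):
            raise ValueError("require hu_bone > hu_soft > hu_air")
        if self.skull_thickness >= min(self.head_radii):
            raise ValueError("skull_thickness must be < min(head_radii)")


@dataclass
class ErrorModel:
    """Controlled conversion-error field turning a planning CT into a
    synthetic CT.

    global_bias : HU added uniformly inside BODY.
    noise_sigma : sd of i.i.d. Gaussian HU noise inside BODY (>= 0).
    bone_dilation : mm; signed radius of the spherical structuring element
        used to dilate (positive) or erode (negative) the bone compartment,
        reassigning hu_bone / hu_soft at the interface.
    contour_shift : mm; translation of the body content along axis 0,
        emulating facial-contour distortion.
    metal_artifact : optional ``(center_mm, radius_mm, hu_value)`` sphere
        carved into the synthetic CT (signal void).
    """

    global_bias: float = 0.0
    noise_sigma: float = 0.0
    bone_dilation: float = 0.0
    contour_shift: float = 0.0
    metal_artifact: Optional[tuple] = None

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def is_identity(self) -> bool:
        return (
            self.global_bias == 0
            and self.noise_sigma == 0
            and self.bone_dilation == 0
            and self.contour_shift == 0
            and self.metal_artifact is None
        )


@dataclass
class BeamSpec:
    """Parallel beam for the toy dose engine."""

    direction: int = 0                  # array axis the beam travels along
    entrance_dose: float = 60.0         # Gy at the body surface
    attenuation_scale: float = 0.004    # per mm at water density
    target_center: Optional[tuple] = None   # world mm; defaults to PTV center
    target_radius: float = 18.0

    def __post_init__(self):
        if self.entrance_dose <= 0 or self.attenuation_scale <= 0:
            raise ValueError("entrance_dose and attenuation_scale must be > 0")
        if self.direction not in (0, 1, 2):
            raise ValueError("direction must be an axis index 0, 1 or 2")


def _ellipsoid(world: np.ndarray, center: np.ndarray, radii) -> np.ndarray:
    d = (world - center) / np.asarray(radii, dtype=float)
    return np.einsum("...i,...i->...", d, d) <= 1.0


def _world_grid(shape, spacing, origin) -> np.ndarray:
    axes = [np.arange(n, dtype=float) * s + o
            for n, s, o in zip(shape, spacing, origin)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    return np.stack([ii, jj, kk], axis=-1)


def build_anatomy(spec: PhantomSpec):
    """Construct the planning-CT-like volume and its structure masks.

    Returns ``(ct, structures)`` where ``structures`` maps names to
    :class:`BinaryMask`: ``BODY`` (every voxel above background air), ``PTV``
    (sphere at the target position) and one sphere per configured OAR.
    """
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    # center the head in the grid
    extent = (np.asarray(shape) - 1) * spacing
    origin = -extent / 2.0
    world = _world_grid(shape, spacing, origin)
    center = np.zeros(3)

    values = np.full(shape, spec.hu_air, dtype=np.float64)
    outer = _ellipsoid(world, center, spec.head_radii)
    inner_radii = np.asarray(spec.head_radii) - spec.skull_thickness
    inner = _ellipsoid(world, center, inner_radii)
    values[outer] = spec.hu_bone          # skull shell ...
    values[inner] = spec.hu_soft          # ... hollowed by soft tissue

    # sinus-like air cavities in the anterior-inferior soft tissue
    rng = np.random.default_rng(spec.seed)
    for n, r in enumerate(spec.air_cavity_radii):
        offset = np.array([0.0, inner_radii[1] * 0.5, -inner_radii[2] * 0.3])
        offset += rng.uniform(-3, 3, size=3)
        cav = _ellipsoid(world, center + offset, (r, r, r)) & inner
        values[cav] = spec.hu_air

    ct = ScalarVolume(values=values, spacing=spacing, origin=origin)
    body = values > spec.hu_air + BODY_HU_MARGIN

    target_center = center + np.asarray(spec.target_offset, dtype=float)
    ptv = _ellipsoid(world, target_center,
                     (spec.target_radius,) * 3)
    if not body[ptv].all() or not ptv.any():
        raise ValueError("target sphere must lie inside the body")

    structures = {
        "BODY": BinaryMask("BODY", body, spacing, origin),
        "PTV": BinaryMask("PTV", ptv, spacing, origin),
    }
    for name, (offset, radius) in spec.oar_offsets.items():
        sphere = _ellipsoid(world, center + np.asarray(offset, dtype=float),
                            (radius,) * 3)
        structures[name] = BinaryMask(name, sphere, spacing, origin)
    return ct, structures


def apply_error_model(ct: ScalarVolume, body: BinaryMask, model: ErrorModel,
                      seed: int = 0) -> ScalarVolume:
    """Create the synthetic-CT member of a pair by injecting controlled
    conversion errors inside BODY; voxels outside BODY are unchanged.
    Deterministic given ``seed``."""
    body.check_compatible(ct)
    inside = body.values
    out = ct.values.copy()

    radius_vox = np.abs(model.bone_dilation) / ct.spacing
    if model.bone_dilation != 0 and radius_vox.max() >= 0.5:
        bone = (out > BONE_HU_THRESHOLD) & inside
        ball = _ball_element(radius_vox)
        if model.bone_dilation > 0:
            grown = ndimage.binary_dilation(bone, structure=ball) & inside
            newly = grown & ~bone
            out[newly] = _mode_hu(out, bone)
        else:
            shrunk = ndimage.binary_erosion(bone, structure=ball)
            lost = bone & ~shrunk
            soft = inside & ~bone
            out[lost] = _mode_hu(out, soft) if soft.any() else 0.0

    if model.contour_shift != 0:
        shift_vox = np.zeros(3)
        shift_vox[0] = model.contour_shift / ct.spacing[0]
        shifted = ndimage.shift(out, shift_vox, order=1, mode="constant",
                                cval=ct.values.min())
        out = np.where(inside, shifted, out)

    if model.global_bias != 0:
        out[inside] += model.global_bias

    if model.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, model.noise_sigma, size=ct.shape)
        out[inside] += noise[inside]

    if model.metal_artifact is not None:
        center, radius, hu_value = model.metal_artifact
        world = _world_grid(ct.shape, ct.spacing, ct.origin)
        void = _ellipsoid(world, np.asarray(center, dtype=float),
                          (radius,) * 3) & inside
        out[void] = hu_value

    return ct.with_values(out)


def _ball_element(radius_vox: np.ndarray) -> np.ndarray:
    # sub-voxel radii round to the 6-connected cross only when >= 0.5 voxel
    r = np.maximum(np.round(radius_vox + 1e-9).astype(int), 1)
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in r], indexing="ij")
    d = sum((g / max(n, 1)) ** 2 for g, n in zip(grids, r))
    return d <= 1.0 + 1e-9


def _mode_hu(values: np.ndarray, mask: np.ndarray) -> float:
    vals, counts = np.unique(np.round(values[mask]), return_counts=True)
    return float(vals[np.argmax(counts)])


def relative_density(hu: np.ndarray) -> np.ndarray:
    """Linear HU-to-relative-density calibration, clamped at vacuum."""
    return np.clip(1.0 + np.asarray(hu, dtype=float) / 1000.0, 0.0, None)


def compute_toy_dose(ct: ScalarVolume, beam: BeamSpec,
                     body: Optional[BinaryMask] = None) -> ScalarVolume:
    """Parallel-beam exponential-attenuation dose on a CT.

    For every ray along ``beam.direction``,
    ``dose(depth) = entrance_dose * exp(-attenuation_scale * radiological_depth)``
    where the radiological depth integrates ``relative_density(HU)`` along
    the ray from the body surface to the voxel center (midpoint rule).
    Dose is 0 outside BODY.  Deterministic.
    """
    if body is None:
        inside = ct.values > HU_BODY_DEFAULT_THRESHOLD
    else:
        body.check_compatible(ct)
        inside = body.values
    axis = beam.direction
    step = float(ct.spacing[axis])
    rho = relative_density(ct.values) * inside  # no attenuation outside body

    # cumulative radiological path to each voxel center along the beam axis
    cum = np.cumsum(rho, axis=axis) - rho / 2.0
    raddepth = cum * step
    dose = beam.entrance_dose * np.exp(-beam.attenuation_scale * raddepth)
    dose = np.where(inside, dose, 0.0)
    return ct.with_values(dose)


#: default HU threshold used when no BODY mask is supplied to the dose engine
HU_BODY_DEFAULT_THRESHOLD = -950.0


def smooth_dose_pair(shape=(16, 16, 16), spacing=(3.0, 3.0, 3.0),
                     seed: int = 0, perturb_pct: float = 1.5,
                     shift_mm: float = 0.5, smoothness_vox: float = 3.0):
    """A seeded pair of smooth, similar dose grids for gamma studies.

    The reference is smoothed positive noise scaled to a 60 Gy maximum; the
    evaluated dose is the reference under a smooth multiplicative
    perturbation of amplitude ``perturb_pct`` percent plus a sub-voxel
    spatial shift of ``shift_mm`` mm — the two disagreement modes (dose
    difference and distance-to-agreement) a gamma comparison trades off.
    """
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness_vox)
    base -= base.min()
    if base.max() > 0:
        base /= base.max()
    base = 60.0 * (0.1 + 0.9 * base)
    spacing = np.asarray(spacing, dtype=float)

    perturb = ndimage.gaussian_filter(rng.standard_normal(shape),
                                      smoothness_vox)
    scale = np.abs(perturb).max() or 1.0
    perturb = perturb / scale * perturb_pct / 100.0
    shifted = ndimage.shift(base, shift_mm / spacing, order=1, mode="nearest")
    evaluated = shifted * (1.0 + perturb)

    origin = np.zeros(3)
    return (ScalarVolume(base, spacing, origin),
            ScalarVolume(evaluated, spacing, origin))


def generate_case(spec: PhantomSpec, model: ErrorModel, beam: BeamSpec,
                  prescription_dose: Optional[float] = None,
                  case_id: str = "case", group: str = "",
                  error_seed: Optional[int] = None) -> CaseBundle:
    """Generate one fully deterministic phantom case.

    The synthetic CT is the planning CT passed through ``model``; the
    reference and evaluated doses are the toy-engine doses computed on the
    planning and synthetic CTs with the same beam.  The prescription dose
    defaults to the mean reference dose inside the PTV, mimicking a plan
    normalised to target coverage.
    """
    ct, structures = build_anatomy(spec)
    body = structures["BODY"]
    seed = spec.seed if error_seed is None else error_seed
    sct = apply_error_model(ct, body, model, seed=seed)
    dose_ref = compute_toy_dose(ct, beam, body=body)
    dose_eval = compute_toy_dose(sct, beam, body=body)
    if prescription_dose is None:
        prescription_dose = float(dose_ref.values[structures["PTV"].values].mean())
    return CaseBundle(
        planning_ct=ct,
        synthetic_ct=sct,
        dose_reference=dose_ref,
        dose_evaluated=dose_eval,
        structures=structures,
        prescription_dose=prescription_dose,
        case_id=case_id,
        group=group,
    )
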