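"""Data conditioning: accessory removal via the BODY contour and resampling
of the synthetic CT onto the planning-CT grid."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .grids import (
    HU_AIR,
    BinaryMask,
    ScalarVolume,
    VectorField,
    resample_to_reference,
)


class DegenerateBodyError(ValueError):
    """The BODY mask selects no voxels."""


def zero_outside_body(ct: ScalarVolume, body: BinaryMask,
                      outside_value: float = 0.0) -> ScalarVolume:
    """Assign ``outside_value`` to every voxel outside the BODY contour.

    Removes couch, mould and immobilisation accessories from a planning CT.
    The default of 0 HU (water-equivalent, not air) mirrors common TPS
    practice of zero-filling outside the body contour; pass ``-1000`` to
    treat the exterior as air instead.  Idempotent.
    """
    body.check_compatible(ct)
    if body.voxel_count == 0:
        raise DegenerateBodyError("degenerate body contour: mask is empty")
    out = np.where(body.values, ct.values, float(outside_value))
    return ct.with_values(out)


def align_pair(
    planning: ScalarVolume,
    synthetic: ScalarVolume,
    dvf: Optional[VectorField] = None,
    hu_floor: float = HU_AIR,
):
    """Resample the synthetic CT onto the planning-CT grid.

    The planning member is returned unchanged; the synthetic member is
    warped by ``dvf`` (pull semantics; identity when None), resampled onto
    the planning grid with trilinear interpolation, and clamped below at
    ``hu_floor`` (out-of-extent samples are filled with ``hu_floor``).
    """
    resampled = resample_to_reference(
        synthetic, planning, dvf=dvf, fill_value=hu_floor, floor=hu_floor
    )
    return planning, resampled
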