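"""Cumulative dose-volume histograms and the target/OAR dose metrics used
to compare plans recalculated on a synthetic CT against the planning-CT
reference: V_x% of the prescription (percent of structure volume receiving
at least x% of the prescribed dose), D-mean and D-max (maximum point dose).

Structure membership is voxel-center based (no partial-volume weighting);
D-max is the single maximum voxel dose, not a small-volume surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import BinaryMask, ScalarVolume


class StructureAbsentError(ValueError):
    """Structure mask is empty (contour unavailable for this case)."""


DEFAULT_ISODOSE_FRACTIONS = (0.93, 1.0, 1.1)


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= dose."""

    structure: str
    dose_edges: np.ndarray                 # Gy, ascending, starts at 0
    cumulative_volume_fraction: np.ndarray  # in [0, 1], non-increasing
    total_volume_cm3: float

    def volume_fraction_at(self, dose: float) -> float:
        """Fraction of the structure receiving at least ``dose`` Gy."""
        idx = np.searchsorted(self.dose_edges, dose, side="left")
        if idx >= len(self.dose_edges):
            return 0.0
        return float(self.cumulative_volume_fraction[idx])


@dataclass
class DoseMetrics:
    structure: str
    d_mean: float                  # Gy
    d_max: float                   # Gy
    v_at: dict                     # isodose fraction -> % volume in [0, 100]
    n_voxels: int = 0

    def as_dict(self) -> dict:
        row = {"structure": self.structure, "d_mean_gy": self.d_mean,
               "d_max_gy": self.d_max, "n_voxels": self.n_voxels}
        for f, v in self.v_at.items():
            row[f"v{f * 100:g}pct"] = v
        return row


def _structure_doses(dose: ScalarVolume, mask: BinaryMask) -> np.ndarray:
    mask.check_compatible(dose)
    if mask.voxel_count == 0:
        raise StructureAbsentError(f"structure {mask.name!r} absent (empty mask)")
    return dose.values[mask.values]


def compute_dvh(dose: ScalarVolume, mask: BinaryMask,
                bin_width: float = 0.01) -> DVHCurve:
    """Cumulative DVH of a dose grid within a structure.

    Edges run from 0 to just past the maximum structure dose in steps of
    ``bin_width`` Gy; the curve value at each edge is the fraction of
    structure voxels with dose >= that edge, so it is 1 at 0 Gy and 0
    beyond the maximum dose.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    doses = _structure_doses(dose, mask)
    d_max = float(doses.max())
    n_edges = int(np.ceil(d_max / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    # fraction receiving >= edge, via a sorted search
    sorted_doses = np.sort(doses)
    at_least = doses.size - np.searchsorted(sorted_doses, edges, side="left")
    frac = at_least / doses.size
    return DVHCurve(
        structure=mask.name,
        dose_edges=edges,
        cumulative_volume_fraction=frac,
        total_volume_cm3=mask.volume_cm3,
    )


def dose_metrics(dose: ScalarVolume, mask: BinaryMask, prescription: float,
                 isodose_fractions=DEFAULT_ISODOSE_FRACTIONS) -> DoseMetrics:
    """D-mean, D-max and V_x% of the prescription for one structure."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    doses = _structure_doses(dose, mask)
    v_at = {
        float(f): float(100.0 * np.mean(doses >= f * prescription))
        for f in isodose_fractions
    }
    return DoseMetrics(
        structure=mask.name,
        d_mean=float(doses.mean()),
        d_max=float(doses.max()),
        v_at=v_at,
        n_voxels=doses.size,
    )


#: sentinel below which a reference value cannot anchor a relative difference
RELATIVE_EPS = 1e-9


@dataclass
class MetricDiff:
    """Evaluated-minus-reference difference for one scalar metric."""

    metric: str
    reference: float
    evaluated: float
    absolute: float
    normalized_pct: float | None   # None when the reference is ~0 ("NA")


def diff_metrics(reference: DoseMetrics, evaluated: DoseMetrics,
                 prescription: float) -> list:
    """Per-metric differences between evaluated and reference dose metrics.

    Absolute difference is ``evaluated - reference``; the normalized
    difference is that difference as a percentage of the reference value,
    flagged ``None`` (reported "NA") when the reference is numerically zero.
    """
    if reference.structure != evaluated.structure:
        raise ValueError("metrics belong to different structures")
    if set(reference.v_at) != set(evaluated.v_at):
        raise ValueError("isodose fraction sets differ")

    def one(metric: str, ref: float, ev: float) -> MetricDiff:
        absolute = ev - ref
        norm = 100.0 * absolute / ref if abs(ref) > RELATIVE_EPS else None
        return MetricDiff(metric, ref, ev, absolute, norm)

    out = [
        one("d_mean", reference.d_mean, evaluated.d_mean),
        one("d_max", reference.d_max, evaluated.d_max),
    ]
    for f in sorted(reference.v_at):
        out.append(one(f"v{f * 100:g}pct", reference.v_at[f], evaluated.v_at[f]))
    return out
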