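"""Readers and writers for the volume formats the pipeline consumes.

NIfTI (via nibabel) and NRRD (via SimpleITK) carry :class:`ScalarVolume`,
:class:`VectorField` and :class:`BinaryMask`; DICOM (via pydicom) covers a
CT slice series (position-sorted, rescale slope/intercept applied), RTDOSE
(DoseGridScaling applied) and RTSTRUCT (contours rasterised to masks by
even-odd polygon fill per slice).

All loaders normalise to the package's axis-aligned grid convention
(array axis a = world axis a, origin at the center of voxel (0,0,0)):
axis permutations and flips are resolved at load time, and genuinely
oblique orientations are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk
from skimage.draw import polygon2mask

from .grids import BinaryMask, ScalarVolume, VectorField

_OBLIQUE_TOL = 1e-3


# ---------------------------------------------------------------------------
# NIfTI / NRRD
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray):
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine")
    direction = rot / spacing
    if not np.allclose(np.abs(direction), np.eye(3), atol=_OBLIQUE_TOL):
        raise ValueError("oblique orientation not supported; reorient first")
    return spacing, affine[:3, 3].copy()


def _load_nifti_array(path):
    img = nib.as_closest_canonical(nib.load(str(path)))
    spacing, origin = _grid_from_affine(img.affine)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return data, spacing, origin


def _load_nrrd_array(path):
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=_OBLIQUE_TOL):
        raise ValueError("oblique orientation not supported; reorient first")
    data = sitk.GetArrayFromImage(img)          # (z, y, x)
    data = np.transpose(data, (2, 1, 0)).astype(np.float64)
    return data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def load_volume(path) -> ScalarVolume:
    """Load a scalar volume from .nii/.nii.gz or .nrrd."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        data, spacing, origin = _load_nifti_array(path)
    elif path.suffix in (".nrrd", ".nhdr"):
        data, spacing, origin = _load_nrrd_array(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return ScalarVolume(values=data, spacing=spacing, origin=origin)


def load_mask(path, name: str | None = None) -> BinaryMask:
    vol = load_volume(path)
    return BinaryMask(name or Path(path).name.split(".")[0],
                      vol.values > 0.5, vol.spacing, vol.origin)


def load_vector_field(path) -> VectorField:
    """Load a displacement field stored as a 4D (i, j, k, 3) NIfTI."""
    path = Path(path)
    data, spacing, origin = _load_nifti_array(path)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("displacement field must have shape (ni, nj, nk, 3)")
    return VectorField(displacements=data, spacing=spacing[:3], origin=origin)


def _diag_affine(spacing, origin) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def save_volume(volume: ScalarVolume, path):
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(volume.values,
                              _diag_affine(volume.spacing, volume.origin))
        nib.save(img, str(path))
    elif path.suffix in (".nrrd", ".nhdr"):
        img = sitk.GetImageFromArray(np.transpose(volume.values, (2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def save_mask(mask: BinaryMask, path):
    save_volume(ScalarVolume(mask.values.astype(np.float64), mask.spacing,
                             mask.origin), path)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _check_axial_orientation(ds):
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    if not (np.allclose(np.abs(row), [1, 0, 0], atol=_OBLIQUE_TOL)
            and np.allclose(np.abs(col), [0, 1, 0], atol=_OBLIQUE_TOL)):
        raise ValueError("only axis-aligned axial DICOM geometry is supported")
    return row, col


def load_dicom_ct_series(directory) -> ScalarVolume:
    """Read a CT slice series: slices sorted by position along the slice
    normal, rescale slope/intercept applied to produce HU."""
    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file())
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices = [s for s in slices if hasattr(s, "ImagePositionPatient")]
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    row, col = _check_axial_orientation(slices[0])
    normal = np.cross(row, col)
    slices.sort(key=lambda s: float(
        np.dot(np.asarray(s.ImagePositionPatient, dtype=float), normal)))

    first = slices[0]
    px_spacing = np.asarray(first.PixelSpacing, dtype=float)  # (row, col)
    positions = np.array([np.dot(np.asarray(s.ImagePositionPatient, float),
                                 normal) for s in slices])
    if len(slices) > 1:
        dz = np.diff(positions)
        if np.ptp(dz) > 1e-3:
            raise ValueError("non-uniform slice spacing")
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    planes = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(s.pixel_array.astype(np.float64) * slope + intercept)
    # pixel_array is (rows, cols) = (y, x); volume axes are (x, y, z)
    values = np.stack([p.T for p in planes], axis=-1)
    origin = np.asarray(first.ImagePositionPatient, dtype=float)
    spacing = np.array([px_spacing[1], px_spacing[0], slice_spacing])
    return ScalarVolume(values=values, spacing=spacing, origin=origin)


def load_rtdose(path) -> ScalarVolume:
    """Read an RTDOSE grid, applying DoseGridScaling; values in Gy."""
    ds = pydicom.dcmread(str(path))
    _check_axial_orientation(ds)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    frames = ds.pixel_array.astype(np.float64) * scaling   # (z, y, x)
    values = np.transpose(frames, (2, 1, 0))
    px_spacing = np.asarray(ds.PixelSpacing, dtype=float)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and np.ptp(dz) > 1e-3:
        raise ValueError("non-uniform dose frame spacing")
    slice_spacing = float(dz.mean()) if offsets.size > 1 else 1.0
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    origin = origin + np.array([0.0, 0.0, offsets[0]])
    spacing = np.array([px_spacing[1], px_spacing[0], slice_spacing])
    return ScalarVolume(values=values, spacing=spacing, origin=origin)


def load_rtstruct(path, reference: ScalarVolume) -> dict:
    """Rasterise an RTSTRUCT's contours onto the reference grid.

    Each closed planar contour is filled as a polygon on its slice and
    XOR-combined with other contours of the same structure, which realises
    even-odd semantics (holes and islands).
    """
    ds = pydicom.dcmread(str(path))
    names = {int(r.ROINumber): str(r.ROIName)
             for r in ds.StructureSetROISequence}
    out: dict = {}
    ni, nj, nk = reference.shape
    for roi in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi.ReferencedROINumber), "ROI")
        mask = np.zeros(reference.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = (pts - reference.origin) / reference.spacing
            k = int(round(float(np.median(idx[:, 2]))))
            if not (0 <= k < nk):
                continue
            plane = polygon2mask((ni, nj), idx[:, :2])
            mask[:, :, k] ^= plane
        out[name] = BinaryMask(name, mask, reference.spacing.copy(),
                               reference.origin.copy())
    return out


# ---------------------------------------------------------------------------
# case bundles on disk
# ---------------------------------------------------------------------------

def save_case(bundle, directory):
    """Write a CaseBundle as NIfTI volumes plus JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(bundle.planning_ct, directory / "planning_ct.nii.gz")
    save_volume(bundle.synthetic_ct, directory / "synthetic_ct.nii.gz")
    save_volume(bundle.dose_reference, directory / "dose_reference.nii.gz")
    save_volume(bundle.dose_evaluated, directory / "dose_evaluated.nii.gz")
    for name, mask in bundle.structures.items():
        save_mask(mask, directory / f"mask_{name}.nii.gz")
    meta = {
        "case_id": bundle.case_id,
        "group": bundle.group,
        "prescription_dose": bundle.prescription_dose,
        "prescription_isodose_fraction": bundle.prescription_isodose_fraction,
        "structures": sorted(bundle.structures),
    }
    (directory / "case.json").write_text(json.dumps(meta, indent=2))


def load_case(directory):
    """Read a CaseBundle previously written by :func:`save_case`."""
    from .grids import CaseBundle  # local import to avoid cycle at top

    directory = Path(directory)
    meta = json.loads((directory / "case.json").read_text())
    structures = {
        name: load_mask(directory / f"mask_{name}.nii.gz", name)
        for name in meta["structures"]
    }
    return CaseBundle(
        planning_ct=load_volume(directory / "planning_ct.nii.gz"),
        synthetic_ct=load_volume(directory / "synthetic_ct.nii.gz"),
        dose_reference=load_volume(directory / "dose_reference.nii.gz"),
        dose_evaluated=load_volume(directory / "dose_evaluated.nii.gz"),
        structures=structures,
        prescription_dose=meta["prescription_dose"],
        prescription_isodose_fraction=meta["prescription_isodose_fraction"],
        case_id=meta["case_id"],
        group=meta.get("group", ""),
    )
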