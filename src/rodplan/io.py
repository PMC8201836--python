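"""File interchange: NIfTI masks/dose, DICOM RT Structure Set export, CSV DVHs.

NIfTI is the primary interchange format (the affine encodes spacing and
origin); the RT Structure Set export exists so generated structures can be
imported into a treatment planning system, and traces axial mask boundaries
into closed planar contours in patient millimetre coordinates.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .core import DoseGrid, StructureMask, StructureSet, VoxelGrid
from .dvh import DVHCurve

__all__ = [
    "write_mask",
    "read_mask",
    "write_dose",
    "read_dose",
    "write_structure_set",
    "export_rtstruct",
    "write_dvh_csv",
    "write_report_json",
]

_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def _grid_from_img(img: nib.Nifti1Image) -> tuple[VoxelGrid, float]:
    zooms = img.header.get_zooms()[:3]
    spacing = float(np.mean(zooms))
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        warnings.warn(
            f"anisotropic voxel spacing {zooms} accepted; using the mean "
            f"{spacing:.4f} mm on the isotropic grid",
            stacklevel=3,
        )
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = VoxelGrid(shape=img.shape[:3], spacing_mm=spacing, origin_mm=origin)
    return grid, spacing


def write_mask(mask: StructureMask, path: str | Path) -> Path:
    """Write a binary mask as NIfTI (uint8, affine carries spacing/origin)."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine())
    nib.save(img, path)
    return path


def read_mask(path: str | Path, name: str | None = None) -> StructureMask:
    """Read a NIfTI mask; values must be exactly {0, 1}."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(
            f"{path} is not a binary mask (values {vals[:8]}); refusing to read"
        )
    grid, _ = _grid_from_img(img)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    return StructureMask(name or stem, grid, data.astype(bool))


def write_dose(dose: DoseGrid, path: str | Path) -> Path:
    """Write a dose grid (Gy) as NIfTI float32."""
    path = Path(path)
    img = nib.Nifti1Image(dose.data.astype(np.float32), dose.grid.affine())
    img.header.set_intent("estimate", name="dose_gy")
    nib.save(img, path)
    return path


def read_dose(path: str | Path) -> DoseGrid:
    img = nib.load(Path(path))
    grid, _ = _grid_from_img(img)
    return DoseGrid(grid, np.asanyarray(img.dataobj).astype(np.float64))


def write_structure_set(
    structures: StructureSet, directory: str | Path
) -> dict[str, str]:
    """Write every mask as NIfTI plus a manifest JSON with names and volumes (cm3)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spacing_mm": structures.grid.spacing_mm,
        "shape": list(structures.grid.shape),
        "structures": {},
    }
    files: dict[str, str] = {}
    for mask in structures:
        fname = f"{mask.name}.nii.gz"
        write_mask(mask, directory / fname)
        files[mask.name] = fname
        manifest["structures"][mask.name] = {
            "file": fname,
            "volume_cm3": round(mask.volume_cm3, 4),
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return files


def read_structure_set(directory: str | Path) -> StructureSet:
    """Read back a directory written by :func:`write_structure_set`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    structures: StructureSet | None = None
    for name, entry in manifest["structures"].items():
        mask = read_mask(directory / entry["file"], name=name)
        if structures is None:
            structures = StructureSet(mask.grid)
        structures.add(mask)
    if structures is None:
        raise ValueError(f"no structures listed in {directory}/manifest.json")
    return structures


def _mask_contours_mm(mask: StructureMask) -> list[np.ndarray]:
    """Closed axial boundary polygons of a mask, in patient mm, one per loop."""
    grid = mask.grid
    ox, oy, oz = grid.origin_mm
    sp = grid.spacing_mm
    polygons: list[np.ndarray] = []
    for k in range(grid.shape[2]):
        axial = mask.data[:, :, k]
        if not axial.any():
            continue
        padded = np.pad(axial.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            pts = contour - 1.0  # undo padding; columns are (x_idx, y_idx)
            xyz = np.column_stack(
                [ox + sp * pts[:, 0], oy + sp * pts[:, 1], np.full(len(pts), oz + sp * k)]
            )
            polygons.append(xyz)
    return polygons


def export_rtstruct(
    structures: StructureSet, path: str | Path, patient_id: str = "PHANTOM"
) -> Path:
    """Export a DICOM RT Structure Set with one ROI per non-empty structure.

    Contours are closed planar polygons traced from the mask boundary on each
    axial slice, in patient coordinates (mm).  Empty structures are skipped
    with a warning.
    """
    if not structures.names:
        raise ValueError("cannot export an empty structure set")
    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    ds.StructureSetLabel = "rodplan"
    ds.FrameOfReferenceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()

    roi_seq, contour_seq, obs_seq = [], [], []
    number = 0
    for mask in structures:
        if mask.is_empty():
            warnings.warn(f"structure '{mask.name}' is empty; skipped", stacklevel=2)
            continue
        number += 1
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = mask.name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        contours = []
        for poly in _mask_contours_mm(mask):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [f"{v:.4f}" for v in poly.ravel()]
            contours.append(c)
        rc.ContourSequence = contours
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.ROIObservationLabel = mask.name
        obs.RTROIInterpretedType = "ORGAN"
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    pydicom.dcmwrite(path, ds)
    return path


def write_dvh_csv(curves: list[DVHCurve], path: str | Path) -> Path:
    """Write cumulative DVH curves as CSV: dose_gy plus one fraction column each."""
    path = Path(path)
    widths = {c.bin_width_gy for c in curves}
    if len(widths) != 1:
        raise ValueError("all curves must share one bin width for CSV export")
    n = max(c.edges_gy.size for c in curves)
    bw = curves[0].bin_width_gy
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dose_gy"] + [f"{c.structure}_fraction" for c in curves])
        for i in range(n):
            row = [f"{bw * i:.4f}"]
            for c in curves:
                row.append(f"{c.cum_fraction[i]:.6f}" if i < c.cum_fraction.size else "0.000000")
            writer.writerow(row)
    return path


def write_report_json(report_dict: dict, path: str | Path) -> Path:
    """Deterministic (sorted-key) JSON dump of a plan report or summary."""
    path = Path(path)
    path.write_text(json.dumps(report_dict, indent=2, sort_keys=True))
    return path
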