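"""CT volume container and DICOM/NIfTI round-trip I/O.

The in-memory convention everywhere in this package is: voxel array of
Hounsfield units (HU), axis order (slice, row, column), 0-based indices,
``spacing`` in millimetres per axis in the same order.  The storage affine
``HU = slope * stored + intercept`` is applied exactly once, at read time;
``CTVolume.voxels`` always holds HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants; names the field."""


@dataclass
class CTVolume:
    """A 3D grid of HU values with spacing and storage-affine metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Hounsfield units.  Integer HU is canonical; float arrays are
        accepted and rounded half-to-even where binning requires integers.
    spacing : tuple of float
        Millimetres per axis, (slice, row, column) order.
    rescale_slope, rescale_intercept : float
        Affine mapping between on-disk stored integers and HU.  Purely
        storage metadata: ``voxels`` is already in HU.
    orientation : str
        Axis-convention tag; the generators and readers in this package
        all produce "SRC" (slice, row, column).
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (5.0, 0.7, 0.7)
    rescale_slope: float = 1.0
    rescale_intercept: float = -1024.0
    orientation: str = "SRC"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError("voxels: expected a non-empty 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxels: HU values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing: need three positive extents (mm)")
        if self.rescale_slope == 0:
            raise ValidationError("rescale_slope: must be non-zero")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    def stored_array(self) -> np.ndarray:
        """Voxels mapped to storage integers via the inverse affine."""
        stored = (self.voxels - self.rescale_intercept) / self.rescale_slope
        return np.rint(stored).astype(np.int16)


def write_nifti(volume: CTVolume, path: os.PathLike | str) -> Path:
    """Write a volume as NIfTI-1, HU stored as int16, spacing in the zooms."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(
        np.rint(volume.voxels).astype(np.int16), affine=affine
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)
    return path


def read_nifti(path: os.PathLike | str) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=np.asarray(data), spacing=zooms,
                    rescale_slope=1.0, rescale_intercept=0.0)


def write_dicom_series(volume: CTVolume, directory: os.PathLike | str) -> Path:
    """Write one CT DICOM file per slice.

    Pixel data hold ``(HU - intercept) / slope`` as unsigned 16-bit; the
    RescaleSlope/RescaleIntercept tags carry the volume's storage affine so
    that readers recover HU exactly.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stored = volume.stored_array()
    if stored.min() < 0 or stored.max() > 65535:
        raise ValidationError(
            "rescale_intercept: stored values fall outside unsigned 16-bit range"
        )
    stored = stored.astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    n_slices = volume.shape[0]
    for i in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "SYN000"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i * volume.spacing[0])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = float(volume.spacing[0])
        ds.SpacingBetweenSlices = float(volume.spacing[0])
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[2])]
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = float(volume.rescale_slope)
        ds.RescaleIntercept = float(volume.rescale_intercept)
        ds.PixelData = stored[i].tobytes()
        pydicom.dcmwrite(directory / f"slice_{i:04d}.dcm", ds,
                         enforce_file_format=True)
    return directory


def read_dicom_series(directory: os.PathLike | str) -> CTVolume:
    """Read a single-series DICOM directory back into HU.

    Slices are ordered by ImagePositionPatient z (InstanceNumber as the
    fallback); the rescale affine is applied exactly once here.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise IOError(f"no DICOM files found in {directory}")
    slices = [pydicom.dcmread(f) for f in files]

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    slices.sort(key=zpos)
    first = slices[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    stack = np.stack([s.pixel_array.astype(np.float64) for s in slices])
    hu = stack * slope + intercept
    if len(slices) > 1:
        dz = abs(zpos(slices[1]) - zpos(slices[0]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    spacing = (dz, float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    hu_int = np.rint(hu)
    if np.allclose(hu, hu_int):
        hu = hu_int.astype(np.int16 if abs(hu_int).max() < 32768 else np.int32)
    return CTVolume(voxels=hu, spacing=spacing, rescale_slope=slope,
                    rescale_intercept=intercept)


def write_volume(volume: CTVolume, fmt: str, path: os.PathLike | str) -> Path:
    """Write a volume as ``fmt`` in {"nifti", "dicom_series"}."""
    if fmt == "nifti":
        return write_nifti(volume, path)
    if fmt == "dicom_series":
        return write_dicom_series(volume, path)
    raise ValidationError(f"format: unknown volume format {fmt!r}")


def read_volume(path: os.PathLike | str) -> CTVolume:
    """Read NIfTI (``.nii``/``.nii.gz`` file) or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)
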