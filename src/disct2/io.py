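"""NIfTI (primary) and optional DICOM I/O for series, maps and label volumes.

Spatial convention: volume axes are (slice, row, col); multi-echo stacks are
written as 4-D NIfTI with echo as the 4th axis and the echo times in a JSON
sidecar next to the image. DICOM export (one file per slice per echo with
EchoTime / PixelSpacing / ImagePositionPatient populated) needs the optional
``pydicom`` dependency and raises a clear error when it is missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import Geometry
from .t2map import MultiEchoSeries, T2Map

__all__ = [
    "save_series_nifti",
    "load_series_nifti",
    "save_labels_nifti",
    "load_labels_nifti",
    "save_t2map_nifti",
    "write_dicom_series",
    "read_seeds_json",
]


def _affine(geometry: Geometry) -> np.ndarray:
    pos = np.asarray(geometry.slice_positions, dtype=float)
    step = float(pos[1] - pos[0]) if pos.size > 1 else geometry.slice_thickness
    aff = np.diag([step, geometry.pixel_spacing[0], geometry.pixel_spacing[1], 1.0])
    aff[0, 3] = pos[0]
    aff[1, 3] = geometry.origin[0]
    aff[2, 3] = geometry.origin[1]
    return aff


def _geometry_from(img: nib.Nifti1Image, sidecar: dict) -> Geometry:
    aff = img.affine
    n_slices = img.shape[0]
    step = float(aff[0, 0])
    return Geometry(
        pixel_spacing=(float(aff[1, 1]), float(aff[2, 2])),
        slice_thickness=float(sidecar.get("slice_thickness", abs(step))),
        slice_positions=tuple(aff[0, 3] + step * i for i in range(n_slices)),
        origin=(float(aff[1, 3]), float(aff[2, 3])),
    )


def save_series_nifti(series: MultiEchoSeries, path: str | Path) -> None:
    """Write a multi-echo series as 4-D NIfTI plus a JSON sidecar."""
    path = Path(path)
    vol = np.moveaxis(series.data, 0, -1)  # (slice,row,col,echo)
    nib.save(nib.Nifti1Image(vol, _affine(series.geometry)), path)
    sidecar = {
        "echo_times_ms": list(series.echo_times),
        "slice_thickness": series.geometry.slice_thickness,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_series_nifti(path: str | Path) -> MultiEchoSeries:
    path = Path(path)
    img = nib.load(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    return MultiEchoSeries(
        data=data,
        echo_times=tuple(sidecar["echo_times_ms"]),
        geometry=_geometry_from(img, sidecar),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_labels_nifti(labels: np.ndarray, geometry: Geometry, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(geometry)), Path(path))


def load_labels_nifti(path: str | Path) -> tuple[np.ndarray, Geometry]:
    img = nib.load(Path(path))
    labels = np.nan_to_num(np.asarray(img.dataobj)).astype(np.int16)
    return labels, _geometry_from(img, {})


def save_t2map_nifti(t2map: T2Map, path: str | Path) -> None:
    """Write T2 (ms) and the validity mask (``*_valid``) as NIfTI files."""
    path = Path(path)
    nib.save(nib.Nifti1Image(t2map.t2, _affine(t2map.geometry)), path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            valid_path = path.with_name(name[: -len(suffix)] + "_valid" + suffix)
            break
    else:
        valid_path = path.with_name(path.stem + "_valid" + path.suffix)
    nib.save(
        nib.Nifti1Image(t2map.valid.astype(np.uint8), _affine(t2map.geometry)), valid_path
    )


def write_dicom_series(series: MultiEchoSeries, out_dir: str | Path) -> list[Path]:
    """Export one DICOM file per slice per echo (requires ``pydicom``)."""
    try:
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM export requires the optional 'pydicom' dependency "
            "(pip install disct2[dicom])"
        ) from exc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = series.geometry
    series_uid = generate_uid()
    written: list[Path] = []
    scale = 65535.0 / max(float(series.data.max()), 1e-12)
    for e, te in enumerate(series.echo_times):
        for s in range(geom.n_slices):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "MR"
            ds.EchoTime = float(te)
            ds.PixelSpacing = [geom.pixel_spacing[0], geom.pixel_spacing[1]]
            ds.SliceThickness = geom.slice_thickness
            ds.ImagePositionPatient = [
                float(geom.slice_positions[s]),
                float(geom.origin[0]),
                float(geom.origin[1]),
            ]
            ds.ImageOrientationPatient = [0, 1, 0, 0, 0, 1]
            ds.InstanceNumber = e * geom.n_slices + s + 1
            ds.Rows, ds.Columns = series.data.shape[2], series.data.shape[3]
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = 1.0 / scale
            ds.RescaleIntercept = 0.0
            ds.PixelData = (series.data[e, s] * scale).astype(np.uint16).tobytes()
            path = out / f"echo{e:02d}_slice{s:02d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            written.append(path)
    return written


def read_seeds_json(path: str | Path) -> list[dict]:
    """Read seed annotations: a list of {subject, level, slice, row, col}."""
    seeds = json.loads(Path(path).read_text())
    required = {"subject", "level", "slice", "row", "col"}
    for entry in seeds:
        missing = required - set(entry)
        if missing:
            raise ValueError(f"seed entry missing {sorted(missing)}: {entry}")
    return seeds
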