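"""Grid I/O: the portable ``.pgrid`` format of record and DICOM RT Dose.

The portable format is a single JSON header line (shape, spacing mm, origin
mm, quantity, sentinel, provenance, dtype) followed by the raw little-endian
float64 payload flattened x-fastest.  It round-trips bit-exactly, including
NaN exclusion sentinels, which DICOM quantization cannot; DICOM RT Dose
import/export is provided for interoperability only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import VoxelGrid

__all__ = ["read_grid", "write_grid", "import_dicom_rtdose", "export_dicom_rtdose"]

_MAGIC = "pgrid-v1"
_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


def write_grid(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid to the portable format (bit-exact round trip)."""
    header = {
        "magic": _MAGIC,
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "quantity": grid.quantity,
        "sentinel": "nan",
        "provenance": grid.provenance,
        "dtype": "<f8",
        "order": "x-fastest",
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode("utf-8") + b"\n")
        fh.write(np.ascontiguousarray(grid.values.ravel(order="F"), dtype="<f8").tobytes())


def read_grid(path: str | Path) -> VoxelGrid:
    """Read a portable grid file; raises ``ValueError`` on malformed input."""
    with open(path, "rb") as fh:
        line = fh.readline()
        try:
            header = json.loads(line.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: not a portable grid file") from exc
        if header.get("magic") != _MAGIC:
            raise ValueError(f"{path}: bad magic {header.get('magic')!r}")
        shape = tuple(header["shape"])
        payload = fh.read()
    n = int(np.prod(shape))
    if len(payload) != 8 * n:
        raise ValueError(f"{path}: truncated payload ({len(payload)} bytes for {n} voxels)")
    values = np.frombuffer(payload, dtype="<f8").reshape(shape, order="F")
    return VoxelGrid(
        values.copy(),
        tuple(header["spacing_mm"]),
        tuple(header["origin_mm"]),
        header["quantity"],
        header.get("provenance", ""),
    )


def export_dicom_rtdose(grid: VoxelGrid, path: str | Path,
                        template: Dataset | None = None) -> None:
    """Write a grid as a DICOM RT Dose object.

    Values are stored as signed 32-bit integers with ``DoseGridScaling``
    chosen from the grid maximum, so quantization error is far below 0.01%
    of the maximum and negative Δdose values survive.  Non-dose quantities
    (LET, RBE, Δdose) are tagged in ``SeriesDescription``; NaN sentinels are
    written as 0 (the portable format is the format of record).
    """
    vals = np.nan_to_num(grid.values, nan=0.0)
    amax = float(np.abs(vals).max())
    scaling = amax / (2**31 - 1) if amax > 0 else 1.0
    pixels = np.round(vals / scaling).astype(np.int32)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    if template is not None:
        for tag in ("PatientName", "PatientID", "StudyInstanceUID", "FrameOfReferenceUID"):
            if hasattr(template, tag):
                setattr(ds, tag, getattr(template, tag))
    if not hasattr(ds, "StudyInstanceUID"):
        ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.SeriesDescription = f"protonlet:{grid.quantity}"

    nx, ny, nz = grid.shape
    sx, sy, sz = grid.spacing
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [f"{sy:.6f}", f"{sx:.6f}"]
    ds.SliceThickness = f"{sz:.6f}"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    # DICOM positions address voxel centres; internal origin is the corner
    ds.ImagePositionPatient = [
        f"{grid.origin[0] + 0.5 * sx:.6f}",
        f"{grid.origin[1] + 0.5 * sy:.6f}",
        f"{grid.origin[2] + 0.5 * sz:.6f}",
    ]
    ds.GridFrameOffsetVector = [k * sz for k in range(nz)]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 1
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)


def import_dicom_rtdose(path: str | Path) -> VoxelGrid:
    """Read a DICOM RT Dose object into a grid (values × DoseGridScaling)."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(f"{path}: not an RT Dose object (Modality={getattr(ds, 'Modality', None)!r})")
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path}: RT Dose object lacks DoseGridScaling")
    arr = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)
    if arr.ndim == 2:
        arr = arr[None, ...]
    values = arr.transpose(2, 1, 0)  # (frames, rows, cols) -> (x, y, z)
    sy, sx = (float(v) for v in ds.PixelSpacing)
    gfo = ds.GridFrameOffsetVector
    offsets = [float(v) for v in gfo] if isinstance(gfo, (list, tuple)) or hasattr(gfo, "__len__") else [float(gfo)]
    sz = offsets[1] - offsets[0] if len(offsets) > 1 else float(getattr(ds, "SliceThickness", 1.0))
    pos = [float(v) for v in ds.ImagePositionPatient]
    origin = (pos[0] - 0.5 * sx, pos[1] - 0.5 * sy, pos[2] - 0.5 * sz)
    desc = str(getattr(ds, "SeriesDescription", ""))
    quantity = desc.removeprefix("protonlet:") if desc.startswith("protonlet:") else "dose_Gy"
    return VoxelGrid(values, (sx, sy, sz), origin, quantity, provenance=f"dicom:{path}")
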