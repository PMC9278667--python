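"""DICOM and CSV I/O for modulation-curve analysis.

Reads per-slice acquisition metadata (table position, tube current,
exposure time, CTDIvol) from the headers of a reconstructed CT series and
assembles :class:`~atcmlab.atcm_sim.ModulationCurve` objects; writes
synthetic series produced by the simulator as standard CT Image Storage
files so the extraction path can be exercised end to end.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (CTImageStorage, ExplicitVRLittleEndian,
                         generate_uid)

from .atcm_sim import ModulationCurve, Protocol, SliceRecord
from .wed import WEDProfile

_RESCALE_INTERCEPT = -1024.0


def _format_ds(value: float) -> str:
    """Format a float for a DICOM decimal string (max 16 characters)."""
    s = repr(float(value))
    if len(s) > 16:
        s = f"{value:.10g}"
    return s


def write_series(records: list[SliceRecord], out_dir,
                 protocol: Protocol | None = None, direction: str = "",
                 phantom_name: str = "", series_uid: str | None = None,
                 study_uid: str | None = None) -> list[Path]:
    """Write slice records as a DICOM CT series (one file per slice)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = study_uid or generate_uid()
    frame_uid = generate_uid()
    paths = []
    for i, rec in enumerate(records):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = phantom_name or "PHANTOM"
        ds.PatientID = phantom_name or "PHANTOM"
        ds.SeriesDescription = " ".join(
            x for x in [protocol.name if protocol else "", direction] if x)
        ds.InstanceNumber = (rec.instance_number if rec.instance_number
                             is not None else i + 1)
        ds.SliceLocation = _format_ds(rec.table_position)
        ds.ImagePositionPatient = ["0", "0", _format_ds(rec.table_position)]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SliceThickness = _format_ds(rec.recon_thickness)
        ds.PixelSpacing = [_format_ds(rec.pixel_size),
                           _format_ds(rec.pixel_size)]
        ds.XRayTubeCurrent = int(round(rec.ma))
        ds.ExposureTime = int(round(rec.exposure_time))
        if rec.ctdi_vol is not None:
            ds.CTDIvol = float(rec.ctdi_vol)
        if protocol is not None:
            ds.KVP = _format_ds(protocol.kvp)
            ds.SpiralPitchFactor = float(protocol.pitch)
            ds.ProtocolName = protocol.name
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = _format_ds(_RESCALE_INTERCEPT)
        raw = np.clip(np.round(rec.image - _RESCALE_INTERCEPT),
                      0, 65535).astype(np.uint16)
        ds.Rows, ds.Columns = raw.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = raw.tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = out / f"slice_{ds.InstanceNumber:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_series(path) -> list[SliceRecord]:
    """Read a single-series DICOM directory into slice records.

    Records are returned in acquisition order (InstanceNumber). The table
    position comes from Slice Location, falling back to the z component of
    Image Position (Patient); pixel values are rescaled to HU. A missing
    CTDIvol tag produces a warning and an absent field, not a failure.
    """
    files = sorted(p for p in Path(path).iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise ValueError(f"no DICOM files found in {path}")
    records: list[tuple[int, SliceRecord]] = []
    series_uid = None
    for f in files:
        ds = pydicom.dcmread(f)
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise ValueError("mixed SeriesInstanceUID in directory"
                             f" {path}: {series_uid} vs {uid}")
        if "SliceLocation" in ds:
            pos = float(ds.SliceLocation)
        elif "ImagePositionPatient" in ds:
            pos = float(ds.ImagePositionPatient[2])
        else:
            raise KeyError("neither SliceLocation (0020,1041) nor"
                           " ImagePositionPatient (0020,0032) present in"
                           f" {f.name}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        image = ds.pixel_array.astype(float) * slope + intercept
        if "CTDIvol" in ds:
            ctdi = float(ds.CTDIvol)
        else:
            warnings.warn(f"CTDIvol tag (0018,9345) missing in {f.name};"
                          " field left absent", stacklevel=2)
            ctdi = None
        pixel_size = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
        instance = int(getattr(ds, "InstanceNumber", len(records) + 1))
        records.append((instance, SliceRecord(
            table_position=pos, image=image,
            ma=float(getattr(ds, "XRayTubeCurrent", 0.0)),
            exposure_time=float(getattr(ds, "ExposureTime", 0.0)),
            ctdi_vol=ctdi,
            recon_thickness=float(getattr(ds, "SliceThickness", 0.0)),
            pixel_size=pixel_size, instance_number=instance)))
    records.sort(key=lambda item: item[0])
    return [rec for _, rec in records]


def to_modulation_curve(records: list[SliceRecord],
                        direction: str = "auto",
                        protocol: Protocol | None = None,
                        phantom_name: str = "") -> ModulationCurve:
    """Assemble records into a modulation curve ordered by scan order.

    With ``direction="auto"`` the scanning direction is inferred from the
    table-position trend along the acquisition order: positions falling
    with instance number mean head-to-feet (HF). Records are re-sorted by
    instance number first, so the input ordering is immaterial.
    """
    if len(records) < 2:
        raise ValueError("need at least two slice records")
    recs = sorted(records, key=lambda r: (r.instance_number
                                          if r.instance_number is not None
                                          else 0))
    z = np.array([r.table_position for r in recs])
    dz = np.diff(z)
    if not (np.all(dz < 0) or np.all(dz > 0)):
        raise ValueError("table positions are not monotone along the"
                         " acquisition order")
    if direction == "auto":
        direction = "HF" if dz[0] < 0 else "FH"
    if any(r.ctdi_vol is None for r in recs):
        raise ValueError("cannot build a dose curve: some records lack"
                         " CTDIvol")
    proto = protocol or Protocol(
        "unknown", reference_mas=1.0,
        recon_thickness=(recs[0].recon_thickness or 1.0))
    return ModulationCurve(
        z=z, ctdi_vol=np.array([r.ctdi_vol for r in recs]),
        ma=np.array([r.ma for r in recs]), direction=direction,
        protocol=proto, phantom_name=phantom_name)


# ---------------------------------------------------------------------------
# CSV round-trips

def curve_to_csv(curve: ModulationCurve, path) -> None:
    pd.DataFrame({
        "index": np.arange(len(curve)),
        "table_position_mm": curve.z,
        "ma": curve.ma,
        "ctdi_vol_mGy": curve.ctdi_vol,
    }).to_csv(path, index=False)


def curve_from_csv(path, direction: str = "auto",
                   protocol: Protocol | None = None) -> ModulationCurve:
    df = pd.read_csv(path)
    z = df["table_position_mm"].to_numpy()
    if direction == "auto":
        direction = "HF" if z[1] < z[0] else "FH"
    proto = protocol or Protocol("unknown", reference_mas=1.0)
    return ModulationCurve(z=z, ctdi_vol=df["ctdi_vol_mGy"].to_numpy(),
                           ma=df["ma"].to_numpy(), direction=direction,
                           protocol=proto)


def profile_to_csv(profile: WEDProfile, path) -> None:
    pd.DataFrame({"table_position_mm": profile.z,
                  "wed_mm": profile.wed}).to_csv(path, index=False)


def profile_from_csv(path, source: str = "image") -> WEDProfile:
    df = pd.read_csv(path)
    return WEDProfile(z=df["table_position_mm"].to_numpy(),
                      wed=df["wed_mm"].to_numpy(), source=source)
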