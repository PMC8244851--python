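"""Series I/O: NIfTI + JSON sidecar (canonical), DICOM import, rescaling.

The canonical on-disk form of a series is one 3D NIfTI volume (two spatial
dimensions by the series dimension) plus a JSON sidecar holding the
acquisition metadata (modality, TR, TI list or flip angles, field strength,
vendor, pixel size, per-series scale factors, seed).  DICOM directories can
be imported; images are ordered by the inversion-time or flip-angle tag, not
by file name.  ``apply_intensity_rescale`` undoes vendor per-series scale
factors (Philips-style stored-value / scale-slope convention) so signal is
comparable across series points.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .phantom import ImageSeries

__all__ = [
    "SeriesMetadata",
    "write_series",
    "read_series",
    "apply_intensity_rescale",
]

_SIDECAR = "series.json"
_VOLUME = "series.nii"

#: Vendors whose exported magnitudes carry per-series scale slopes that must
#: be divided out before quantitative fitting.
VENDORS_REQUIRING_RESCALE = frozenset({"Philips"})


@dataclass
class SeriesMetadata:
    """Acquisition metadata carried next to the pixel data."""

    modality: str
    tr_ms: float
    series_values: tuple[float, ...]
    pixel_mm: float
    vendor: str = ""
    field_tesla: float | None = None
    scale_slopes: tuple[float, ...] | None = None  # one per series point
    acquisition_date: str | None = None
    phantom_id: str | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.series_values = tuple(float(v) for v in self.series_values)
        if self.scale_slopes is not None:
            slopes = tuple(float(s) for s in self.scale_slopes)
            if len(slopes) != len(self.series_values):
                raise ValueError("one scale slope per series point required")
            if not all(np.isfinite(s) and s != 0 for s in slopes):
                raise ValueError("scale slopes must be finite and nonzero")
            self.scale_slopes = slopes


def _metadata_from_series(series: ImageSeries) -> SeriesMetadata:
    if series.protocol is not None:
        p = series.protocol
        return SeriesMetadata(
            modality=p.modality,
            tr_ms=p.tr_ms,
            series_values=tuple(p.series_values),
            pixel_mm=p.pixel_mm,
            vendor=series.labels.get("vendor", ""),
            field_tesla=series.labels.get("field_tesla"),
            rng_seed=p.rng_seed,
        )
    md = dict(series.metadata)
    return SeriesMetadata(
        modality=md["modality"],
        tr_ms=md["tr_ms"],
        series_values=tuple(series.series_values),
        pixel_mm=md["pixel_mm"],
        vendor=md.get("vendor", ""),
        field_tesla=md.get("field_tesla"),
        scale_slopes=md.get("scale_slopes"),
        rng_seed=md.get("rng_seed"),
    )


def write_series(
    series: ImageSeries,
    path,
    format: str = "nifti",
    metadata: SeriesMetadata | None = None,
) -> Path:
    """Write a series to ``path`` (a directory) as NIfTI+JSON or DICOM files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    md = metadata or _metadata_from_series(series)
    if format == "nifti":
        import nibabel as nib

        vol = np.moveaxis(series.images, 0, -1)  # (ny, nx, n_series)
        affine = np.diag([md.pixel_mm, md.pixel_mm, 1.0, 1.0])
        img = nib.Nifti1Image(vol.astype(np.float64), affine)
        nib.save(img, path / _VOLUME)
        (path / _SIDECAR).write_text(json.dumps(asdict(md), indent=2))
    elif format == "dicom":
        _write_dicom_dir(series, path, md)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _write_dicom_dir(series: ImageSeries, path: Path, md: SeriesMetadata) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

    peak = series.images.max()
    slope = peak / 65535.0 if peak > 0 else 1.0
    for k, (img, sv) in enumerate(zip(series.images, series.series_values)):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.Manufacturer = md.vendor
        ds.MagneticFieldStrength = md.field_tesla
        ds.RepetitionTime = md.tr_ms
        if md.modality == "IR":
            ds.InversionTime = sv
            ds.FlipAngle = 90.0
        else:
            ds.FlipAngle = sv
        ds.Rows, ds.Columns = img.shape
        ds.PixelSpacing = [md.pixel_mm, md.pixel_mm]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.rint(img / slope).astype(np.uint16).tobytes()
        ds.save_as(path / f"image_{k:03d}.dcm", enforce_file_format=True)
    sidecar = asdict(md)
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2))


def read_series(path, format: str | None = None) -> ImageSeries:
    """Read a series directory written by :func:`write_series`.

    DICOM directories are ordered by the TI or flip-angle element of each
    file, independent of file names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = path / _SIDECAR
    if format is None:
        format = "nifti" if (path / _VOLUME).exists() else "dicom"
    if not sidecar_path.exists():
        raise ValueError(f"missing metadata sidecar {_SIDECAR} in {path}")
    raw = json.loads(sidecar_path.read_text())
    missing = [k for k in ("modality", "tr_ms", "series_values", "pixel_mm") if raw.get(k) is None]
    if missing:
        raise ValueError(f"metadata incomplete, missing fields: {missing}")
    md = SeriesMetadata(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})

    if format == "nifti":
        import nibabel as nib

        vol = np.asarray(nib.load(path / _VOLUME).dataobj, dtype=float)
        images = np.moveaxis(vol, -1, 0)
    elif format == "dicom":
        import pydicom

        entries = []
        for f in path.glob("*.dcm"):
            ds = pydicom.dcmread(f)
            sv = float(ds.InversionTime) if md.modality == "IR" else float(ds.FlipAngle)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            icpt = float(getattr(ds, "RescaleIntercept", 0.0))
            entries.append((sv, ds.pixel_array.astype(float) * slope + icpt))
        if not entries:
            raise ValueError(f"no DICOM files found in {path}")
        entries.sort(key=lambda e: e[0])
        if tuple(e[0] for e in entries) != md.series_values:
            raise ValueError("DICOM series variables do not match sidecar metadata")
        shapes = {e[1].shape for e in entries}
        if len(shapes) > 1:
            raise ValueError("mixed image geometries in DICOM series")
        images = np.stack([e[1] for e in entries])
    else:
        raise ValueError(f"unknown format {format!r}")

    return ImageSeries(
        images=images,
        series_values=md.series_values,
        labels={"vendor": md.vendor, "field_tesla": md.field_tesla},
        metadata=asdict(md),
    )


def apply_intensity_rescale(series: ImageSeries, metadata: SeriesMetadata) -> ImageSeries:
    """Divide each image by its per-series scale slope.

    No-op for vendors without scale factors; vendors known to require
    rescaling must provide them.
    """
    if metadata.scale_slopes is None:
        if metadata.vendor in VENDORS_REQUIRING_RESCALE:
            raise ValueError(
                f"vendor {metadata.vendor!r} requires per-series scale slopes"
            )
        return series
    slopes = np.asarray(metadata.scale_slopes, dtype=float)
    images = series.images / slopes[:, None, None]
    md = dict(series.metadata)
    md["scale_slopes"] = None  # factors consumed
    return ImageSeries(
        images=images,
        series_values=series.series_values,
        protocol=series.protocol,
        labels=dict(series.labels),
        truth=series.truth,
        metadata=md,
    )
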