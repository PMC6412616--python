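"""Reading, writing and rasterizing angiographic inputs.

Domain containers
-----------------
``FrameSequence``
    An ordered run of grayscale x-ray frames with a frame rate.  Higher
    intensity means brighter; iodinated contrast attenuates x-rays, so
    vessels and blush are *dark* in raw frames.
``RoiPolygon`` / ``RoiTrack``
    A fixed region of interest over the myocardium, and its per-frame
    manually adjusted version used for cardiac motion correction.
``BlushCurve``
    The per-frame blush intensity values the QuBE score is computed from.

Conventions
-----------
Coordinates are 0-based ``(row, col)`` with pixel centers at integer
coordinates.  A pixel belongs to a polygon iff its center is inside by
the even-odd rule; pixels whose center lies exactly on the boundary are
included.  Intensities are converted to floating point at read time; the
original bit depth is recorded but not used downstream.

Supported formats: multi-frame DICOM (modality XA, uncompressed pixel
data) and directories of single-frame TIFF/PNG images ordered
lexicographically by filename.  Writing is lossless by construction:
integer-valued sequences round-trip through uint8/uint16, anything else
through floating-point TIFF; DICOM output requires integer values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .errors import ContentError, FormatError

DEFAULT_FRAME_RATE_HZ = 12.5
"""Fallback acquisition rate when file metadata carries none (cine runs
in this pipeline are 12.5 frames per second)."""

_STACK_META = "sequence.json"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """Ordered grayscale frames plus acquisition frame rate."""

    frames: np.ndarray  # (n_frames, rows, cols) float array
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    id: str = ""
    source_dtype: str = ""  # original on-disk dtype, informational only

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim == 3:
            pass
        elif arr.ndim == 1 and arr.dtype == object or isinstance(self.frames, (list, tuple)):
            arr = np.stack([np.asarray(f, dtype=np.float64) for f in self.frames])
        else:
            raise ContentError(f"frames must be a (n, rows, cols) stack, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        if arr.shape[0] < 2:
            raise ContentError(f"a sequence needs at least 2 frames, got {arr.shape[0]}")
        if not np.all(np.isfinite(arr)):
            raise ContentError("frame intensities must be finite")
        if arr.min() < 0:
            raise ContentError("frame intensities must be non-negative")
        if not self.frame_rate_hz > 0:
            raise ContentError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def dims(self) -> Tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class RoiPolygon:
    """Simple polygon over the image plane, vertices as (row, col)."""

    vertices: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContentError("ROI vertices must be an (n, 2) array of (row, col)")
        if v.shape[0] < 3:
            raise ContentError(f"a polygon needs at least 3 vertices, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ContentError("ROI vertices must be finite")
        if not _is_simple_polygon(v):
            raise ContentError("ROI polygon must be simple (no self-intersection)")
        self.vertices = v

    def shifted(self, d_row: float, d_col: float) -> "RoiPolygon":
        return RoiPolygon(self.vertices + np.array([d_row, d_col]))

    def bounds(self) -> Tuple[float, float, float, float]:
        """(min_row, min_col, max_row, max_col)."""
        mn = self.vertices.min(axis=0)
        mx = self.vertices.max(axis=0)
        return mn[0], mn[1], mx[0], mx[1]


@dataclass
class RoiTrack:
    """One polygon per frame; the manually motion-corrected ROI."""

    polygons: List[RoiPolygon]

    def __post_init__(self) -> None:
        self.polygons = list(self.polygons)
        if not self.polygons:
            raise ContentError("an ROI track needs at least one polygon")
        for p in self.polygons:
            if not isinstance(p, RoiPolygon):
                raise ContentError("track entries must be RoiPolygon instances")

    def __len__(self) -> int:
        return len(self.polygons)

    def __getitem__(self, i: int) -> RoiPolygon:
        return self.polygons[i]


@dataclass
class BlushCurve:
    """Per-frame blush intensity values."""

    values: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ContentError("blush curve values must be finite")
        if not self.frame_rate_hz > 0:
            raise ContentError("frame_rate_hz must be > 0")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate_hz


Roi = Union[RoiPolygon, RoiTrack]


def _is_simple_polygon(vertices: np.ndarray) -> bool:
    from shapely.geometry import LinearRing

    try:
        ring = LinearRing([(float(c), float(r)) for r, c in vertices])
    except Exception:
        return False
    return bool(ring.is_simple) and ring.length > 0


# ---------------------------------------------------------------------------
# Sequence IO
# ---------------------------------------------------------------------------

def read_sequence(path, format: str = "auto", frame_rate_hz: float | None = None,
                  id: str | None = None) -> FrameSequence:
    """Read an angiogram run from a multi-frame DICOM file or an image-stack
    directory (lexicographically ordered single-frame TIFF/PNG files).

    ``frame_rate_hz`` overrides any rate found in file metadata; when
    neither is available the 12.5 Hz default applies.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if format == "auto":
        format = "image_stack" if path.is_dir() else "dicom"
    if format == "dicom":
        frames, meta_rate, dtype = _read_dicom(path)
    elif format == "image_stack":
        frames, meta_rate, dtype = _read_stack(path)
    else:
        raise FormatError(f"unknown sequence format {format!r}")
    rate = frame_rate_hz if frame_rate_hz is not None else (
        meta_rate if meta_rate is not None else DEFAULT_FRAME_RATE_HZ)
    return FrameSequence(frames=frames, frame_rate_hz=rate,
                         id=id if id is not None else path.stem, source_dtype=dtype)


def write_sequence(seq: FrameSequence, path, format: str = "image_stack") -> None:
    """Write a sequence losslessly.

    ``image_stack`` writes numbered TIFF files into a directory (uint8 /
    uint16 when the values are integers in range, 64-bit float otherwise)
    plus a small JSON sidecar carrying the frame rate.  ``dicom`` writes a
    single multi-frame XA file and, being integer-only, refuses
    non-integer intensities rather than rounding them (lossy encodings
    are never produced).
    """
    path = Path(path)
    if format == "image_stack":
        _write_stack(seq, path)
    elif format == "dicom":
        _write_dicom(seq, path)
    else:
        raise FormatError(f"unknown sequence format {format!r}")


def _integer_valued(frames: np.ndarray) -> bool:
    return bool(np.all(frames == np.round(frames)))


def _read_dicom(path: Path):
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - exercised via FormatError path
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if arr.ndim == 2:
        raise ContentError("DICOM file holds a single frame; a sequence needs >= 2")
    if arr.ndim != 3:
        raise ContentError(f"unexpected DICOM pixel array shape {arr.shape}")
    rate = None
    ft = getattr(ds, "FrameTime", None)
    if ft:
        rate = 1000.0 / float(ft)
    elif getattr(ds, "RecommendedDisplayFrameRate", None):
        rate = float(ds.RecommendedDisplayFrameRate)
    elif getattr(ds, "CineRate", None):
        rate = float(ds.CineRate)
    return arr.astype(np.float64), rate, str(arr.dtype)


def _write_dicom(seq: FrameSequence, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frames = seq.frames
    if not _integer_valued(frames):
        raise FormatError("DICOM output is integer-only; writing non-integer "
                          "intensities would be lossy (refused)")
    if frames.max() > 0xFFFF:
        raise FormatError("DICOM output limited to 16-bit unsigned intensities")
    as_int = frames.astype(np.uint16)
    bits = 8 if frames.max() <= 0xFF else 16
    if bits == 8:
        as_int = frames.astype(np.uint8)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.XRayAngiographicImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "XA"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.PatientName = seq.id or "anon"
    ds.PatientID = seq.id or "anon"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = seq.n_frames
    ds.Rows, ds.Columns = seq.dims
    ds.BitsAllocated = bits
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    ds.FrameTime = repr(1000.0 / seq.frame_rate_hz)  # ms, DS element
    ds.PixelData = as_int.tobytes()
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(str(path), enforce_file_format=True)


def _read_stack(path: Path):
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff", ".png"))
    if len(files) < 2:
        raise ContentError(f"image stack {path} holds {len(files)} frames; need >= 2")
    frames = []
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:
            raise FormatError(f"cannot read frame {f}: {exc}") from exc
        if img.ndim != 2:
            raise ContentError(f"frame {f.name} is not single-channel grayscale")
        frames.append(np.asarray(img))
    dims = frames[0].shape
    for f, img in zip(files, frames):
        if img.shape != dims:
            raise ContentError(
                f"inconsistent frame dimensions: {f.name} is {img.shape}, expected {dims}")
    rate = None
    meta = path / _STACK_META
    if meta.exists():
        rate = float(json.loads(meta.read_text()).get("frame_rate_hz"))
    dtype = str(frames[0].dtype)
    return np.stack(frames).astype(np.float64), rate, dtype


def _write_stack(seq: FrameSequence, path: Path) -> None:
    import tifffile

    path.mkdir(parents=True, exist_ok=True)
    frames = seq.frames
    if _integer_valued(frames) and frames.max() <= 0xFF:
        out = frames.astype(np.uint8)
    elif _integer_valued(frames) and frames.max() <= 0xFFFF:
        out = frames.astype(np.uint16)
    else:
        out = frames.astype(np.float64)  # lossless for arbitrary intensities
    width = max(4, len(str(seq.n_frames)))
    for i in range(seq.n_frames):
        tifffile.imwrite(path / f"frame_{i:0{width}d}.tif", out[i])
    (path / _STACK_META).write_text(json.dumps(
        {"frame_rate_hz": seq.frame_rate_hz, "id": seq.id}, indent=1))


# ---------------------------------------------------------------------------
# ROI IO
# ---------------------------------------------------------------------------

def read_roi(path) -> Roi:
    """Read an ROI polygon or per-frame track from JSON.

    Schema: ``{"type": "roi", "vertices": [[r, c], ...]}`` or
    ``{"type": "roi_track", "frames": [[[r, c], ...], ...]}``.  A track
    whose length disagrees with a sequence is detected at use time, not
    here.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except Exception as exc:
        raise FormatError(f"cannot parse ROI JSON {path}: {exc}") from exc
    return roi_from_dict(doc)


def roi_from_dict(doc: dict) -> Roi:
    kind = doc.get("type")
    if kind == "roi":
        return RoiPolygon(np.asarray(doc["vertices"], dtype=np.float64))
    if kind == "roi_track":
        return RoiTrack([RoiPolygon(np.asarray(v, dtype=np.float64))
                         for v in doc["frames"]])
    raise FormatError(f"unknown ROI document type {kind!r}")


def roi_to_dict(obj: Roi) -> dict:
    if isinstance(obj, RoiPolygon):
        return {"type": "roi", "vertices": obj.vertices.tolist()}
    if isinstance(obj, RoiTrack):
        return {"type": "roi_track",
                "frames": [p.vertices.tolist() for p in obj.polygons]}
    raise ContentError(f"cannot serialize {type(obj).__name__} as ROI")


def write_roi(obj: Roi, path) -> None:
    Path(path).write_text(json.dumps(roi_to_dict(obj)))


# ---------------------------------------------------------------------------
# Blush-curve IO
# ---------------------------------------------------------------------------

def read_curve(path) -> BlushCurve:
    """Read a blush curve CSV with mandatory header frame_index,time_s,value."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["frame_index", "time_s", "value"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"curve CSV must start with columns {required}, "
                          f"got {list(df.columns)}")
    if len(df) < 2:
        raise ContentError("a blush curve needs at least 2 points")
    dt = np.diff(df["time_s"].to_numpy())
    rate = 1.0 / float(np.mean(dt)) if np.all(dt > 0) else DEFAULT_FRAME_RATE_HZ
    return BlushCurve(values=df["value"].to_numpy(), frame_rate_hz=rate)


def write_curve(curve: BlushCurve, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "frame_index": np.arange(len(curve)),
        "time_s": curve.times_s,
        "value": curve.values,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_roi(roi: RoiPolygon, dims: Tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose center lies inside the polygon.

    Inclusion is the even-odd rule on pixel centers at integer (row, col)
    coordinates; centers exactly on the boundary count as inside.  The
    mask is clipped to ``dims``; an empty clipped mask is an error.
    """
    rows, cols = int(dims[0]), int(dims[1])
    if rows <= 0 or cols <= 0:
        raise ContentError(f"invalid frame dims {dims}")
    mask = np.zeros((rows, cols), dtype=bool)
    mn_r, mn_c, mx_r, mx_c = roi.bounds()
    r0 = max(0, int(math.ceil(mn_r - 1e-9)))
    r1 = min(rows - 1, int(math.floor(mx_r + 1e-9)))
    c0 = max(0, int(math.ceil(mn_c - 1e-9)))
    c1 = min(cols - 1, int(math.floor(mx_c + 1e-9)))
    if r0 > r1 or c0 > c1:
        raise ContentError("ROI polygon lies entirely outside the frame")
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1, dtype=np.float64),
                         np.arange(c0, c1 + 1, dtype=np.float64), indexing="ij")
    inside = _even_odd_inside(roi.vertices, rr, cc)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    if not mask.any():
        raise ContentError("ROI mask is empty after clipping to the frame")
    return mask


def _even_odd_inside(vertices: np.ndarray, rr: np.ndarray, cc: np.ndarray,
                     eps: float = 1e-9) -> np.ndarray:
    """Vectorized even-odd test with boundary points counted inside."""
    inside = np.zeros(rr.shape, dtype=bool)
    boundary = np.zeros(rr.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # crossing test: ray from the point toward +col
        cond = (r1 > rr) != (r2 > rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = c1 + (rr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= cond & (cc < c_int)
        # on-segment test
        dr, dc = r2 - r1, c2 - c1
        seg_len2 = dr * dr + dc * dc
        if seg_len2 == 0:
            on = (np.abs(rr - r1) <= eps) & (np.abs(cc - c1) <= eps)
        else:
            cross = (rr - r1) * dc - (cc - c1) * dr
            t = ((rr - r1) * dr + (cc - c1) * dc) / seg_len2
            on = (np.abs(cross) <= eps * math.sqrt(seg_len2)) & (t >= -eps) & (t <= 1 + eps)
        boundary |= on
    return inside | boundary
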