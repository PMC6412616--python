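"""Quantitative blush evaluation (QuBE) core pipeline.

Per frame the pipeline is:

1. **Contrast inversion** — raw angiograms show contrast as dark; every
   frame is replaced by ``global_max - value`` so contrast density is
   positive and "brightest" means most contrast.
2. **Large-structure removal** — a square median filter (native kernel
   35 x 35 px) estimates the background of arteries, diaphragm and other
   large structures; subtracting it leaves the mid/high-spatial-frequency
   residual that contains the myocardial blush.
3. **Blush value** — within the region of interest, the residual is mean
   smoothed (5 x 5) and the blush value of the frame is the local average
   of the few brightest pixels (the k = max(10, ceil(2% of ROI area))
   largest smoothed residuals).
4. **Panning correction** — a rudimentary translation correction: each
   frame's integer offset against a reference frame is estimated by
   maximizing normalized cross-correlation over the overlap, and the ROI
   is shifted along with it.

The QuBE score of the resulting per-frame blush curve is the maximum
increase plus the maximum decrease of intensity, both taken over all
ordered frame pairs.

Two implementation notes.  The median uses the order statistic at rank
``side**2 // 2`` (the exact median for odd windows, the upper-middle
value for even ones — the paper's 20 and 50 px kernels are even) with
edge replication at the frame border and the window centered at
``floor(side/2)``.  Integer-valued frames take a histogram-based O(side)
path; arbitrary float frames take an exact generic path with the same
convention.  ``compute_blush_curve`` filters only the ROI neighbourhood
(bounding box dilated by kernel + smoothing), which is exactly
equivalent to whole-frame filtering for every pixel that contributes to
the blush value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.fft
import scipy.ndimage

from .angio_io import (BlushCurve, FrameSequence, Roi, RoiPolygon, RoiTrack,
                       rasterize_roi)
from .errors import ContentError

__all__ = [
    "KernelSpec", "BlushOptions", "QubeResult",
    "invert_contrast", "median_filter_background", "subtract_background",
    "frame_blush_value", "estimate_panning_offsets", "compute_blush_curve",
    "qube_score", "load_options",
]


@dataclass(frozen=True)
class KernelSpec:
    """Square median-filter kernel; the native configuration uses 35 px."""

    side_px: int = 35

    def __post_init__(self) -> None:
        if int(self.side_px) != self.side_px or self.side_px < 3:
            raise ContentError(f"kernel side must be an integer >= 3, got {self.side_px}")
        object.__setattr__(self, "side_px", int(self.side_px))


@dataclass(frozen=True)
class BlushOptions:
    """Tunable knobs of the blush pipeline.

    The defaults reproduce the native configuration: 35 px median kernel,
    blush value from the brightest max(10, ceil(2% of ROI area)) pixels
    after 5 x 5 mean smoothing, panning correction on with a +-20 px
    integer search radius.
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    top_fraction: float = 0.02
    min_top_pixels: int = 10
    smoothing_side_px: int = 5
    panning_correction: bool = True
    panning_search_radius_px: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ContentError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.min_top_pixels < 1:
            raise ContentError("min_top_pixels must be >= 1")
        if self.smoothing_side_px < 1 or self.smoothing_side_px % 2 == 0:
            raise ContentError("smoothing_side_px must be an odd integer >= 1")
        if self.panning_search_radius_px < 0:
            raise ContentError("panning_search_radius_px must be >= 0")

    def with_kernel(self, side_px: int) -> "BlushOptions":
        return replace(self, kernel=KernelSpec(side_px))


@dataclass
class QubeResult:
    """QuBE score with its decomposition and provenance.

    ``score = max_increase_a + max_decrease_b`` where ``a`` is the largest
    rise ``v_j - v_i`` (i < j) of the blush curve floored at 0 and ``b``
    the largest fall, also floored at 0.  ``offsets`` holds the per-frame
    integer panning translation applied (empty when panning was off).
    """

    score: float
    max_increase_a: float
    max_decrease_b: float
    curve: BlushCurve
    offsets: List[Tuple[int, int]] = field(default_factory=list)


def load_options(path) -> BlushOptions:
    """Build :class:`BlushOptions` from a YAML or JSON config file that
    mirrors its field names (``kernel`` given as the side in pixels)."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ContentError(f"options config {path} must be a mapping")
    kw = dict(doc)
    if "kernel" in kw:
        kw["kernel"] = KernelSpec(int(kw["kernel"]))
    return BlushOptions(**kw)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def invert_contrast(seq: FrameSequence) -> FrameSequence:
    """Flip polarity so contrast density is positive.

    Every frame becomes ``global_max - value`` with ``global_max`` the
    maximum intensity over the whole sequence, preserving the ordering of
    contrast density across frames.
    """
    gmax = float(seq.frames.max())
    return FrameSequence(frames=gmax - seq.frames, frame_rate_hz=seq.frame_rate_hz,
                         id=seq.id, source_dtype=seq.source_dtype)


def median_filter_background(frame: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Median-filtered background estimate of one frame.

    Each output pixel is the median of its ``side x side`` neighbourhood
    (window centered at ``floor(side/2)``; even-count windows use the
    upper-middle order statistic), with edge replication at the border.
    """
    if isinstance(kernel, int):
        kernel = KernelSpec(kernel)
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ContentError("median_filter_background expects a single 2-D frame")
    k = kernel.side_px
    if k > min(frame.shape):
        raise ContentError(f"kernel side {k} exceeds frame dims {frame.shape}")
    fast = _as_small_uint(frame)
    if fast is not None:
        return _median_uint(fast[0], k).astype(np.float64) * fast[1]
    # generic exact path, same rank convention
    return scipy.ndimage.rank_filter(frame.astype(np.float64), rank=k * k // 2,
                                     size=k, mode="nearest")


def _as_small_uint(frame: np.ndarray):
    """Return (uint array, scale) when the frame is non-negative integer
    valued and fits uint8/uint16, else None.  scale restores float units."""
    if frame.size == 0 or frame.min() < 0:
        return None
    if not np.all(frame == np.floor(frame)):
        return None
    mx = frame.max()
    if mx <= 0xFF:
        return frame.astype(np.uint8), 1.0
    if mx <= 0xFFFF:
        return frame.astype(np.uint16), 1.0
    return None


def _median_uint(frame: np.ndarray, k: int) -> np.ndarray:
    """Histogram rank median with edge replication via padding.

    Padding by the full window guarantees every retained pixel sees a
    complete window, so the ignore-outside border rule of the rank filter
    never applies and the result equals replicate-border filtering.
    """
    from skimage.filters import rank
    import warnings

    pad = k
    padded = np.pad(frame, pad, mode="edge")
    fp = np.ones((k, k), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # bit-depth performance note
        out = rank.median(padded, footprint=fp)
    # rank.median centers even footprints at floor(side/2) like rank_filter
    return out[pad:pad + frame.shape[0], pad:pad + frame.shape[1]]


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Residual ``frame - background`` clipped below at 0.

    Negative residuals (background brighter than the frame) carry no
    contrast density and are clipped rather than propagated.
    """
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ContentError(
            f"frame {frame.shape} and background {background.shape} dims differ")
    return np.clip(frame - background, 0.0, None)


def frame_blush_value(residual: np.ndarray, mask: np.ndarray,
                      opts: BlushOptions = BlushOptions()) -> float:
    """Blush value of one frame: local average of the brightest pixels.

    The residual is mean-smoothed with a ``smoothing_side_px`` square
    window (edge replication) and the value is the mean of the
    ``k = max(min_top_pixels, ceil(top_fraction * mask_area))`` largest
    smoothed residuals inside the mask.  The mean of the k largest values
    is invariant to which of several tied pixels at the cut are chosen,
    so ties need no further rule.
    """
    residual = np.asarray(residual, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if residual.shape != mask.shape:
        raise ContentError("residual and mask dims differ")
    area = int(mask.sum())
    if area == 0:
        raise ContentError("empty ROI mask")
    if opts.smoothing_side_px > 1:
        smoothed = scipy.ndimage.uniform_filter(
            residual, size=opts.smoothing_side_px, mode="nearest")
    else:
        smoothed = residual
    vals = smoothed[mask]
    k = min(area, max(opts.min_top_pixels, math.ceil(opts.top_fraction * area)))
    top = np.partition(vals, area - k)[area - k:]
    return float(top.mean())


# ---------------------------------------------------------------------------
# Panning correction
# ---------------------------------------------------------------------------

def estimate_panning_offsets(seq: FrameSequence, reference_index: int = 0,
                             radius_px: int = 20) -> List[Tuple[int, int]]:
    """Integer translation of every frame against a reference frame.

    For each frame the offset ``(d_row, d_col)`` within ``+-radius_px``
    maximizing the normalized cross-correlation with the reference over
    their overlap is returned; ties are broken by smallest Euclidean norm,
    then row-major order.  The reference frame maps to (0, 0).  An offset
    ``d`` means the frame content sits at the reference content translated
    by ``d`` — shifting the ROI by ``d`` follows the panned anatomy.
    """
    n, (rows, cols) = seq.n_frames, seq.dims
    if not (0 <= reference_index < n):
        raise ContentError(f"reference_index {reference_index} out of range")
    if radius_px < 0:
        raise ContentError("radius must be >= 0")
    if radius_px >= min(rows, cols) / 2:
        raise ContentError(
            f"search radius {radius_px} too large for {rows}x{cols} frames")
    if radius_px == 0:
        return [(0, 0)] * n

    ref = seq.frames[reference_index].astype(np.float64)
    shape = (scipy.fft.next_fast_len(rows + radius_px),
             scipy.fft.next_fast_len(cols + radius_px))
    ref_hat = scipy.fft.rfft2(ref, shape)
    int_ref, int_ref2 = _integral_images(ref)
    lag_r, lag_c = np.meshgrid(np.arange(-radius_px, radius_px + 1),
                               np.arange(-radius_px, radius_px + 1), indexing="ij")
    # overlap rectangle in moving-frame coordinates for each lag
    r0 = np.maximum(0, lag_r); r1 = rows - 1 + np.minimum(0, lag_r)
    c0 = np.maximum(0, lag_c); c1 = cols - 1 + np.minimum(0, lag_c)
    n_px = (r1 - r0 + 1) * (c1 - c0 + 1)

    offsets: List[Tuple[int, int]] = []
    for i in range(n):
        if i == reference_index:
            offsets.append((0, 0))
            continue
        mov = seq.frames[i].astype(np.float64)
        cross_full = scipy.fft.irfft2(scipy.fft.rfft2(mov, shape) * np.conj(ref_hat),
                                      shape)
        cross = cross_full[lag_r % shape[0], lag_c % shape[1]]
        int_mov, int_mov2 = _integral_images(mov)
        s_m = _rect_sum(int_mov, r0, r1, c0, c1)
        s_m2 = _rect_sum(int_mov2, r0, r1, c0, c1)
        s_r = _rect_sum(int_ref, r0 - lag_r, r1 - lag_r, c0 - lag_c, c1 - lag_c)
        s_r2 = _rect_sum(int_ref2, r0 - lag_r, r1 - lag_r, c0 - lag_c, c1 - lag_c)
        num = cross - s_m * s_r / n_px
        var_m = np.maximum(s_m2 - s_m ** 2 / n_px, 0.0)
        var_r = np.maximum(s_r2 - s_r ** 2 / n_px, 0.0)
        den = np.sqrt(var_m * var_r)
        scale = max(den.max(), 1e-300)
        ncc = np.where(den > 1e-9 * scale, num / np.maximum(den, 1e-300), -np.inf)
        offsets.append(_argmax_with_ties(ncc, lag_r, lag_c))
    return offsets


def _integral_images(a: np.ndarray):
    pad = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    pad2 = pad.copy()
    np.cumsum(np.cumsum(a, 0), 1, out=pad[1:, 1:])
    np.cumsum(np.cumsum(a * a, 0), 1, out=pad2[1:, 1:])
    return pad, pad2


def _rect_sum(integral: np.ndarray, r0, r1, c0, c1):
    return (integral[r1 + 1, c1 + 1] - integral[r0, c1 + 1]
            - integral[r1 + 1, c0] + integral[r0, c0])


def _argmax_with_ties(ncc: np.ndarray, lag_r: np.ndarray, lag_c: np.ndarray,
                      rtol: float = 1e-9) -> Tuple[int, int]:
    best = ncc.max()
    if not np.isfinite(best):
        cand = np.ones_like(ncc, dtype=bool)
    else:
        cand = ncc >= best - rtol * max(1.0, abs(best))
    rs, cs = lag_r[cand], lag_c[cand]
    order = np.lexsort((cs, rs, rs * rs + cs * cs))
    return int(rs[order[0]]), int(cs[order[0]])


# ---------------------------------------------------------------------------
# Blush curve and score
# ---------------------------------------------------------------------------

def compute_blush_curve(seq: FrameSequence, roi: Roi,
                        opts: BlushOptions = BlushOptions(),
                        offsets: Optional[Sequence[Tuple[int, int]]] = None,
                        ) -> Tuple[BlushCurve, List[Tuple[int, int]]]:
    """Blush curve of a sequence: invert, median background, subtract,
    panning-shift the ROI, blush value — once per frame.

    ``roi`` may be a fixed :class:`RoiPolygon` (panning correction applies
    when enabled) or an :class:`RoiTrack` of per-frame polygons, in which
    case panning is skipped because the track already encodes the motion.
    Precomputed ``offsets`` may be supplied to reuse a panning estimate
    across configurations.  Returns the curve and the offsets applied.
    """
    n = seq.n_frames
    dims = seq.dims
    if isinstance(roi, RoiTrack):
        if len(roi) != n:
            raise ContentError(
                f"ROI track length {len(roi)} does not match {n} frames")
        polygons = list(roi.polygons)
        applied = [(0, 0)] * n
    else:
        if offsets is not None:
            applied = [(int(dr), int(dc)) for dr, dc in offsets]
            if len(applied) != n:
                raise ContentError("precomputed offsets length mismatch")
        elif opts.panning_correction and opts.panning_search_radius_px > 0:
            applied = estimate_panning_offsets(
                seq, radius_px=opts.panning_search_radius_px)
        else:
            applied = [(0, 0)] * n
        polygons = [roi.shifted(dr, dc) for dr, dc in applied]

    inv = invert_contrast(seq)
    k = opts.kernel.side_px
    if k > min(dims):
        raise ContentError(f"kernel side {k} exceeds frame dims {dims}")
    margin = k + opts.smoothing_side_px
    values = np.empty(n)
    for i in range(n):
        try:
            values[i] = _frame_value_cropped(inv.frames[i], polygons[i], opts, margin)
        except ContentError as exc:
            raise ContentError(f"frame {i}: {exc}") from exc
    curve = BlushCurve(values=values, frame_rate_hz=seq.frame_rate_hz)
    return curve, applied


def _frame_value_cropped(frame: np.ndarray, poly: RoiPolygon,
                         opts: BlushOptions, margin: int) -> float:
    """Blush value via a crop of the ROI neighbourhood.

    The crop extends ``margin >= kernel + smoothing`` beyond the polygon
    bounding box (clipped to the frame), so every pixel feeding the blush
    value sees complete median and smoothing windows, or windows cut by
    the true frame border where replication applies identically — the
    result equals the whole-frame pipeline exactly.
    """
    rows, cols = frame.shape
    mn_r, mn_c, mx_r, mx_c = poly.bounds()
    r0 = max(0, int(math.floor(mn_r)) - margin)
    r1 = min(rows - 1, int(math.ceil(mx_r)) + margin)
    c0 = max(0, int(math.floor(mn_c)) - margin)
    c1 = min(cols - 1, int(math.ceil(mx_c)) + margin)
    if r0 > r1 or c0 > c1 or mx_r < 0 or mx_c < 0 or mn_r > rows - 1 or mn_c > cols - 1:
        raise ContentError("ROI lies outside the frame")
    k = opts.kernel.side_px
    if r1 - r0 + 1 < k or c1 - c0 + 1 < k:  # small frame: fall back to full frame
        r0, c0, r1, c1 = 0, 0, rows - 1, cols - 1
    crop = frame[r0:r1 + 1, c0:c1 + 1]
    background = median_filter_background(crop, opts.kernel)
    residual = subtract_background(crop, background)
    mask = rasterize_roi(poly.shifted(-r0, -c0), crop.shape)
    return frame_blush_value(residual, mask, opts)


def qube_score(curve: BlushCurve, offsets: Optional[List[Tuple[int, int]]] = None,
               ) -> QubeResult:
    """QuBE score: maximum increase plus maximum decrease of the curve.

    ``a = max_{i<j} (v_j - v_i)`` and ``b = max_{i<j} (v_i - v_j)``, both
    floored at 0; the score is ``a + b``.  Both extrema are over all
    ordered frame pairs (global rise and fall, not consecutive frames).
    """
    v = curve.values
    if len(v) < 2:
        raise ContentError(f"QuBE score needs >= 2 curve points, got {len(v)}")
    run_min = np.minimum.accumulate(v)
    run_max = np.maximum.accumulate(v)
    a = max(0.0, float(np.max(v[1:] - run_min[:-1])))
    b = max(0.0, float(np.max(run_max[:-1] - v[1:])))
    return QubeResult(score=a + b, max_increase_a=a, max_decrease_b=b,
                      curve=curve, offsets=list(offsets) if offsets else [])


def score_sequence(seq: FrameSequence, roi: Roi,
                   opts: BlushOptions = BlushOptions(),
                   offsets: Optional[Sequence[Tuple[int, int]]] = None) -> QubeResult:
    """Convenience wrapper: blush curve then QuBE score."""
    curve, applied = compute_blush_curve(seq, roi, opts, offsets=offsets)
    return qube_score(curve, offsets=applied)
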