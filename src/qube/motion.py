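"""Cardiac-motion-corrected blush analysis.

The native pipeline keeps one fixed ROI (plus integer panning
correction); cardiac motion is a mix of translation, rotation and
non-isotropic deformation that the fixed ROI cannot follow.  Manual
correction is represented here as externally supplied per-frame ROI
tracks — the workflow of observers who adjust the ROI on every frame so
it marks the same area of myocardium throughout.  This module computes
motion-corrected curves, compares them with the native ones (per-frame
Pearson correlation and paired QuBE scores), and models observer
variability as Gaussian vertex jitter on a track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .angio_io import BlushCurve, FrameSequence, RoiPolygon, RoiTrack
from .blush_core import (BlushOptions, QubeResult, compute_blush_curve,
                         qube_score)
from .errors import ContentError

__all__ = ["MotionComparison", "motion_corrected_curve",
           "compare_native_vs_corrected", "pearson_r", "jitter_track"]


@dataclass
class MotionComparison:
    """Native (fixed ROI) vs motion-corrected (tracked ROI) analysis of one
    sequence: both blush curves, their per-frame Pearson correlation, and
    both QuBE scores."""

    curve_native: BlushCurve
    curve_corrected: BlushCurve
    pearson_r: float          # NaN when either curve is constant
    score_native: QubeResult
    score_corrected: QubeResult


def motion_corrected_curve(seq: FrameSequence, track: RoiTrack,
                           opts: BlushOptions = BlushOptions()) -> BlushCurve:
    """Blush curve with frame ``i`` evaluated inside the track's ``i``-th
    polygon.  Panning correction does not apply — the track already
    encodes the motion."""
    if len(track) != seq.n_frames:
        raise ContentError(f"track length {len(track)} does not match "
                           f"{seq.n_frames} frames")
    curve, _ = compute_blush_curve(seq, track, opts)
    return curve


def compare_native_vs_corrected(seq: FrameSequence, roi: RoiPolygon,
                                track: RoiTrack,
                                opts: BlushOptions = BlushOptions(),
                                ) -> MotionComparison:
    """Run both analyses on one sequence and compare them."""
    curve_nat, offsets = compute_blush_curve(seq, roi, opts)
    curve_cor = motion_corrected_curve(seq, track, opts)
    return MotionComparison(
        curve_native=curve_nat,
        curve_corrected=curve_cor,
        pearson_r=pearson_r(curve_nat.values, curve_cor.values),
        score_native=qube_score(curve_nat, offsets=offsets),
        score_corrected=qube_score(curve_cor),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    When either vector is constant the coefficient is undefined and NaN
    is returned (a flagged missing value — never coerced to 0).
    Downstream summaries skip NaN entries and log how many were skipped.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ContentError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ContentError("pearson_r needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def jitter_track(track: RoiTrack, sigma_px: float, seed: int = 0,
                 rng: Optional[np.random.Generator] = None) -> RoiTrack:
    """Observer-variability model: independent Gaussian jitter (std
    ``sigma_px``) added to every vertex of every polygon of a track."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for p in track.polygons:
        out.append(RoiPolygon(p.vertices + rng.normal(0.0, sigma_px,
                                                      size=p.vertices.shape)))
    return RoiTrack(out)
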