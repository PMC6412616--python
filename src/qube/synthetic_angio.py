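"""Synthetic coronary angiogram simulator with known ground truth.

Real angiographic runs of myocardial blush are not publicly available,
so every pipeline stage is exercised on simulated scenes that contain
the ingredients that make blush quantification hard:

* a dark epicardial **vessel tree** (quadratic Bezier branches with
  Gaussian cross-sections) opacifying and washing out with its own
  bolus-transit profile,
* a static dark **diaphragm** edge and a static **catheter**,
* a mid-spatial-frequency **blush region**: a spatial Gaussian (default
  scale 45 px) whose amplitude follows a gamma-variate time curve
  ``h(t) = A * ((t-t0)/tp)**alpha * exp(alpha * (1 - (t-t0)/tp))`` for
  ``t > t0`` (0 before arrival), normalized so ``h(t0+tp) = A``,
* rigid **cardiac motion** (sinusoidal translation + rotation about the
  image center), slow linear **panning drift**, and additive Gaussian
  noise.

Frames are composited as dark structures on a bright background (raw
angiogram polarity), rigid-motion warped with bilinear interpolation,
noise-corrupted, and by default quantized to 8-bit — the integer depth
of typical cine runs.  Everything is deterministic given the seed.

Cohorts mirror the four-level Myocardial Blush Grade (MBG 0-3): in
``associated`` mode the blush amplitude increases with the assigned
grade (with per-patient jitter); in ``null`` mode amplitudes are drawn
from one distribution regardless of grade, giving a negative control for
association statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.ndimage

from .angio_io import (BlushCurve, FrameSequence, RoiPolygon, RoiTrack,
                       read_sequence, write_sequence)
from .errors import ContentError

__all__ = [
    "SimulationParams", "SyntheticGroundTruth", "SyntheticCohort",
    "CohortPatient", "gamma_variate", "simulate_sequence", "true_blush_curve",
    "make_cohort", "near_bifurcation_params", "write_cohort", "load_cohort",
]


def gamma_variate(t, t0_s: float, tp_s: float, alpha: float,
                  amplitude: float = 1.0):
    """Gamma-variate bolus curve, peak-normalized: value at ``t0+tp`` is
    exactly ``amplitude``; 0 at and before arrival ``t0``."""
    t = np.asarray(t, dtype=np.float64)
    x = (t - t0_s) / tp_s
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = amplitude * np.power(x[pos], alpha) * np.exp(alpha * (1.0 - x[pos]))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimulationParams:
    """Scene, kinetics, motion and noise settings of one simulated run."""

    dims: Tuple[int, int] = (256, 256)
    n_frames: int = 60
    frame_rate_hz: float = 12.5
    background_level: float = 200.0
    # blush
    blush_center: Tuple[float, float] = (150.0, 150.0)
    blush_sigma_px: float = 45.0
    blush_amplitude: float = 30.0
    t0_s: float = 1.0
    tp_s: float = 1.6
    alpha: float = 3.0
    # vessel tree
    include_vessels: bool = True
    n_branches: int = 3          # root branches off the trunk
    n_branch_levels: int = 3
    vessel_width_px: Tuple[float, float] = (3.0, 7.0)
    vessel_contrast: float = 70.0
    vessel_t0_s: float = 0.4
    vessel_tp_s: float = 0.8
    vessel_alpha: float = 2.0
    # diaphragm and catheter
    include_diaphragm: bool = True
    diaphragm_edge_row: float = 215.0
    diaphragm_soft_width_px: float = 12.0
    diaphragm_contrast: float = 35.0
    include_catheter: bool = True
    catheter_width_px: float = 4.0
    catheter_contrast: float = 60.0
    # motion
    cardiac_period_s: float = 0.8
    translation_amplitude_px: Tuple[float, float] = (4.0, 3.0)
    rotation_amplitude_deg: float = 1.5
    panning_drift_px: Tuple[float, float] = (0.15, 0.25)
    motion_phase_rad: float = 0.0
    # noise / quantization
    noise_sigma: float = 2.0
    bit_depth: Optional[int] = 8   # None disables quantization
    # reference ROI (defaults to a square around the blush center)
    roi_center: Optional[Tuple[float, float]] = None
    roi_half_side_px: float = 40.0
    # optional pinned bifurcation just outside the ROI (motion-artifact scenario)
    bifurcation_point: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.blush_center
        if not (0 <= r < self.dims[0] and 0 <= c < self.dims[1]):
            raise ContentError(f"blush center {self.blush_center} outside "
                               f"frame dims {self.dims}")
        for name in ("blush_amplitude", "blush_sigma_px", "vessel_contrast",
                     "diaphragm_contrast", "catheter_contrast", "noise_sigma",
                     "background_level"):
            if getattr(self, name) < 0:
                raise ContentError(f"{name} must be >= 0")
        if self.cardiac_period_s <= 0:
            raise ContentError("cardiac period must be > 0")
        if self.n_frames < 2:
            raise ContentError("need at least 2 frames")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def reference_roi(self) -> RoiPolygon:
        cr, cc = self.roi_center if self.roi_center is not None else self.blush_center
        h = self.roi_half_side_px
        return RoiPolygon(np.array([[cr - h, cc - h], [cr - h, cc + h],
                                    [cr + h, cc + h], [cr + h, cc - h]]))


@dataclass
class SyntheticGroundTruth:
    """What the simulator knows and the pipeline must recover."""

    true_curve: BlushCurve                      # h(t) sampled at frame times
    motion_per_frame: List[Tuple[float, float, float]]  # (d_row, d_col, theta_deg)
    structure_masks: Dict[str, np.ndarray]      # reference-pose binary masks
    roi_reference: RoiPolygon
    roi_track_truth: RoiTrack                   # reference ROI under each frame's motion
    params: Optional[SimulationParams] = None


@dataclass
class CohortPatient:
    patient_id: str
    sequence: FrameSequence
    ground_truth: SyntheticGroundTruth
    mbg_grade: int
    blush_amplitude: float


@dataclass
class SyntheticCohort:
    patients: List[CohortPatient]
    grade_amplitudes: Dict[int, float]
    mode: str

    def grades(self) -> List[int]:
        return [p.mbg_grade for p in self.patients]


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    """Quadratic Bezier sampled at n points, returned as (n, 2) (row, col)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _stamp_curve(canvas: np.ndarray, pts: np.ndarray, width_px: float) -> None:
    """Overlay a Gaussian-cross-section tube along a sampled curve.

    The canvas accumulates the maximum of per-sample radial bumps, so
    overlapping samples do not brighten each other.
    """
    rows, cols = canvas.shape
    sigma = max(width_px / 2.0, 0.6)
    rad = int(math.ceil(3 * sigma))
    offs = np.arange(-rad, rad + 1, dtype=np.float64)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    for r, c in pts:
        ir, ic = int(round(r)), int(round(c))
        if ir < -rad or ir >= rows + rad or ic < -rad or ic >= cols + rad:
            continue
        bump = np.exp(-((dr + ir - r) ** 2 + (dc + ic - c) ** 2) / (2 * sigma ** 2))
        r0, r1 = max(0, ir - rad), min(rows, ir + rad + 1)
        c0, c1 = max(0, ic - rad), min(cols, ic + rad + 1)
        br0, bc0 = r0 - (ir - rad), c0 - (ic - rad)
        view = canvas[r0:r1, c0:c1]
        np.maximum(view, bump[br0:br0 + (r1 - r0), bc0:bc0 + (c1 - c0)], out=view)


def _vessel_tree(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Random epicardial tree in the left half of the frame (profile, peak 1).

    Branch geometry is confined to columns left of the reference ROI so
    that, under default motion, vessels never enter a blush-centered ROI;
    the pinned bifurcation of :func:`near_bifurcation_params` is the
    deliberate exception.
    """
    rows, cols = params.dims
    canvas = np.zeros(params.dims)
    w_lo, w_hi = params.vessel_width_px
    scale = rows / 256.0
    # keep the random tree clear of the reference ROI: Bezier curves stay in
    # the convex hull of their control points, so clamping columns suffices
    col_limit = max(10.0, params.reference_roi().bounds()[1] - 20.0)

    def _pt(r, c):
        return (r, min(c, col_limit))

    trunk = _bezier(_pt(-5.0, 70 * scale + rng.uniform(-10, 10) * scale),
                    _pt(110 * scale, 85 * scale + rng.uniform(-20, 20) * scale),
                    _pt(rows - 20.0, 55 * scale + rng.uniform(-15, 15) * scale),
                    max(60, int(rows * 1.2)))
    _stamp_curve(canvas, trunk, w_hi)
    parents = [trunk]
    width = w_hi
    for _ in range(max(0, params.n_branch_levels - 1)):
        width = max(w_lo, 0.65 * width)
        children = []
        for parent in parents:
            for _ in range(params.n_branches if parent is trunk else 1):
                u = rng.uniform(0.15, 0.8)
                start = parent[int(u * (len(parent) - 1))]
                end = start + np.array([rng.uniform(30, 80) * scale,
                                        -rng.uniform(15, 55) * scale])
                ctrl = (start + end) / 2 + rng.uniform(-15, 15, size=2) * scale
                child = _bezier(_pt(*start), _pt(*ctrl), _pt(*end),
                                max(30, int(rows * 0.4)))
                _stamp_curve(canvas, child, width)
                children.append(child)
        parents = children
    if params.bifurcation_point is not None:
        _stamp_bifurcation(canvas, params)
    return canvas


def _stamp_bifurcation(canvas: np.ndarray, params: SimulationParams) -> None:
    """Pinned fork adjacent to the reference ROI: a feeding segment ending
    at the bifurcation point plus two daughters running alongside the ROI
    edge, so rigid motion sweeps vessel pixels across the ROI border."""
    br, bc = params.bifurcation_point
    w = params.vessel_width_px[1]
    feed = _bezier((br - 10, bc - 45), (br - 2, bc - 22), (br, bc), 70)
    up = _bezier((br, bc), (br - 28, bc + 3), (br - 55, bc - 4), 80)
    down = _bezier((br, bc), (br + 28, bc + 3), (br + 55, bc - 4), 80)
    for pts in (feed, up, down):
        _stamp_curve(canvas, pts, w)


def _catheter_map(params: SimulationParams) -> np.ndarray:
    rows, cols = params.dims
    canvas = np.zeros(params.dims)
    s = rows / 256.0
    pts = _bezier((0.0, 18 * s), (rows / 2, 6 * s), (rows - 1.0, 30 * s),
                  max(60, int(rows * 1.2)))
    _stamp_curve(canvas, pts, params.catheter_width_px)
    return canvas * params.catheter_contrast


def _diaphragm_map(params: SimulationParams) -> np.ndarray:
    rows, cols = params.dims
    rr = np.arange(rows, dtype=np.float64)[:, None]
    soft = 1.0 / (1.0 + np.exp(-(rr - params.diaphragm_edge_row)
                               / params.diaphragm_soft_width_px))
    return np.broadcast_to(soft * params.diaphragm_contrast, params.dims).copy()


def _motion_transform(params: SimulationParams, t: float, frame_index: int):
    """(d_row, d_col, theta_deg) of the frame's rigid motion."""
    phase = 2 * math.pi * t / params.cardiac_period_s + params.motion_phase_rad
    s = math.sin(phase)
    dr = params.translation_amplitude_px[0] * s + params.panning_drift_px[0] * frame_index
    dc = params.translation_amplitude_px[1] * s + params.panning_drift_px[1] * frame_index
    theta = params.rotation_amplitude_deg * s
    return dr, dc, theta


def _apply_motion_to_points(pts: np.ndarray, motion, center) -> np.ndarray:
    dr, dc, theta = motion
    th = math.radians(theta)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return (pts - center) @ rot.T + center + np.array([dr, dc])


def _warp_frame(frame: np.ndarray, motion, center) -> np.ndarray:
    """Rigid warp: content at reference point p appears at T(p).

    Bilinear interpolation, edge replication; sub-pixel motion is
    intended — it stresses the integer panning correction downstream.
    """
    dr, dc, theta = motion
    if dr == 0 and dc == 0 and theta == 0:
        return frame
    th = math.radians(theta)
    rot_inv = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    center = np.asarray(center)
    offset = center - rot_inv @ (center + np.array([dr, dc]))
    return scipy.ndimage.affine_transform(frame, rot_inv, offset=offset,
                                          order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_sequence(params: SimulationParams
                      ) -> Tuple[FrameSequence, SyntheticGroundTruth]:
    """Render one angiographic run and its ground truth."""
    rng = np.random.default_rng(params.seed)
    rows, cols = params.dims
    rr, cc = np.meshgrid(np.arange(rows, dtype=np.float64),
                         np.arange(cols, dtype=np.float64), indexing="ij")
    br, bc = params.blush_center
    blush_spatial = np.exp(-((rr - br) ** 2 + (cc - bc) ** 2)
                           / (2 * params.blush_sigma_px ** 2))
    vessel = _vessel_tree(params, rng) if params.include_vessels else np.zeros(params.dims)
    diaphragm = _diaphragm_map(params) if params.include_diaphragm else np.zeros(params.dims)
    catheter = _catheter_map(params) if params.include_catheter else np.zeros(params.dims)
    static = params.background_level - diaphragm - catheter

    times = params.times_s
    h = gamma_variate(times, params.t0_s, params.tp_s, params.alpha,
                      params.blush_amplitude)
    v = gamma_variate(times, params.vessel_t0_s, params.vessel_tp_s,
                      params.vessel_alpha, params.vessel_contrast)
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    ref_roi = params.reference_roi()

    frames = np.empty((params.n_frames, rows, cols), dtype=np.float32)
    motions: List[Tuple[float, float, float]] = []
    track: List[RoiPolygon] = []
    for i, t in enumerate(times):
        scene = static - vessel * v[i] - blush_spatial * h[i]
        motion = _motion_transform(params, t, i)
        motions.append(motion)
        warped = _warp_frame(scene, motion, center)
        if params.noise_sigma > 0:
            warped = warped + rng.normal(0.0, params.noise_sigma, size=warped.shape)
        if params.bit_depth is not None:
            top = float(2 ** params.bit_depth - 1)
            warped = np.clip(np.round(warped), 0.0, top)
        else:
            warped = np.clip(warped, 0.0, None)
        frames[i] = warped.astype(np.float32)
        track.append(RoiPolygon(_apply_motion_to_points(ref_roi.vertices, motion,
                                                        center)))

    seq = FrameSequence(frames=frames, frame_rate_hz=params.frame_rate_hz,
                        id=f"sim-{params.seed}")
    gt = SyntheticGroundTruth(
        true_curve=BlushCurve(values=h, frame_rate_hz=params.frame_rate_hz),
        motion_per_frame=motions,
        structure_masks={"vessels": vessel > 0.05,
                         "diaphragm": diaphragm > 0.05 * max(params.diaphragm_contrast, 1e-12),
                         "catheter": catheter > 0.05 * max(params.catheter_contrast, 1e-12)},
        roi_reference=ref_roi,
        roi_track_truth=RoiTrack(track),
        params=params,
    )
    return seq, gt


def true_blush_curve(gt: SyntheticGroundTruth) -> BlushCurve:
    """Ground-truth kinetics sampled at frame times (peak value equals the
    blush amplitude at the frame nearest ``t0 + tp``)."""
    return gt.true_curve


def near_bifurcation_params(seed: int = 0, **overrides) -> SimulationParams:
    """Scenario of the motion-artifact experiment: a vessel bifurcation
    pinned a few pixels outside the left ROI edge, with pronounced rigid
    motion, so the fixed ROI intermittently swallows vessel pixels while
    the ground-truth track never does."""
    base = SimulationParams(seed=seed)
    roi_min_col = base.blush_center[1] - base.roi_half_side_px
    kw = dict(
        bifurcation_point=(base.blush_center[0], roi_min_col - 12.0),
        rotation_amplitude_deg=6.0,
        translation_amplitude_px=(6.0, 5.0),
        panning_drift_px=(0.1, 0.15),
        noise_sigma=1.0,
        seed=seed,
    )
    kw.update(overrides)
    return replace(base, **kw)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

DEFAULT_GRADE_AMPLITUDES: Tuple[float, float, float, float] = (0.0, 15.0, 30.0, 45.0)
"""Blush amplitude (8-bit intensity units) by MBG grade in associated mode:
no blush at grade 0, then evenly spaced steps up to a clearly visible
grade-3 blush."""


def make_cohort(n_per_grade: int, mode: str = "associated",
                base_params: Optional[SimulationParams] = None, seed: int = 0,
                grade_amplitudes: Sequence[float] = DEFAULT_GRADE_AMPLITUDES,
                amplitude_jitter: float = 0.25) -> SyntheticCohort:
    """Simulate ``4 * n_per_grade`` graded patients.

    ``associated`` assigns each patient the amplitude of its MBG grade
    times a uniform jitter in ``1 +- amplitude_jitter``; ``null`` draws
    every amplitude from ``U(0, max(grade_amplitudes))`` regardless of
    grade.  Per-patient seeds, motion phases and vessel trees derive
    deterministically from the master seed.
    """
    if n_per_grade < 1:
        raise ContentError("n_per_grade must be >= 1")
    if mode not in ("associated", "null"):
        raise ContentError(f"unknown cohort mode {mode!r}")
    base = base_params if base_params is not None else SimulationParams()
    master = np.random.default_rng(seed)
    patients: List[CohortPatient] = []
    for grade in range(4):
        for j in range(n_per_grade):
            if mode == "associated":
                amp = grade_amplitudes[grade] * master.uniform(
                    1 - amplitude_jitter, 1 + amplitude_jitter)
            else:
                amp = master.uniform(0.0, max(grade_amplitudes))
            p = replace(base,
                        blush_amplitude=float(amp),
                        motion_phase_rad=float(master.uniform(0, 2 * math.pi)),
                        seed=int(master.integers(0, 2 ** 31 - 1)))
            seq, gt = simulate_sequence(p)
            patients.append(CohortPatient(
                patient_id=f"mbg{grade}_{j:02d}", sequence=seq, ground_truth=gt,
                mbg_grade=grade, blush_amplitude=float(amp)))
    return SyntheticCohort(patients=patients,
                           grade_amplitudes={g: float(grade_amplitudes[g])
                                             for g in range(4)},
                           mode=mode)


# ---------------------------------------------------------------------------
# Cohort / ground-truth persistence (structure masks are not serialized)
# ---------------------------------------------------------------------------

def _gt_to_dict(gt: SyntheticGroundTruth) -> dict:
    return {
        "true_curve": gt.true_curve.values.tolist(),
        "frame_rate_hz": gt.true_curve.frame_rate_hz,
        "motion_per_frame": [list(m) for m in gt.motion_per_frame],
        "roi_reference": gt.roi_reference.vertices.tolist(),
        "roi_track_truth": [p.vertices.tolist() for p in gt.roi_track_truth.polygons],
    }


def _gt_from_dict(doc: dict) -> SyntheticGroundTruth:
    return SyntheticGroundTruth(
        true_curve=BlushCurve(values=np.asarray(doc["true_curve"]),
                              frame_rate_hz=doc["frame_rate_hz"]),
        motion_per_frame=[tuple(m) for m in doc["motion_per_frame"]],
        structure_masks={},
        roi_reference=RoiPolygon(np.asarray(doc["roi_reference"])),
        roi_track_truth=RoiTrack([RoiPolygon(np.asarray(v))
                                  for v in doc["roi_track_truth"]]),
    )


def write_ground_truth(gt: SyntheticGroundTruth, path) -> None:
    Path(path).write_text(json.dumps(_gt_to_dict(gt)))


def read_ground_truth(path) -> SyntheticGroundTruth:
    return _gt_from_dict(json.loads(Path(path).read_text()))


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """One subdirectory per patient (TIFF stack + ground-truth JSON) plus
    a labels CSV (patient_id, mbg)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        pdir = out / p.patient_id
        write_sequence(p.sequence, pdir / "frames", format="image_stack")
        write_ground_truth(p.ground_truth, pdir / "ground_truth.json")
        rows.append({"patient_id": p.patient_id, "mbg": p.mbg_grade,
                     "blush_amplitude": p.blush_amplitude})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    (out / "cohort.json").write_text(json.dumps(
        {"mode": cohort.mode, "grade_amplitudes": cohort.grade_amplitudes}))


def load_cohort(in_dir) -> SyntheticCohort:
    import pandas as pd

    root = Path(in_dir)
    labels = pd.read_csv(root / "labels.csv")
    meta = json.loads((root / "cohort.json").read_text()) \
        if (root / "cohort.json").exists() else {"mode": "unknown", "grade_amplitudes": {}}
    patients = []
    for _, row in labels.iterrows():
        pdir = root / str(row["patient_id"])
        seq = read_sequence(pdir / "frames", format="image_stack")
        gt = read_ground_truth(pdir / "ground_truth.json")
        patients.append(CohortPatient(
            patient_id=str(row["patient_id"]), sequence=seq, ground_truth=gt,
            mbg_grade=int(row["mbg"]),
            blush_amplitude=float(row.get("blush_amplitude", np.nan))))
    return SyntheticCohort(patients=patients,
                           grade_amplitudes={int(k): float(v) for k, v in
                                             meta["grade_amplitudes"].items()},
                           mode=meta["mode"])
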