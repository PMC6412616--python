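"""Association statistics and experiment orchestration.

Statistics follow the analysis design of the clinical evaluation:
QuBE scores are summarized as median (IQR); score-vs-MBG association is
Spearman rank correlation (mid-rank ties, two-sided p via the t
approximation); between-grade differences use Kruskal-Wallis with tie
correction; inter-observer agreement uses Lin's concordance correlation
coefficient (population-moment estimator); native vs motion-corrected
scores are compared with the Wilcoxon signed-rank test (zero differences
dropped, mid-ranks for tied magnitudes, exact enumeration for n <= 25,
normal approximation with tie correction beyond).  The 0.05 significance
threshold is reported alongside results, never used to suppress them.

Experiments: the kernel comparison scores every patient of a graded
cohort under several median-kernel sizes (default {20, 35, 50} px — the
native 35 plus the two alternatives) and tabulates median (IQR) per
grade per kernel with per-kernel association statistics; the motion
experiment compares native and observer-corrected analyses patient by
patient and aggregates per-observer correlation summaries, Wilcoxon
tests, and between-observer concordance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .angio_io import RoiTrack
from .blush_core import (BlushOptions, KernelSpec, compute_blush_curve,
                         estimate_panning_offsets, qube_score)
from .errors import ContentError
from .motion import compare_native_vs_corrected, pearson_r
from .synthetic_angio import SyntheticCohort

__all__ = [
    "SIGNIFICANCE_LEVEL", "StatResult", "GradeTable",
    "spearman_association", "kruskal_wallis", "lin_ccc",
    "wilcoxon_signed_rank", "summarize_median_iqr",
    "kernel_comparison_experiment", "motion_experiment",
    "DEFAULT_COMPARISON_KERNELS",
]

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
DEFAULT_COMPARISON_KERNELS: Tuple[int, int, int] = (20, 35, 50)
"""Kernel sides evaluated by the comparison experiment: the native 35 px
plus the smaller (20 px) and larger (50 px) alternatives."""


@dataclass
class StatResult:
    """A test statistic with its two-sided p-value and sample size.

    Undefined results (e.g. Spearman against a constant grade vector) are
    flagged via ``missing=True`` with NaN statistic and p-value rather
    than being silently coerced.
    """

    statistic: float
    p_value: float
    n: int
    method: str
    missing: bool = False


@dataclass
class GradeTable:
    """Median (IQR) of scores per MBG grade per kernel, plus group sizes."""

    table: pd.DataFrame   # index grade 0..3; columns n, median_k{K}, q1_k{K}, q3_k{K}
    kernels: List[int]
    quartile_method: str = "inclusive linear interpolation"

    def __post_init__(self) -> None:
        n_col = self.table["n"]
        if (n_col < 0).any():
            raise ContentError("negative group size in grade table")
        for k in self.kernels:
            q1, md, q3 = (self.table[f"{s}_k{k}"] for s in ("q1", "median", "q3"))
            ok = (q1 <= md + 1e-12) & (md <= q3 + 1e-12)
            if not ok[n_col > 0].all():
                raise ContentError("quartile ordering violated in grade table")

    @property
    def cohort_size(self) -> int:
        return int(self.table["n"].sum())

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def spearman_association(scores: Sequence[float], grades: Sequence[int]
                         ) -> StatResult:
    """Spearman rank correlation between scores and ordinal grades.

    Mid-ranks for ties; two-sided p from the t approximation with n - 2
    degrees of freedom.  All grades identical → undefined, flagged."""
    scores = np.asarray(scores, dtype=np.float64)
    grades = np.asarray(grades, dtype=np.float64)
    if scores.shape != grades.shape:
        raise ContentError("scores and grades length mismatch")
    n = len(scores)
    if n < 4:
        raise ContentError("spearman_association needs n >= 4")
    if np.all(grades == grades[0]) or np.all(scores == scores[0]):
        return StatResult(float("nan"), float("nan"), n,
                          "spearman (undefined: constant input)", missing=True)
    res = scipy.stats.spearmanr(scores, grades)
    return StatResult(float(res.statistic), float(res.pvalue), n,
                      "spearman, t approximation")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H with tie correction, p from chi-square (k-1 df).

    By convention H = 0, p = 1 when every observation is identical."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ContentError("kruskal_wallis needs >= 2 non-empty groups")
    n = int(sum(len(g) for g in groups))
    if n < 5:
        raise ContentError("kruskal_wallis needs total n >= 5")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return StatResult(0.0, 1.0, n, "kruskal-wallis (degenerate: all equal)")
    res = scipy.stats.kruskal(*groups)
    return StatResult(float(res.statistic), float(res.pvalue), n,
                      "kruskal-wallis, chi-square approximation")


def lin_ccc(x: Sequence[float], y: Sequence[float],
            sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ``ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))**2)``
    with population (n-denominator) moments per the original estimator;
    ``sample_moments=True`` switches to the n-1 variant.  Returns NaN
    (flagged missing) when both vectors are constant with equal means.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ContentError("lin_ccc length mismatch")
    if len(x) < 2:
        raise ContentError("lin_ccc needs n >= 2")
    ddof = 1 if sample_moments else 0
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - ddof)
    den = vx + vy + (x.mean() - y.mean()) ** 2
    if den == 0:
        return float("nan")
    return float(np.clip(2 * sxy / den, -1.0, 1.0))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped (classical Wilcoxon, count logged);
    tied magnitudes get mid-ranks.  For n <= 25 retained pairs the p-value
    enumerates all 2^n sign patterns exactly (dynamic programming over
    doubled ranks, which are integers even with .5 mid-ranks); beyond
    that a normal approximation with tie correction applies.  The
    statistic reported is ``min(W+, W-)``; identical vectors give
    statistic 0, p = 1.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ContentError("wilcoxon length mismatch")
    d = x - y
    n_zero = int(np.sum(d == 0))
    if n_zero:
        log.info("wilcoxon_signed_rank: dropped %d zero differences", n_zero)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult(0.0, 1.0, 0, "wilcoxon signed-rank (all zero diffs)")
    ranks = scipy.stats.rankdata(np.abs(d))      # mid-ranks
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= 25:
        p = _wilcoxon_exact_p(ranks, w_plus)
        method = "wilcoxon signed-rank, exact enumeration"
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        method = "wilcoxon signed-rank, normal approximation with tie correction"
    return StatResult(stat, min(1.0, float(p)), n, method)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating the null distribution of W+.

    Each sign pattern is equally likely under H0; the distribution of
    W+ = sum of ranks of positive differences is built by convolving
    (1 + z^{2r}) over the doubled (hence integer) mid-ranks.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in r2:
        counts[r:top + r + 1] += counts[0:top + 1]
        top += r
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    lo = counts[:w2 + 1].sum()       # P(W+ <= w)
    hi = counts[w2:].sum()           # P(W+ >= w)
    return min(1.0, 2.0 * min(lo, hi))


def summarize_median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, q1, q3) with quartiles by inclusive linear interpolation
    of the order statistics."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if len(v) == 0:
        raise ContentError("summarize_median_iqr needs a non-empty list")
    return (float(np.median(v)),
            float(np.percentile(v, 25, method="linear")),
            float(np.percentile(v, 75, method="linear")))


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def kernel_comparison_experiment(
        cohort: SyntheticCohort,
        kernels: Sequence[int] = DEFAULT_COMPARISON_KERNELS,
        opts: BlushOptions = BlushOptions(),
        ) -> Tuple[GradeTable, Dict[int, Dict[str, StatResult]], pd.DataFrame]:
    """Score every patient under every kernel and tabulate by grade.

    The panning-offset estimate is kernel-independent, so it is computed
    once per patient and reused across kernels.  Returns the grade table,
    per-kernel Spearman / Kruskal-Wallis statistics, and the per-patient
    score frame.
    """
    kernels = [KernelSpec(int(k)).side_px for k in kernels]
    if not cohort.patients:
        raise ContentError("empty cohort")
    records = []
    for p in cohort.patients:
        roi = p.ground_truth.roi_reference
        if opts.panning_correction and opts.panning_search_radius_px > 0:
            offs = estimate_panning_offsets(
                p.sequence, radius_px=opts.panning_search_radius_px)
        else:
            offs = [(0, 0)] * p.sequence.n_frames
        for k in kernels:
            curve, _ = compute_blush_curve(p.sequence, roi, opts.with_kernel(k),
                                           offsets=offs)
            res = qube_score(curve, offsets=offs)
            records.append({"patient_id": p.patient_id, "mbg": p.mbg_grade,
                            "kernel": k, "score": res.score,
                            "a": res.max_increase_a, "b": res.max_decrease_b})
    scores = pd.DataFrame.from_records(records)

    rows = {}
    for grade in range(4):
        sub = scores[scores["mbg"] == grade]
        row = {"n": int(sub["patient_id"].nunique())}
        for k in kernels:
            vals = sub[sub["kernel"] == k]["score"].to_numpy()
            if len(vals):
                md, q1, q3 = summarize_median_iqr(vals)
            else:
                md = q1 = q3 = float("nan")
            row.update({f"median_k{k}": md, f"q1_k{k}": q1, f"q3_k{k}": q3})
        rows[grade] = row
    table = GradeTable(pd.DataFrame.from_dict(rows, orient="index")
                       .rename_axis("grade"), kernels=list(kernels))

    stats: Dict[int, Dict[str, StatResult]] = {}
    for k in kernels:
        sub = scores[scores["kernel"] == k]
        by_grade = [sub[sub["mbg"] == g]["score"].to_numpy() for g in range(4)]
        stats[k] = {
            "spearman": spearman_association(sub["score"].to_numpy(),
                                             sub["mbg"].to_numpy()),
            "kruskal_wallis": kruskal_wallis([g for g in by_grade if len(g)]),
        }
    return table, stats, scores


def motion_experiment(cohort: SyntheticCohort,
                      tracks_per_observer: Dict[str, Sequence[RoiTrack]],
                      opts: BlushOptions = BlushOptions()) -> dict:
    """Native vs observer-corrected analysis over a cohort subset.

    ``tracks_per_observer`` maps an observer label to one ROI track per
    patient (same order as ``cohort.patients``).  Per observer the report
    carries each patient's native/corrected Pearson r and QuBE scores,
    the median and range of r, and the Wilcoxon test of native vs
    corrected scores; Lin's CCC compares the corrected scores of every
    observer pair.  Constant-curve (NaN) correlations are skipped in the
    aggregates with a logged count.
    """
    n_pat = len(cohort.patients)
    for obs, tracks in tracks_per_observer.items():
        if len(tracks) != n_pat:
            missing = n_pat - len(tracks)
            raise ContentError(
                f"observer {obs!r}: {missing} patient track(s) missing "
                f"(got {len(tracks)} for {n_pat} patients)")
    report: dict = {"n_patients": n_pat,
                    "significance_level": SIGNIFICANCE_LEVEL,
                    "observers": {}, "lin_ccc_between_observers": {}}
    corrected_scores: Dict[str, List[float]] = {}
    for obs, tracks in tracks_per_observer.items():
        per_patient = []
        for p, track in zip(cohort.patients, tracks):
            if len(track) != p.sequence.n_frames:
                raise ContentError(f"observer {obs!r}, patient {p.patient_id}: "
                                   f"track length mismatch")
            cmp = compare_native_vs_corrected(
                p.sequence, p.ground_truth.roi_reference, track, opts)
            per_patient.append({
                "patient_id": p.patient_id, "mbg": p.mbg_grade,
                "pearson_r": cmp.pearson_r,
                "score_native": cmp.score_native.score,
                "score_corrected": cmp.score_corrected.score,
            })
        rs = np.array([q["pearson_r"] for q in per_patient])
        n_nan = int(np.isnan(rs).sum())
        if n_nan:
            log.info("motion_experiment: observer %s: skipped %d undefined "
                     "correlations", obs, n_nan)
        rs_ok = rs[~np.isnan(rs)]
        wil = wilcoxon_signed_rank([q["score_native"] for q in per_patient],
                                   [q["score_corrected"] for q in per_patient])
        report["observers"][obs] = {
            "patients": per_patient,
            "median_r": float(np.median(rs_ok)) if len(rs_ok) else float("nan"),
            "range_r": [float(rs_ok.min()), float(rs_ok.max())] if len(rs_ok)
                       else [float("nan")] * 2,
            "n_undefined_r": n_nan,
            "wilcoxon_native_vs_corrected": {
                "statistic": wil.statistic, "p_value": wil.p_value,
                "n": wil.n, "method": wil.method},
        }
        corrected_scores[obs] = [q["score_corrected"] for q in per_patient]
    names = list(tracks_per_observer)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            key = f"{names[i]}|{names[j]}"
            report["lin_ccc_between_observers"][key] = lin_ccc(
                corrected_scores[names[i]], corrected_scores[names[j]])
    return report
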