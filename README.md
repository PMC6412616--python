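# qube — quantitative myocardial blush evaluation

After primary percutaneous coronary intervention (PCI) for myocardial
infarction, restoring flow in the epicardial artery does not guarantee
perfusion of the heart muscle itself.  On the angiogram, tissue
perfusion appears as *myocardial blush*: a faint, diffuse opacification
around the artery as contrast washes through the capillary bed.
Clinically it is graded visually (Myocardial Blush Grade, MBG 0–3), a
coarse and observer-dependent scale.  `qube` implements the Quantitative
Blush Evaluator approach — a scalar perfusion score computed from the
time–intensity curve of a myocardial region of interest (ROI) — together
with the analysis machinery needed to probe its limitations, and a fully
synthetic coronary-angiogram simulator so that every stage can be tested
against known ground truth.

It is aimed at researchers in quantitative angiographic image analysis
who want a tested, scriptable reimplementation of the method and a
controllable phantom for experiments on kernel sizes, panning and
cardiac motion.

## The method

For a grayscale angiographic run (frames $I_t$, default 12.5 frames/s):

1. **Inversion.** Contrast attenuates x-rays, so frames are flipped,
   $I'_t = \max I - I_t$, making contrast density positive.
2. **Large-structure removal.** A square median filter (native kernel
   35 × 35 px) estimates the background $B_t = \mathrm{med}_{35}(I'_t)$
   containing arteries, diaphragm and catheter; the residual
   $R_t = \max(I'_t - B_t, 0)$ keeps the mid/high-spatial-frequency
   blush.
3. **Blush value.** Within the ROI, $R_t$ is mean-smoothed (5 × 5) and
   the frame's blush value $v_t$ is the average of the
   $k = \max(10, \lceil 0.02\,|\mathrm{ROI}| \rceil)$ brightest smoothed
   pixels.
4. **Panning correction.** Each frame's integer translation against a
   reference frame is estimated by exhaustive normalized
   cross-correlation within ±20 px, and the ROI follows it.
5. **Score.** With the blush curve $v_1,\dots,v_T$,

   $$\mathrm{QuBE} = \underbrace{\max_{i<j}(v_j - v_i)}_{a}
   + \underbrace{\max_{i<j}(v_i - v_j)}_{b},$$

   both terms floored at 0: the maximum rise plus the maximum fall of
   intensity during contrast passage.

Cardiac motion correction is modeled as externally supplied per-frame
ROI tracks (the manual-observer workflow); `qube.motion` compares native
and corrected analyses, and `qube.evaluation` provides the association
statistics (Spearman, Kruskal–Wallis, Lin's concordance, Wilcoxon
signed-rank, median/IQR tables) used to relate scores to MBG grades.

The simulator (`qube.synthetic_angio`) composes a bright background with
a dark Bézier vessel tree, diaphragm edge, catheter, and a Gaussian
blush region (scale 45 px) whose amplitude follows a gamma-variate bolus
curve $h(t) = A\,x^{\alpha} e^{\alpha(1-x)}$, $x = (t-t_0)/t_p$; rigid
cardiac motion, panning drift and Gaussian noise are applied on top.
Graded cohorts tie the blush amplitude to an assigned MBG grade
(`associated` mode) or sever that link (`null` mode) for calibration
experiments.

## Worked example

```python
import numpy as np
from qube import (SimulationParams, simulate_sequence, score_sequence,
                  pearson_r)

seq, gt = simulate_sequence(SimulationParams(seed=42, blush_amplitude=40.0))
res = score_sequence(seq, gt.roi_reference)
print(f"QuBE score {res.score:.3f} (a={res.max_increase_a:.3f}, "
      f"b={res.max_decrease_b:.3f})")
print("true peak frame", int(np.argmax(gt.true_curve.values)),
      "curve argmax", int(np.argmax(res.curve.values)))
print("r vs truth %.3f" % pearson_r(res.curve.values, gt.true_curve.values))
```

prints

```
QuBE score 2.238 (a=1.227, b=1.011)
true peak frame 33 curve argmax 35
r vs truth 0.983
```

The score decomposes into the curve's maximum rise `a` and maximum fall
`b`; the recovered blush curve peaks within two frames of the true
gamma-variate peak and correlates at 0.983 with it despite vessels,
diaphragm, motion, noise and 8-bit quantization.  The same pipeline is
available from the shell:

```bash
qube simulate --seed 42 --out run/
qube score --input run/frames --roi run/roi.json --out result.json
qube cohort --mode associated --n-per-grade 10 --seed 7 --out cohort/
qube experiment kernels --cohort cohort/ --kernels 20,35,50 \
     --out-table table.csv --out-stats stats.json
```

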