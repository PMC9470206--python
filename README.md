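# bmassay

Analysis toolkit for **point-light biological-motion preference assays in
zebrafish**. When a handful of dots move like a swimming conspecific, fish
approach them; mirror the display vertically and the kinematics become
gravity-incompatible and the attraction weakens. `bmassay` implements the
full desk-side pipeline of such a two-choice place-preference experiment,
for behavioural researchers who want a reproducible, scriptable alternative
to ad-hoc analysis code:

* **stimuli** — read/write point-light sequences (long or wide delimited
  text), rescale them to a physical body length, build the *inverted*
  (vertical mirror) and *non-BM* (rigid constant-spacing, constant-speed
  chain) control stimuli;
* **kinematics** — per-dot vertical velocity/acceleration by central
  differences and the *gravity signature*: sign-split mean magnitudes of
  upward vs downward motion, the kinematic fingerprint that distinguishes
  biological from inverted motion;
* **tracking** — single-fish head/centroid/tail detection in grayscale
  frames (Otsu segmentation, principal-axis body points, temporal head/tail
  continuity);
* **preference** — ROI bands along the stimulus walls, the three dependent
  variables (dwell time%, orientation%, and **Rproj**, the scalar projection
  of the mean heading unit vector onto the stimulus direction), baseline
  normalisation (Δ), 1-minute binning, exclusion rules (freezing, restricted
  swimming, missing frames) and occupancy heatmaps;
* **stats** — Shapiro–Wilk-gated paired/independent t-tests and
  sign-flip/label-shuffle permutation t-tests, BH-FDR over the time-bin
  families, and drivers for the dual-display (within-subject) and
  single-display (between-subject) designs;
* **synthetic** — seeded generators for biased swim trajectories, rendered
  fish video frames with exact ground truth, and point-light sequences with
  a prescribed up/down acceleration asymmetry, plus a parameter-recovery
  harness (type-I error and power against the analytic paired-t oracle).

The central statistic, for a fish with per-frame heading unit vectors
$\mathbf{u}_t$ inside an ROI with inward normal $\mathbf{n}$:

$$R_{proj} = \Big(\tfrac{1}{T}\sum_{t=1}^{T}\mathbf{u}_t\Big)\cdot\mathbf{n} \in [-1, 1],$$

with dwell time% and orientation% as companion measures, all reported as
baseline-normalised Δs and compared with the normality-gated test battery.

## Worked example

Simulate a 24-fish dual-display cohort with a mild attraction (λ = 0.08)
toward the wall showing the upright stimulus, summarise each fish and run
the within-design battery:

```python
import numpy as np
from bmassay import (ArenaGeometry, PeriodDesign, SwimParams, define_rois,
                     simulate_cohort, summarize, analyze_experiment)

arena   = ArenaGeometry()          # 15 cm tank, 12 cm tracked, 20% ROI bands
design  = PeriodDesign()           # 1 min baseline + 4 x 1 min test bins
rois    = define_rois(arena)
trajs   = simulate_cohort(SwimParams(attraction=0.08), arena, design, 24, seed=7)
summaries = [summarize(t, rois, design, fish_id=i) for i, t in enumerate(trajs)]

d = np.array([s.value("ROI 1", "test", "d_time_pct") for s in summaries])
print(f"mean dtime ROI1: {d.mean():.2f} +- {d.std(ddof=1):.2f} %")

report = analyze_experiment(summaries, design="within", seed=1)
sel = (report.metric == "time_pct") & (report.roi == "ROI 1")
print(report[sel][["period", "method", "statistic", "df", "n_used", "p", "p_adj"]]
      .to_string(index=False))
```

prints

```
mean dtime ROI1: 3.38 +- 8.75 %
period   method  statistic   df  n_used        p    p_adj
  test paired-t   1.891036 23.0      24 0.071282      NaN
  bin1 paired-t   2.150874 23.0      24 0.042228 0.161612
  bin2 paired-t   0.366572 23.0      24 0.717289 0.717289
  bin3 paired-t   1.490212 23.0      24 0.149756 0.199674
  bin4 paired-t   1.826356 23.0      24 0.080806 0.161612
```

Each fish spent on average 3.4 percentage points more of the test period
than of the baseline in the band next to the attracting wall (between-fish
SD 8.75). The whole-test paired comparison is reported unadjusted
(p = 0.071 at this effect size and n); the four 1-minute bins form a BH-FDR
family (`p_adj`), so the nominally significant first minute (p = 0.042)
does not survive correction — exactly the bookkeeping used for the real
assay.

A command-line layer wraps the same functions
(`bmassay stimuli invert|nonbm`, `bmassay kinematics`, `bmassay track`,
`bmassay analyze`, `bmassay simulate ...`); see `bmassay --help`.

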