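# fluortrack

Quantitative tracking and kinetic analysis of indocyanine-green (ICG)
near-infrared fluorescence in dual-channel endoscopy video.

## The problem

Systemic ICG with an NIR-capable endoscope is widely used to judge
tissue perfusion by eye.  The same recordings carry more information
than a snapshot: because malignant tissue has chaotic neovasculature and
no lymphatic recovery, dye tends to arrive *late*, rise with a
*shallower slope*, and *persist* after the peak compared with adjacent
normal mucosa.  Turning that observation into numbers requires solving
three problems at once: the camera moves, so a surgeon-annotated region
must be tracked through the white-light channel; the paired NIR channel
must be reduced to a fluorescence-intensity time series FI(t); and the
curve must be summarized by comparable kinetic milestones.

`fluortrack` is a toolkit for that pipeline, aimed at researchers
analyzing intraoperative fluorescence recordings:

* **tracking** — minimum-eigenvalue corner detection inside each
  annotated polygon and pyramidal Kanade–Lucas–Tomasi optical flow, with
  a RANSAC similarity transform carrying the polygon frame-to-frame,
  forward–backward validation, and explicit gap/censoring accounting
  when tracking is lost;
* **intensity** — mean NIR grey value (0–255 g.u.) over the tracked
  polygon per frame, plus 25×25 px spot means for still images and
  percent-decline photobleaching assessment for static specimens;
* **kinetics** — the milestone profile of each curve: latency end
  (first rise of 5 g.u. above baseline), F_max and T_max, the rise and
  its gradient, F_½max / T_½max, the 100 s clearance flag (T_100, F_100,
  Fall_100, DownSlope_100), tracking length, final intensity, skew and
  kurtosis, plus a logarithmic trend fit and latency-aligned group mean
  curves;
* **classification** — KNN grouping of tracked points by their dynamic
  signatures, seeded by the surgeon's tumour/control annotation;
* **stats** — benign/cancer/control tables of mean ± SD with
  Kruskal–Wallis and pairwise Mann–Whitney U tests (exact for small n),
  and the Wilcoxon signed-rank comparison of automatic vs manual
  grouping;
* **synth** — a fully ground-truthed generator of kinetic curves,
  cohorts and moving dual-channel videos (gamma-variate inflow +
  saturating retention), so the whole pipeline is testable without
  clinical data.

See `docs/methods.md` for the model definitions and numerical choices.

## Worked example

Simulate a small cohort (5 subjects per tissue class, 10 min traces at
30 fps), reduce every trace to its milestone profile, and build the
group comparison table:

```python
from fluortrack import simulate_cohort, compute_profile, build_group_table

members = simulate_cohort(n_per_group=5, seed=42)
profiles = {}
for m in members:
    profiles.setdefault(m.group, []).append(compute_profile(m.trace))

table = build_group_table(profiles).table
cols = ["benign_mean", "cancer_mean", "control_mean", "p_cancer_vs_control"]
print(table.loc[["T_max (s)", "Upslope gradient (g.u./s)", "Fall_100 (g.u.)"], cols])
```

prints

```
                           benign_mean  cancer_mean  control_mean  p_cancer_vs_control
variable
T_max (s)                       92.527      201.647        72.313                0.008
Upslope gradient (g.u./s)        2.250        0.764         2.446                0.008
Fall_100 (g.u.)                 92.918       10.604        83.548                0.008
```

The simulated malignant lesions peak late (T_max ≈ 200 s vs ≈ 72 s for
normal mucosa), climb with a ~3× shallower gradient, and lose only
~11 g.u. in the 100 s after their peak where benign lesions lose
~93 g.u. — the slow-ingress / long-persistence phenotype, each contrast
significant by Mann–Whitney U at n = 5 per group.

The same analysis runs end-to-end from video: `simulate_video` renders a
moving dual-channel scene with known region tracks, `run_tracking`
follows the annotated polygons in the white-light channel, and
`extract_trace` reads the NIR means through the tracked geometry.  A
`fluortrack` command-line tool wraps each stage (`simulate`, `track`,
`extract`, `kinetics`, `classify`, `stats`, `spot`, `photobleach`).

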