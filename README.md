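# engramflow

**Post-learning neurochemistry and the consolidation of motor memories — a
tested, reusable analysis pipeline.**

Skill learning transiently shifts the balance of excitation and inhibition
in primary motor cortex (M1): glutamate (Glu) and GABA concentrations
measured by MRS change within minutes of practice, and those early changes
are thought to gate the overnight ("offline") consolidation of the new
memory. `engramflow` implements the full analysis chain that links the two:

* **MRS quantification** — tissue-corrected absolute concentrations from
  water-scaled estimates and GM/WM/CSF voxel fractions
  (`factor = (f_gm·43.3 + f_wm·35.88 + f_csf·5.556) / (1 − f_csf)`,
  no metabolites in CSF), with the 3-SD / 15-Hz-linewidth / SNR ≤ 30
  quality-control rules and immediate / 30-min / averaged change scores;
* **behavior** — correct-sequence counts for the 4-1-3-2-4 finger-tapping
  task, early/late learning-phase segmentation from a random-intercept +
  random-slope mixed model with consecutive-block contrasts, and overnight
  gains `100·(day2 − day1_last)/day1_last`;
* **BOLD features** — a simplified task GLM (double-gamma HRF), the
  engram-style conjunction ROI (active at the end of learning *and* at
  next-day retrieval), integrated local correlation maps
  `ILC(v) = Σ w(u,v)·corr(x_v, x_u) / Σ w(u,v)`, multivoxel
  local-correlation (MVLC) reactivation similarity
  `r(task, post-rest) − r(task, pre-rest)`, and ROI-to-ROI functional
  connectivity on the Fisher-z scale;
* **statistics** — `dv ~ Time*Group + (Time | ID)` repeated-measures mixed
  models, the Glu-GABA coupling-change test (dependent non-overlapping
  r-to-z), residual-based partial correlations with covariate adjustment,
  Fisher/Steiger comparisons of correlations, Benjamini-Hochberg FDR within
  hypothesis families, and 3×IQR outlier fences;
* **a synthetic two-day cohort generator** (Learning n=36, Control n=21,
  six MRS time points, 12 + 1 practice blocks, four BOLD runs per subject)
  with planted, documented effect structure, so the whole pipeline is
  testable end to end without access to any subject data.

The scientific background, model assumptions, planted-parameter
definitions, and numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
from engramflow.config import CohortConfig, RunConfig
from engramflow.pipeline import run_all

report = run_all(RunConfig(cohort=CohortConfig(master_seed=1)))
s = report["summary"]
print(s["mean_overnight_gain_pct"])   # 9.99   -> mean overnight gain (%)
print(s["phase_boundary_block"])      # 4      -> first late-phase block
print(s["coupling"]["Learning"])      # r_pre 0.01, r_post 0.64 on this cohort
```

On the default synthetic cohort with seed 1 this prints a mean overnight
gain of **9.99%** (the generator plants 10.46% ± 1.8% SE), a learning-phase
boundary at **block 4** (blocks 1-3 form the early phase), and a Glu-GABA
coupling that rises from **r = 0.01** at baseline to **r = 0.64** over the
post-learning period on this particular cohort (the planted population
values are 0.18 → 0.58; single-cohort correlations at n = 36 are noisy, and
averaging 100 cohorts recovers 0.15 / 0.57). The correlation battery on the
same run reports, among others, a partial correlation of **−0.47** between
the 30-min GABA change and the overnight M1 gray-matter change (planted
−0.48) and **0.44** between the immediate Glu change and the overnight
M1-right-putamen connectivity change (planted 0.368 on the measured scale).

The same pipeline is available from the shell:

```bash
engramflow run-all --seed 1 --out out/        # simulate -> ... -> report
engramflow simulate --seed 1 --out data/      # just the synthetic cohort
engramflow quantify --in data/metabolites.csv --out out/
engramflow behavior --in data/behavior.csv --out out/
```

`out/report.json` and `out/report.md` summarize the metabolite dynamics,
the coupling change, the baseline-dependence correlations, and the
FDR-corrected correlation battery; every table is also written as CSV.
Identical config + seed reproduces every output byte for byte.

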