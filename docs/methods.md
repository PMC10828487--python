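# Methods

`engramflow` re-implements, as a tested pipeline, an analysis linking early
post-learning changes in primary-motor-cortex (M1) glutamate (Glu) and GABA
to overnight behavioral, functional, and structural correlates of motor
memory consolidation. Because the original subject data are confidential,
the pipeline ships with a synthetic-cohort generator that reproduces the
study's design and planted effect structure, so every stage is exercised
end to end without any download. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not show.

## Study design being emulated

Two groups — Learning (n = 36) and Control (n = 21) — are scanned across
two days. Single-voxel MRS of M1 is measured at six time points: baseline,
four post-task scans spanning the first ~30 min, and a day-2 baseline. The
exact spacing of the four post scans is not fixed by the protocol we
emulate beyond "the first 30 minutes"; we place them at 10-min intervals
(labels `post0`, `post10`, `post20`, `post30`), with `post0` the
"immediate" and `post30` the "after 30 min" measurement. The Learning
group practices a five-digit finger sequence (4-1-3-2-4) for twelve 30-s
blocks on day 1 and is tested with one block on day 2. Resting BOLD runs
bracket the task on day 1, with another at the day-2 baseline.

## MRS quantification

Water-scaled metabolite estimates are converted to mM-scale concentrations
using the voxel's tissue composition, assuming water concentrations of
43.3 M (GM), 35.88 M (WM), 5.556 M (CSF), no metabolites in CSF, a single
T2 regime for GM and WM, and no T1 correction (long-TR acquisition). These
assumptions admit exactly one correction:

    factor = (f_gm * 43.3 + f_wm * 35.88 + f_csf * 5.556) / (1 - f_csf)

The CSF water term participates in the numerator (its numeric effect is
small but nonzero); the `1 - f_csf` renormalization implements the
no-metabolites-in-CSF assumption. A near-pure-CSF voxel
(`f_csf >= 1 - 1e-9`) is a hard error.

Quality control excludes a measurement when (a) its concentration is more
than 3 SD from the mean of all time-point measurements of that metabolite —
pooled within group by default (a `group_pooled` switch pools across
groups; the within-subject alternative has too few points), (b) the water
linewidth exceeds 15 Hz FWHM (15.0 is kept, 15.01 excluded), or (c) SNR is
<= 30 (30.0 excluded, 30.1 kept). CRLB is carried in the audit table but is
not an exclusion criterion. Change scores per subject and metabolite:
immediate (`post0 - pre`), 30-min (`post30 - pre`), averaged (mean of the
unflagged post scans minus `pre`), plus the day-2 level. Subjects without a
usable baseline are dropped from the delta table with a log entry.

## Behavior

Performance is the number of correct 4-1-3-2-4 sequences completed per
block — a combined speed/accuracy count. The scorer advances a cursor
through the target on each matching press; on a mismatch it falls back to
the longest viable restart position (a KMP failure function), because with
online visual feedback a stray press should not erase a partially correct
continuation. A `strict_reset` variant performs a full reset on mismatch;
the two differ only on adversarial streams. Completed sequences are counted
disjointly (the cursor resets to the start after a full match), which makes
the scorer equal to leftmost-disjoint occurrence enumeration — the oracle
used in the tests.

The learning session is segmented by fitting a random-intercept +
random-slope mixed model of the count on block (block categorical in the
fixed effects, numeric in the random slope) and testing consecutive blocks
with uncorrected contrasts. The late phase starts at the first block whose
step from the previous block is non-significant (alpha = 0.05). A stricter
reading — requiring every later consecutive contrast to be non-significant
as well — is available via `require_all_subsequent=True`, but it is not the
default: with k null contrasts remaining, the probability that none of them
crosses alpha by chance is roughly (1 - alpha)^k (~0.66 for 8 contrasts at
alpha 0.05, even less with positive block-to-block noise), so that
estimator fails to recover a genuinely planted boundary in about a third of
cohorts no matter how many subjects are scanned. The first-gap rule is the
consistent estimator of the same idea. When the mixed model fails to
converge the segmentation falls back to paired t-tests with a warning.

Overnight gain is `100 * (day2_test - day1_last) / day1_last` percent; a
zero day-1 reference is an error.

## BOLD features

**Task GLM.** A deliberately simplified design: early-phase and late-phase
boxcars convolved with a canonical double-gamma HRF (gamma shape 6 minus
1/6 of gamma shape 16, unit peak), the temporal derivative of the combined
task regressor, an intercept, and a linear drift. Per-voxel OLS with exact
t-to-z conversion; zero-variance voxels get z = 0 by convention. Full
cluster-level inference pipelines (FLAME/GRF, registration, ICA-based
denoising) are intentionally out of scope; the ROI definition is what the
downstream stages need.

**Engram conjunction ROI.** Voxels with z > 3.1 in both the end-of-learning
and day-2-retrieval maps, intersected with an optional anatomical mask,
with 26-connected components below a minimum size removed. An empty
conjunction raises an error reporting each map's suprathreshold count.

**Integrated local correlation (ILC).** For each voxel,
`ILC(v) = sum_u w(u,v) corr(x_v, x_u) / sum_u w(u,v)` over neighbors within
3 kernel widths, Gaussian weights `w = exp(-d^2 / 2 sigma^2)` with
distances in mm, self-correlation excluded, per-voxel demeaned time
courses. With the default sigma = 1 mm on a 1.6-mm grid the neighborhood is
exactly the 26 directly surrounding voxels. Reference implementations
delegate this computation to packaged tooling whose exact kernel
normalization is a dialect choice; ours is stated explicitly precisely so a
brute-force oracle exists, and the tests hold the optimized implementation
to that oracle at 1e-10. Zero-variance voxels contribute correlation 0 (and
are logged); computation can be restricted to an ROI's padded bounding box,
which is exactly equivalent on the ROI voxels.

**MVLC reactivation.** The MVLC pattern is the Fisher-z (atanh) ILC vector
over the M1 ROI voxels in a fixed ascending-linear-index order shared
across conditions. The task pattern uses the concatenated late-phase block
volumes with the first 5 volumes of each block dropped (configurable) to
suppress boundary transients. Reactivation is indexed by the similarity
difference `r(task, post-rest) - r(task, pre-rest)`; it is invariant to any
common permutation of the three vectors and is zero exactly when post- and
pre-rest patterns coincide.

**Functional connectivity.** ROI-to-ROI FC is `atanh(corr)` of the two
ROIs' mean time courses; identical/overlapping ROIs (|r| = 1) are an error
directing the caller to disjoint ROIs. Session changes are plain
differences of Fisher-z values; "overnight" is day-2 rest minus day-1
pre-task rest, "short-term" is post-task minus pre-task rest on day 1.

## Statistics

* **Repeated-measures model** `dv ~ Time*Group + (Time | ID)`: REML fit via
  `statsmodels.MixedLM` with categorical Time in the fixed effects and a
  numeric-time random slope. Wald F statistics use balanced split-plot
  (containment) denominator degrees of freedom — subjects − groups for the
  between-subject effect, (subjects − groups)(T − 1) for within-subject
  effects — which a 500-replicate null simulation shows to be calibrated
  (Time x Group rejection ~0.05 at alpha 0.05) at the study's sample sizes.
  Singular random-slope fits trigger a random-intercept-only refit with a
  prominent warning. Post-hoc pairwise time contrasts within each group are
  BH-FDR corrected.
* **Coupling change**: the across-subject Glu-GABA correlation at baseline
  versus over the averaged post period, compared with the dependent-groups,
  non-overlapping-variables r-to-z test (Pearson-Filon covariance; the ZPF*
  form), since the same subjects contribute both correlations.
* **Partial correlations** are residual-based partial Pearson correlations;
  controls (the other metabolite) and covariates (e.g. day-1 performance)
  both reduce df by one each — the standard convention. One-tailed tests
  are used only where a directional hypothesis is stated
  (consolidation-measure -> behavior links); metabolite tests are
  two-sided.
* **Comparing correlations**: Fisher's r-to-z for independent groups;
  Steiger's pooled-r Z for dependent overlapping correlations (the exact
  package variant used originally is not recoverable from printed values;
  Steiger 1980 is the default and the Monte-Carlo oracle in the tests
  agrees with it to 0.1).
* **Multiplicity**: Benjamini-Hochberg step-up within each hypothesis
  family (e.g. the three Glu-gain spans form one family, the GABA-gain
  spans another), encoded explicitly so the family structure can be
  changed in config.
* **Outliers**: metabolite values use the 3-SD rule above; every other
  continuous measure uses Q1 − 3 IQR / Q3 + 3 IQR fences
  (linear-interpolation quantiles, strict inequalities), applied within
  group before the battery.

## The synthetic cohort

The generator's defaults are the study conditions; they are not tuning
knobs. Planted structure:

* Baseline concentrations (mM, typical of 7T M1 MRS): Glu 9.6 ± 0.8,
  GABA 1.5 ± 0.22, NAA 12 ± 1.0, Gln 3 ± 0.45, Cr 7.5 ± 0.55
  (between-subject SD). Per-scan measurement noise: Glu 0.30, GABA 0.12 mM
  (typical repeatability); per-subject post-period physiological shifts:
  Glu 0.55, GABA 0.18 mM.
* A homeostatic regression-to-the-mean slope of −0.4 links the post-period
  change to the baseline level — for GABA in both groups, for Glu fully
  after learning and at 35% strength after rest.
* The across-subject Glu-GABA coupling is 0.18 at baseline and 0.58 over
  the averaged post period in the Learning group (unchanged in Controls).
* The mean overnight gain is 10.46% (SE 1.8% at n = 36), negatively related
  to day-1 final performance (r = −0.30), and with partial correlation 0.45
  with the averaged Glu change given the GABA change.
* The 30-min GABA change predicts the overnight M1 GM change at partial
  r = −0.48; PCC GM change is null. The immediate Glu change predicts the
  overnight M1-right-putamen connectivity change at partial r = 0.368; the
  left-putamen and PCC edges are null.
* Post-rest BOLD mixes the task's local-correlation pattern into the
  resting pattern with weight `reactivation_fidelity` (default 0.3,
  modulated by the subject's immediate Glu change), implementing offline
  reactivation at the pattern level.

Three definitional choices deserve emphasis. First, **planted correlations
are targets on the measured scale**: the generator inverts its own noise
model (scan noise for metabolites; finite-scan-length Fisher-z noise for
FC) so that the statistic a downstream analyst computes converges to the
stated value — this is what makes parameter-recovery tests meaningful.
Second, **cross-modal effects are planted on the partial scale**: the
outcome loads on the raw standardized predictor with a coefficient solved
so that the partial correlation given the other metabolite equals the
target, which simultaneously makes the reverse partial (the other
metabolite given the named one) exactly zero — mirroring the specificity
the analysis reports. Third, **standardization uses population moments**,
computed analytically from the noise model, never the realized sample;
conditioning the plant on sample moments would shrink sampling variability
and distort CI coverage.

BOLD realism is limited: AR(1) temporal noise (coefficient 0.3) plus shared
latent signals assigned to 2x2x2 voxel neighborhoods of the pattern ROI,
with neighborhood strengths drawn from a per-subject pattern stream;
variance-share mixing implements fidelity. There are no motion,
physiological, or scanner confounds, since the corresponding denoising
steps are out of scope — passing tests therefore demonstrate correctness of
the computations and calibration of the statistics, not robustness to
real-scanner artifacts. ROI-to-ROI connectivity targets are realized by a
shared global signal whose weight is solved from the realized ROI-mean
variances; simultaneous targets on several edges interact mildly (the
realized correlations are attenuated by a few percent), which the planted
overnight-change correlation absorbs by construction.

Scaled-down defaults keep a full cohort under ~6 s on one CPU: a 16^3 grid
at 1.6 mm, 120 rest volumes (the acquisition used 420), and 15 s-on/15 s-off
task blocks (acquired 30/30). Paper-scale values are one config edit away.
Behavior streams encode errors as random insertions between completed
sequences and round-trip exactly through the scorer; block counts follow a
saturating curve that reaches its plateau at `changepoint_block` (default
4, i.e. the last significant block-to-block rise is 2 -> 3). Day-2 counts
are integers, so measured gains carry ~1.5% rounding noise — a real-data
feature the recovery tolerances absorb.

Determinism: every stage draws from `SeedSequence([master_seed, subject,
purpose])` substreams; identical config + seed reproduces every output file
byte for byte.

## Problem sizes in the test suite

The acceptance tests run the documented properties at the sizes they are
stated at: 20 oracle volumes (6^3 x 60) for ILC; 200 + 2 x 100 subjects for
the reactivation curve; 1000 random streams for the scoring oracle; 100
seeded cohorts for boundary recovery; 500 null replicates for mixed-model
calibration; 500 cohorts for parameter recovery and coupling power; 50 + 50
end-to-end pipeline runs for the specificity pattern. The whole suite runs
in roughly 20 minutes on one CPU.

## Known limitations

* The end-to-end battery has ~15 hypothesis families, each FDR-controlled
  at q < 0.05. Under a global null the chance that *every* family stays
  quiet is approximately 0.95^15 ≈ 0.46, so roughly half of null cohorts
  show at least one family-level false positive — an irreducible property
  of per-family error control, not an implementation defect. The
  corresponding global-null acceptance check (>= 90% fully-quiet cohorts)
  is therefore expected to fail for any battery of this breadth; the
  per-family false-positive rates themselves are calibrated (~4-5%).
* The family-level detection probability for the Glu-FC(right putamen)
  effect is ~0.6 per cohort at the planted (study-reported) effect size —
  the effect sits near the FDR threshold at n = 36, so "majority of seeds"
  checks on it are inherently close calls.
* Mixed-model denominator df are containment-based, not Satterthwaite;
  at the balanced designs used here the two agree closely and the null
  simulations confirm calibration, but strongly unbalanced panels would
  deserve a dedicated df approximation.
* LCModel spectral fitting, k-space/EPI simulation, registration, VBM and
  sleep physiology are out of scope; GM values enter as a per-subject
  table, and raw spectra are never synthesized.
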