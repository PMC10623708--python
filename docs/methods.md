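# Methods

## The dominant-interval feature

Each patient contributes one whole-lung HU histogram over [−1000, 0]
computed on the parenchyma mask (lung minus vessels, nodules, bronchi,
bullae, hilar structures). Two interval schemes are fixed:

| scheme | bins | candidate pair |
|---|---|---|
| distribution_1 | 100-HU bins, −950 … −50 (9 bins) | [−950,−850) vs [−850,−750) |
| distribution_2 | 50-HU bins, −950 … 0 (19 bins) | [−950,−900) vs [−900,−850) |

The binary feature is 1 when the higher-HU candidate holds strictly more
voxels. Absolute counts are never compared across patients — total lung
voxel counts vary with body size and reconstruction grid — so no
normalisation by lung volume is needed; `total_in_mask` is carried as
metadata only.

Numerical conventions, chosen for exactness and stated because bin
membership at an edge depends on them:

* Bins are half-open [lo, hi); a scheme's final bin is closed at its top
  edge. A voxel at exactly −850 HU counts in [−850, −750).
* Float volumes are rounded half-to-even to integer HU before binning.
* Voxels in [−1000, −950), above a scheme's top edge (but within
  [−1000, 0]), below −1000 or above 0 go to explicit out-of-coverage /
  out-of-range tallies, so the bookkeeping identity
  `sum(counts) + out_of_coverage + below + above == total_in_mask`
  holds exactly.
* Ties between the candidates resolve to the lower-HU interval — the
  control-typical reference category — and emit a warning; on continuous
  synthetic parenchyma a tie is a probability-zero event.

## Segmentation

The original analysis used a CNN lung segmenter. The downstream
statistic needs a parenchyma mask, not a particular model, so this
package defines the segmenter as an interface (`CTVolume → RegionMasks`)
with a classical implementation:

* air threshold −320 HU (default; parenchyma sits near −900, soft tissue
  near +40, so the exact value is uncritical over a wide range),
* removal of connected components touching the volume border (exterior
  air), retention of the two largest interior components, hole filling,
  closing with a 6-connected element, radius 1 voxel;
* vessel/soft-tissue structure cut −300 HU with a radius-1 opening;
  bullae at ≤ −980 HU. Hilum removal is folded into the vessel cut — no
  separate detector, a deliberate simplification.

All thresholds are configurable. `parenchyma` is recomputed from
`lung AND NOT excluded` on every access, so the defining identity cannot
drift. Masks use 0-based (slice, row, column) indexing congruent with
the volume grid; no resampling is performed. Slice thickness is treated
as metadata: histogram counts are voxel counts on the given grid.

## Synthetic phantoms

The generator emulates the geometry and HU composition a threshold
segmenter and the histogram care about, nothing more: an ellipsoidal
soft-tissue body (+40 HU) in exterior air (−1000 HU), two ellipsoidal
lungs strictly interior to the body (a ≥2-voxel tissue shell guarantees
lung air never touches exterior air), parenchyma drawn from a
truncated-Gaussian mixture on [−1000, 0] (truncation by resampling,
clipping only as a last resort), vessels as 26-connected random-walk
tubes at +50 HU dilated by the same 6-connected element the vessel
detector's opening uses (which makes threshold + opening recover them
exactly), nodules as spheres at −50…+100 HU and bullae as spheres at
−1000…−980 HU, all recorded in ground-truth masks.

Default conditions: grid 40×72×72 voxels at (5.0, 0.7, 0.7) mm — about
2·10⁵ lung voxels per phantom, the package's default working size —
with mixture (−905 HU, 40) at weight 0.85 and (−810 HU, 50) at weight
0.15, 2% vessel fraction, two nodules (2–6 mm), one bulla (3–8 mm).
The control mixture concentrates mass in [−950, −750] HU with its mode
below −900, so control phantoms read reference on both schemes.

"Case" phantoms add `case_shift_hu` to every mixture component mean.
No literature value quantifies the real HU shift separating cases from
controls, so it is a free parameter (pipeline default +40 HU, which
flips the 50-HU scheme but usually not the 100-HU scheme — matching the
qualitative pattern that the fine scheme is the more sensitive one).
Shifting every component (rather than one chosen component) keeps the
indicator probability strictly monotone in a single knob.

What the phantoms do **not** model: airway trees, lobar anatomy,
gravity-dependent density gradients, beam hardening, reconstruction
kernels, motion. Passing tests therefore demonstrate correctness of the
measurement and statistics pipeline on known ground truth — not clinical
segmentation performance on real scans.

## Synthetic cohorts

Case/control counts default to 41/48. Binary exposures are Bernoulli per
group; heavy smoking is parameterised by the control prevalence (default
30/48) and a case odds ratio (default 3.5). Tumour markers (CEA, CA125,
CA199) are log-normal per group, parameterised by (median, IQR) with the
closed-form inversion σ = asinh(IQR/2·median)/Φ⁻¹(0.75); defaults are
the observed group medians/IQRs of the reference cohort. Interval
indicators are drawn per group with default probabilities matching the
reference counts (11/41 vs 3/48; 34/41 vs 24/48). `exact=True` assigns
each binary exposure to exactly round(p·n) randomly chosen subjects —
used to rebuild the reference table verbatim. `ex_or_current_smoker` is
generated identical to `heavy_smoker` (the two are count-identical in
the reference cohort); only `heavy_smoker` enters the models.

All generators are pure functions of (spec, seed); one master seed
spawns independent child streams per variable block, so adding a
variable never perturbs another's draws.

Because the binary predictors are conditionally independent given the
outcome by construction, the joint logistic model holds with
coefficients equal to the marginal log odds ratios — which is what makes
the parameter-recovery checks well-posed.

## Statistics

* **2×2 odds ratio**: cross-product estimate; Woolf CI
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); two-sided Wald p. A zero cell
  raises an error — no silent continuity correction. This convention
  reproduces the reference univariate results exactly at printed
  precision, which is what fixes it.
* **Group comparisons**: Pearson χ² *without* Yates correction when all
  expected cells ≥ 5, else Fisher's exact (the uncorrected χ² is what
  reproduces the reference descriptive p-values); Shapiro–Wilk gate at
  α = 0.05 per group routes continuous variables to Mann–Whitney U or a
  two-sample t test.
* **Logistic screen**: candidates fit one at a time by maximum
  likelihood; Wald p < 0.05 admits a variable to the joint model.
  Perfect separation and rank deficiency raise typed errors
  (`ConvergenceError`, `CollinearityError` listing offending terms).
  For a binary predictor the saturated logistic OR equals the 2×2
  cross-product OR and its Wald CI exponentiates to the Woolf CI — an
  equivalence the tests assert to 10⁻⁶.
* **ROC**: empirical curve over all thresholds; trapezoidal AUC (equal
  to Mann–Whitney concordance with ties half-weighted); CI by DeLong
  (midrank placement values), Hanley–McNeil available behind a flag.
  The operating point maximizes Youden's J; among J-ties the
  highest-sensitivity point is taken. How the original study chose its
  operating point is unstated; Youden is recorded with the threshold so
  alternatives can be compared.
* **Rendering**: percentages at one decimal with trailing ".0" dropped
  ("24(50%)", "3(6.2%)" — 6.25 rounds half-to-even to 6.2), ORs at three
  decimals; internal computation at full precision.

## Scope of validation

The reference multivariate results (ORs 3.848 / 5.302 / 3.478, AUC
0.776, sensitivity 90.2%, specificity 52.1%) are functions of
patient-level data that were never deposited; no desk-scale computation
can reproduce them. The corresponding machinery is validated instead by
properties: recovery of known generating ORs within 15% at n = 2,000,
94–96% null coverage of the Woolf interval over 1,000 simulated cohorts
(200/200, exposure prevalence 0.5), exact AUC agreement with a
brute-force pairwise concordance oracle at n ≤ 200, and lung Dice ≥ 0.95
with parenchyma count error ≤ 2% against phantom ground truth over 20
seeds (test phantoms 24×48×48 for speed).

## Known limitations

* The threshold segmenter assumes air-filled lungs surrounded by soft
  tissue; severe consolidation or volumes cropped through the lungs
  would defeat it (the border-removal step then deletes lung components).
* DICOM support covers single-series axial CT with uniform spacing; no
  orientation handling beyond the package's (slice, row, column)
  convention, no gantry tilt.
* The cohort generator draws covariates independently within group
  (apart from the deliberate outcome association), so it cannot emulate
  confounding structures between covariates.
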