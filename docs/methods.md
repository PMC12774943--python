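# Methods

## The signal model

The package models the normalised, spherically-averaged PGSE diffusion-MRI
signal of renal tissue as a three-compartment mixture

    S(b, delta, Delta) = f_VASC * S_VASC(d_VASC, b)
                       + f_IC   * S_IC(d_IC, R, b, delta, Delta)
                       + f_EES  * S_EES(d_EES, b)

with signal volume fractions f_IC (intracellular), f_EES
(extracellular-extravascular) and f_VASC (vascular) summing to one;
f_VASC is always derived as `1 - f_IC - f_EES`.  The compartments are:

* **Intracellular — impermeable sphere.**  Water restricted in a sphere of
  radius R, attenuation given by the Gaussian-phase-distribution
  (Murday–Cotts) closed form.  The log-signal is a sum over the radial
  eigenmodes mu_m (positive roots of the derivative of the first-order
  spherical Bessel function), with the gradient amplitude recovered from
  `b = gamma^2 g^2 delta^2 (Delta - delta/3)`.  The implementation keeps 40
  eigenmodes by default; 20 and 60 agree to 1e-8 over the protocol and
  parameter ranges, so truncation error is negligible.
* **Vascular — astrosticks.**  Randomly oriented one-dimensional segments
  with a high pseudo-diffusivity, orientation-averaged in closed form:
  `S = sqrt(pi) erf(sqrt(b d)) / (2 sqrt(b d))`, with a series expansion
  below `b d < 1e-6` so b = 0 is exactly 1.
* **EES — isotropic ball.**  `S = exp(-b d)`.

Fixed diffusivities: d_IC = d_EES = 2 um^2/ms, d_VASC = 50 um^2/ms.  Free
parameters and their ranges: f_IC, f_EES in [0, 1] (on the simplex), R in
[0, 15] um.  There is no exchange between compartments, no
diffusion-time-dependence beyond the PGSE timing entering the sphere term,
and no T2 weighting in the normalised signal (matched-b0 division cancels
it).  Units at every interface: b in s/mm^2, times in ms, diffusivities in
um^2/ms, radii in um.

Mono-exponential (ADC, bounds (0, 4] um^2/ms) and bi-exponential (IVIM,
perfusion fraction f in [0, 1], D in (0, 4], D* in [4, 100] um^2/ms,
D* > D) baselines share the scheme interface.

### Validity of the GPD sphere signal

The GPD expression is an approximation.  Against an independent
Monte-Carlo random-walk oracle (1e5 walkers, radial specular reflection,
phase accumulated under both gradient lobes, step-size convergence checked)
it agrees to well under 1% for R up to ~7 um anywhere on the kidney
protocol, but degrades at strong attenuation: ~5% at R = 10 um and ~8% at
R = 12 um for the strongest weighting (b = 2500 s/mm^2).  The oracle
comparison in the test suite therefore covers R in {3, 5, 7} um — the
physiological renal cell-radius regime — and this limitation is the main
caveat on fitted radii near the top of the clamp range.  The sphere signal
is also genuinely non-monotone in diffusivity (motional narrowing): it
attenuates at tissue-scale d but returns towards 1 both for frozen spins
and for very fast diffusion; the test suite asserts this bathtub shape
rather than a (wrong) monotone property.

## Acquisition scheme

The packaged full kidney protocol has nine b/delta/Delta combinations
(b = 70–2500 s/mm^2), each acquired in three orthogonal directions that are
spherically averaged, plus one matched b0 per combination at the same echo
time — 18 volumes and 27 direction-resolved DW measurements.  Per-combo TEs
are recorded (54–87 ms, interpolated minimum-TE values; they are not used
by the normalised models and only scale the generator's optional T2
channel).  Scheme files are whitespace tables
(`b delta Delta TE n_directions`), hand-editable and round-trip exact.

## Classical fitting

`fit_nlls` is bound-constrained least squares with a deterministic
multi-start strategy: the objective is evaluated on a fixed grid
(5 x 5 x 5 over the fraction simplex and radius for the three-compartment
model), and the best three grid points are refined with
`scipy.optimize.least_squares`.  Off-simplex fraction pairs are
renormalised proportionally inside the objective, keeping it continuous.
Ties between equal-loss starts break on the lower start index, so the fit
is a pure function of (signals, config).  Magnitude signals are fitted by
plain least squares (not a Rician likelihood), matching the MSE criterion
used for model comparison.  All nine combos enter every model's fit,
including ADC — a deliberate interpretation, since clinical ADC often uses
a b-subset.

## Self-supervised fitting

A fully connected network (input width = number of image volumes, i.e. 18
for the full protocol with the b0 slots fixed at 1; three hidden layers of
18 units; ELU activations; dropout p = 0.5 during training) maps each
voxel's measurement vector to the three free parameters.  Outputs are hard
clamped into their physical ranges ([0,1], [0,1], [0,15] um); if the
clamped fractions leave the simplex they are renormalised proportionally.
The parameters drive the forward model and the training loss is the MSE
between the reconstructed and measured signals over all volumes — no
labels, and training and inference use the same masked dataset.  Adam with
learning rate 1e-4, batch size 32.

Numerical choices that mattered in practice:

* **Input standardisation.**  The network sees per-feature standardised
  signals (the loss is always computed against the raw signals).  Raw DW
  signals share a large common mode; without standardisation the net sits
  on a constant-output saddle for thousands of updates before
  differentiating voxels, and an early-stopping rule can halt inside it.
* **Early stopping** monitors the deterministic (dropout-off) full-dataset
  reconstruction loss each epoch, with patience 50 epochs and min-delta
  1e-7, up to 400 epochs; the retained weights are those of the best
  monitored epoch.  Non-convergence within the epoch budget is flagged on
  the result, not raised.
* **Gradients** through the forward model are analytic for the fractions
  (the mixture is affine in them) and central finite differences
  (h = 1e-3 um) for the sphere radius; the clamp passes zero gradient
  outside its range, and the output head is initialised mid-range so the
  clamp is not saturated at the start.
* **Problem size.**  A few thousand masked voxels give enough updates per
  epoch at the fixed learning rate; the default phantom (32 x 32 x 4)
  and the test fixtures are sized accordingly.

The engines cross-validate: at b0 SNR 50 on the default phantom the
self-supervised f_IC map correlates with ground truth at ~0.96 and differs
from the voxelwise NLLS oracle by a median |Delta f_IC| of ~0.03.

## Protocol economisation

The dual-network selector ranks the 27 direction-resolved DW measurements
(b0 volumes are excluded from candidacy; each retained combo keeps its
matched b0).  A scoring network (27 -> 64 rectified units with batch
normalisation and dropout p = 0.2 -> 27 sigmoid outputs) produces
importance scores in [0, 1]; the 12 highest-scoring measurements, weighted
by their scores, feed a prediction network (12 -> 64 -> 27) that
reconstructs the full vector; both train jointly for 100 epochs with Adam
at learning rate 1e-5 on the MSE of that reconstruction.  One network pair
is trained per subject and scores are averaged across subjects, then over
each b-value's direction triplet; the top four b-values form the reduced
protocol (ties break towards the lower b), guaranteeing complete triplets
and hence an acquirable scheme.  Per-measurement top-12 selection without
triplet grouping is available via the selected indices.

Design notes:

* Each subject's measurement matrix is standardised per feature before
  training.  This is load-bearing: with raw signal levels, gradient
  descent under Adam systematically inflates the scores of low-level,
  unpredictable measurements (a pure noise floor is "rewarded" for
  reconstructing itself), inverting the ranking.  On an equal footing the
  converged scores rank mutually informative b-values above signal-free
  ones, which the planted-structure test checks across ten seeds.
* Gradients reach the scoring network only through retained features (the
  score multiplies the selected measurement); unselected features receive
  gradient only via batch-norm statistics.  Exploration of the retained
  set comes from dropout and batch-to-batch score fluctuation.
* All subjects' network pairs are advanced in lock-step as stacked weight
  tensors; this is a pure speed measure and does not change the
  per-subject mathematics.
* The prediction target is the normalised (standardised) measurement
  vector, consistent with the normalised inputs.

## Synthetic phantoms and cohorts

The generator emulates the study conditions so every module is testable
without data: voxel grids (default 32 x 32 x 4, ~1000+ voxels per class)
carved into disjoint tissue-class slabs; per-voxel parameters drawn from
truncated normals around class means; the acquisition simulated
direction-resolved with independent Rician noise per measurement and per
matched b0 (complex Gaussian of scale 1/SNR on a unit b0), applied before
spherical averaging and before matched-b0 division, in acquisition order.
Class means encode the reported tissue contrasts: normal parenchyma
f_IC 0.12 (SD 0.03), cancerous tumour 0.32, oncocytoma 0.17; vascular
tumours f_VASC 0.29 (SD 0.05) vs non-vascular 0.13 (SD 0.02).  Cell radii
per class are package defaults inside [0, 15] um (5–10 um; no measured
values exist for these tissues).  Cohorts add subject-level jitter to the
class means (f_IC SD 0.03, matching the reported between-patient spread of
normal-parenchyma f_IC) with per-subject seeds spawned from one master
seed.  An optional T2 channel scales each combo's signals and noise by
exp(-TE/T2); matched-b0 division cancels it exactly under a fixed seed,
which the tests assert.

What the phantoms do **not** emulate: anatomy and spatial correlation
(classes are homogeneous slabs), partial-volume mixtures, EPI distortion
and field inhomogeneity, registration and denoising residuals, and
between-vendor protocol variation.  Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not clinical
performance.

## Group statistics

ROI summaries are per-parameter mean/SD/voxel-count tables.  Group
comparisons are rank-based: Wilcoxon's signed-rank for paired groups
(identical paired samples return p = 1 by convention) and the rank-sum
(Mann–Whitney U) variant for unpaired groups — synthetic vascular vs
non-vascular comparisons are unpaired, so the rank-sum form is the default
there; both are exposed.  p-values are star-coded in figure style:
< 0.0001 ****, 0.0001–0.001 ***, 0.001–0.01 **, 0.01–0.05 *, else ns.

## Known limitations

* GPD accuracy degrades for radii >~10 um at the strongest diffusion
  weightings (see above); fitted radii near the clamp ceiling should be
  read qualitatively.
* The patient-level contrasts cannot be reproduced without the (non-public)
  imaging data; the package substitutes a power analysis on the printed
  group means/SDs (n = 10 per group detects the vascular-fraction contrast
  at alpha = 0.05 in effectively all simulated cohorts).
* The selector's score dynamics are those of a reconstruction autoencoder:
  scores measure how useful a measurement is for predicting the full
  vector under the trained networks, not a task-specific (e.g. diagnostic)
  utility.
* Repetition time varies in the emulated acquisition (2000–3349 ms) but is
  not modelled; its effect cancels in normalised signals to the extent T1
  saturation is constant across volumes.
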