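# Methods

## Problem and scope

`mwtriage` implements the statistical analysis chain of a microwave-based
screen for traumatic intracranial hematomas.  A head-worn array of 8
antennas measures complex scattering coefficients (S-parameters) over
0.1–1.95 GHz; chronic subdural hematomas (cSDH) change the dielectric
contrast inside the head and perturb these spectra.  The pipeline turns
multi-antenna, triplicate complex measurements into one feature vector per
subject, classifies it with a rank-truncated subspace model, and reports
diagnostic accuracy by leave-one-out (LOO) cross-validation.  Because the
underlying clinical raw measurements are not publicly available, the
package ships a synthetic measurement generator that reproduces the
statistical structure of such data, and every end-to-end claim in the test
suite is made on synthetic cohorts.

## Channels and the exclusion mask

One complex coefficient is kept per unordered antenna pair ("channel"):
8 reflection channels plus C(8,2) = 28 transmission channels, 36 in total.
Directed duplicates are collapsed by reciprocity; a reader for directed
data should average the two directions.  Antennas are numbered 1–2
(forehead), 3–6 (lateral), 7–8 (back of head).

The default mask retains the 26 channels touching at least one lateral
antenna and removes the reflections of antennas 1, 2, 7, 8 and the
transmissions internal to that peripheral set.  These channels either
traverse a long, strongly attenuated path or probe regions away from the
typically lateral hematoma location.  Lateral reflections (3,3)…(6,6) are
retained, since they touch a lateral antenna; users who want to drop them
can supply any mask via `mask_from_config` or a plain-text mask file
(one `a-b` token per line).

## Feature assembly

1. **Triplicate averaging** — the three consecutive measurements are
   averaged coherently (complex mean).  Coherent averaging preserves the
   phase information the classifier exploits; a magnitude-mean would
   discard it.
2. **Band selection** — a closed interval on the 50 MHz grid, with a
   half-step tolerance at the endpoints to avoid float fragility.  The
   screening configuration uses 0.75–1.95 GHz (25 grid points).
3. **Vectorization** — retained channels × selected frequencies are
   concatenated channel-major in canonical channel order; the default
   layout has 26 × 25 = 650 complex entries.  No further calibration or
   normalization of the raw data is applied.

## The subspace classifier

For each class k ∈ {cSDH, HC}, the training feature vectors are stacked as
columns and the leading r left singular vectors form an orthonormal basis
U_k of the class subspace (default r = 1, "the first subspace dimension").
A subject with feature vector x gets the decision value

    score(x) = d_HC(x) − d_cSDH(x),   d_k(x) = ‖x − U_k U_kᴴ x‖ / ‖x‖,

larger meaning more hematoma-like; classification is `cSDH` iff
score > threshold, with ties going to HC so that a tie never triggers a
positive.  Design choices:

* **No mean-centering** — subspaces pass through the origin, which makes
  the score exactly invariant to a global complex rescaling of x (head
  size, contact pressure).  A centered variant exists behind
  `ClassifierConfig.center` for sensitivity checks.
* **Residuals normalized by ‖x‖** — scores comparable across subjects with
  different overall signal amplitude.
* Degenerate training matrices (rank below r) are rejected at fit time.

## Evaluation

LOO cross-validation scores every subject with a model trained on all
others.  The ROC is traced by sweeping the threshold over all observed
decision values; the point at threshold t counts subjects with score ≥ t
positive (the operating point of the classify rule at a threshold just
below t).  The AUC is the trapezoidal area and equals the tie-aware
Mann–Whitney statistic; the test suite asserts the identity to 1e-12 on
1000 random score sets.  Specificity at 100% sensitivity is the fraction
of controls strictly below the minimum patient score — a control tied with
that minimum counts as a false positive, consistent with the tie rule.

Model selection sweeps all frequency intervals with endpoints on the
50 MHz grid and width ≥ 400 MHz (465 candidates on the full grid), crossed
with candidate ranks.  The rank with the highest AUC averaged over all
intervals is chosen first, then the interval with the highest specificity
at full sensitivity at that rank; ties break deterministically (lower
rank, wider interval, lower band start).  The selection runs once on the
full cohort — it is not nested inside the LOO — so accuracy figures at the
selected setting carry the usual selection optimism; this mirrors how such
screening settings are fixed in practice ("used throughout all tests").

## Resampling checks

* **Robustness** — 100 repeats of the LOO after removing k = 2 random
  subjects (unstratified; a stratified option exists).  A mean AUC close
  to the full-cohort AUC with small SD indicates the configuration does
  not hinge on particular subjects.
* **Random diagnosis** — 100 repeats after assigning every subject an
  independent fair-coin label (a balanced label-permutation variant is
  available); assignments leaving a class with fewer than rank + 2
  subjects are redrawn and the redraw count is reported.  An unbiased
  pipeline scores at chance.  One master seed spawns per-iteration
  substreams, so results are independent of scheduling.

## The synthetic generator

The generator is a deliberately simple attenuation-plus-delay surrogate,
not a field solver; its purpose is the statistical structure the
classifier must cope with, not electromagnetic accuracy.

Per subject, antennas sit at azimuths 2π(a−1)/8 on a circle of radius
R = 0.09 m.  A channel's path length is the chord between its antennas
(transmissions) or 0.3 R (reflections, standing in for the shallow
superficial round trip — any small positive constant serves).  The
noise-free baseline at frequency f (GHz) over path L is

    B(c, f) = exp(−α·s·L·f) · exp(−i·2π·f·τ₀·s·L)

with attenuation α = 25 Np/(m·GHz), slowness τ₀ = 20 ns/m, and a
per-subject head scale s ~ N(1, σ_head²).  Patients draw a lesion volume
v ~ LogNormal(log 100, 0.6²) mL (matching the surgical cohort's ~112 mL
mean) and an azimuth uniform on the lateral arc [π/2, 5π/4] covered by
antennas 3–6 — cSDH is a lateral lesion, which is also what motivates the
channel mask.  With probability 0.3 the volume splits 2:1 over two
opposite azimuths (6/20 clinical patients were bilateral).  The lesion
multiplies into channels by an azimuthal weight exp(−(Δ/λ)²) around its
azimuth and perturbs the spectrum by

    H(c, f) = κ · (v/100)^{1/3} · w_c · B(c, f) · exp(i·2π·f·0.1),

scaling like a linear lesion dimension (a linear-in-v option exists).
Each of the three repetitions applies a repositioning gain
g ~ N(1, σ_rep²) and adds complex noise CN(0, σ_n²|B|²).  A per-subject,
per-channel complex contact gain CN(1, σ_c²) multiplies the whole channel
spectrum: antenna-to-skin coupling differs between subjects channel by
channel and is stable across consecutive repetitions.  This is the
high-dimensional component of inter-subject variability, and it matters
statistically: with only low-dimensional nuisance (the scalar head scale),
the rank-1 LOO analysis acquires a marked pessimistic bias under label
permutation, which rich inter-subject structure dilutes.

Default magnitudes — σ_head = 0.01, σ_c = 0.05, σ_rep = 0.01,
σ_n = 0.02, κ = 0.2, λ = 1.8 rad — were calibrated once by simulation
(`scripts/calibrate_generator.py`) so that the default regime reproduces
the performance envelope reported for the clinical screen: LOO AUC above
0.8 in essentially all seeded 20+20 cohorts (mean ≈ 0.95), chance-level
AUC (≈ 0.47–0.49) for zero-contrast cohorts and for randomly reassigned
diagnoses, and patient decision values correlating positively with
v^{1/3}.  They are frozen; they are not re-tuned at run time.

### What the generator does and does not emulate

It reproduces smooth complex spectra, channel-local and volume-scaled
lesion contrast, triplicate noise, and inter-subject variability at both
low (head scale) and high (contact gains) dimensionality.  It does not
model anatomy, dielectric dispersion, antenna coupling physics, or
lesion-age-dependent attenuation heterogeneity.  Passing tests therefore
demonstrate that the pipeline recovers planted statistical structure and
is honestly calibrated under null conditions — not that the clinical
accuracy figures would replicate on real measurements.

## Numerical choices and degenerate inputs

* SVD via LAPACK (economy mode); class bases ordered by decreasing
  singular value; degeneracy threshold 1e-12 relative.
* ROC thresholds are the distinct observed scores plus a sentinel above
  the maximum; all tie conventions are fixed and documented so curves are
  bit-reproducible.
* Frequency-interval membership uses a half-grid-step tolerance.
* Errors are raised (never silently corrected) for empty masks or
  selections, shape mismatches, zero feature vectors, classes too small
  for the requested rank, degenerate frequency grids, and malformed
  cohort CSV files (with the offending subject/channel or line named).

## Problem sizes used in the shipped analyses

Tests and the acceptance script run at the study scale of 20+20 subjects
with the full 38-point grid for single evaluations, 10–100 seeded
replicates for stochastic claims, and a reduced sweep grid (150 MHz step,
28 subjects) for planted-band-recovery demonstrations; the full 465-
interval sweep is exposed in the API and demonstrated on the reduced grid
in `examples/frequency_sweep.py`.

## Known limitations

* The subspace classifier reconstruction (per-class SVD through the
  origin, relative-residual difference) honors the documented constraints
  of the device's classifier — supervised training, retained "subspace
  dimensions", a single scalar decision value, tunable threshold — but
  the original's exact equations are not public; normalization details
  may differ.
* LOO with per-class subspaces has a small pessimistic bias under label
  permutation (the held-out subject's class has one fewer training
  vector); with the default generator this keeps null AUCs slightly below
  0.5, consistent with the clinical bias check (0.47 ± 0.11).
* Model selection is not nested within the cross-validation; reported
  accuracy at the selected setting is optimistic.
* No confidence intervals on AUC are computed.
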