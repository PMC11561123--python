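# Methods

This note documents the models, the synthetic study design, the numerical
conventions, and the deliberate design choices behind `stimmap`.

## Spatial conventions

All coordinates are template-space millimetres; voxel indices are 0-based;
the 4x4 affine of each volume is the single source of truth for the
voxel-to-world mapping.  Mask volumes are {0,1}-valued.  Streamlines are
polylines of world-mm points; TRK/TCK I/O goes through
`nibabel.streamlines`, and a plain JSON point-list dialect
(`{"streamlines": [[[x,y,z], ...], ...]}`) is provided so small fixtures
stay text-only.  Template frame labels are carried as metadata; a frame
mismatch between inputs warns rather than errors, because the inputs this
pipeline sees in practice carry no reliable frame contract.

## E-field model

Per-patient stimulation fields use an isotropic point source:

    |E|(r) = A * k_cal / max(r, r_min)^2   [V/mm]

with `A` the stimulation amplitude (volts; milliamp-programmed devices are
mapped to the volt scale by a configurable factor, default 1 mA -> 1 V),
`k_cal = 1 mm` a calibration constant and `r_min = 0.5 mm` a clamp that
freezes the singularity at the contact.  This is a deliberately simple
monotone radial field: every downstream statistic consumes only field
magnitudes and their ranks, so the pipeline's logic is preserved under any
smooth monotone falloff.  With the defaults, a 2 V stimulation crosses the
0.2 V/mm activation threshold at sqrt(10) ~ 3.2 mm — a plausible chronic
stimulation extent.  Not modelled: tissue anisotropy/conductivity,
directional leads, multi-contact fractionation, axon-cable activation.

Bilateral implants are analysed in one hemisphere: contacts on the
non-target side are reflected across the midsagittal plane (x -> -x), the
field model being symmetric under that reflection.  When two hemispheric
fields must be pooled on one grid, the default is the voxel-wise maximum
("stimulation reaches this voxel from either side"); voxel-wise mean is
available.

## Sweet-spot model

* Support mask: voxels where **at least 3** patients' fields exceed
  **0.2 V/mm strictly**.  Both constants are exposed; the strict inequality
  at the threshold is pinned by test.
* R-map: at each supported voxel, the across-patient Spearman correlation
  (Pearson selectable) between field magnitude and improvement.  Voxels
  with zero across-patient magnitude variance get r = 0.  All outcomes are
  converted to improvement polarity (higher = clinically better) before
  any correlation, so positive map values always mean beneficial.
* Scoring: Spearman correlation between a patient's magnitudes and the
  R-map values over the support `mask AND {field > threshold}` (full-mask
  and nonzero-union supports selectable).  Fewer than 10 support voxels
  yields an *undefined-score marker* (NaN), which downstream validation
  excludes and counts — a 0 would be a meaningful rank correlation and is
  never imputed.  Average ranks break ties throughout.
* The R-map peak (argmax; first voxel in array order on exact ties) serves
  as the reference coordinate for contact-distance analyses.
* The signed map is kept (no positive-only thresholding before scoring).

## Fiber filtering

* Model fit: each streamline's Fiber-R-Score is the across-patient Spearman
  correlation between the **peak** trilinearly interpolated field magnitude
  along the streamline and improvement.  Streamlines reached (peak
  strictly above 0.2 V/mm) by fewer than 3 patients, or with zero peak
  variance, are flagged `unscored` with r = 0.  "Reached/intersected"
  deliberately reuses the same 0.2 V/mm constant as the sweet-spot model so
  one exposure concept spans both arms.
* Patient scoring: over intersected streamlines (peak > threshold), with
  `m_s` the **mean** interpolated magnitude along streamline `s`, three
  coefficients are computed:
  - `stim_weighted_mean_r = sum(m_s r_s) / n_intersected` — the primary
    validation coefficient.  It keeps the stimulation-strength information:
    under-stimulating a beneficial tract lowers the score.
  - `weighted_mean_r = sum(m_s r_s) / sum(m_s)` — a convex, magnitude-
    normalized mean of the intersected scores.  Because the weights cancel,
    it is nearly constant for any patient whose field reaches only the
    signal-carrying bundle, which makes it a poor validation coefficient in
    a geometry without strongly negative tracts; it is reported for
    sensitivity analyses.
  - `weighted_sum_r = sum(m_s r_s)` — the unnormalized sum.
  No intersected streamlines -> undefined marker (NaN), excluded and
  counted downstream.
* Out-of-grid streamline points read as field 0.

## Validation statistics

Per-arm validation Spearman-correlates patient scores with improvement
across the cohort.  The asymptotic p uses the t-approximation; because the
cohorts are small (14/29), a Monte-Carlo permutation p with +1 smoothing,
`(1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)` (two-sided by default,
one-sided selectable), is always computed alongside, with its own seeded
generator.  Validation refuses cohorts with fewer than 5 usable patients.

The responder-threshold analysis partitions the training cohort at a
progression threshold (top responders: progression change <= threshold),
reports each patient's mirrored-contact distance to a reference coordinate
(default: the R-map peak), and per-group means of progression, LEDD change
and amplitude, swept over a threshold grid.  Empty groups are flagged and
their statistics left absent.

LEDD (levodopa-equivalent daily dose) sums daily doses times the standard
published conversion factors; the factor table ships as an editable JSON
(`stimmap/data/ledd_factors.json`).  COMT-inhibitor adjuncts that scale the
concurrent levodopa dose are out of scope for the flat per-drug table and
must be pre-applied.

## Synthetic study design

The generator emulates the two-cohort design with planted ground truth.

* Geometry: target centre at (-12, -13, -6) mm (a dorsolateral-STN-like
  template coordinate), analysis grid 0.5 mm isotropic over a +/-10 mm box
  around it.  Contacts = target + isotropic Gaussian scatter
  (sigma = 2 mm); each patient lands in a random hemisphere (opposite-side
  contacts are mirrored placements of the same scatter).
* Stimulation parameters: training cohort (n = 14) 1.9 +/- 0.3 V, 60 us,
  130 Hz; validation cohort (n = 29) 2.9 +/- 0.9 V with an 8/29
  milliamp-programmed subset at 3.0 +/- 0.6 mA.
* Outcome model: `improvement = a - b * distance(contact, target) + noise`.
  - Training (improvement in UPDRS-III points over two years):
    a = 4, b = 2 /mm, noise sd = 1.2.  These values give roughly 3 of 14
    patients with stable-or-better two-year change scores — matching the
    emulated trial's 4 of 14 — and enough signal for a 14-patient map to
    localize; they imply a strong in-sample spatial effect, as observed in
    the emulated study.  Outcomes are emitted as pre/post UPDRS-III pairs
    (baseline ~ N(28, 6), clipped nonnegative) whose difference is the
    progression change score.  Scores are kept continuous rather than
    integer-rounded so that noiseless configurations remain strictly
    monotone in distance.
  - Validation (percent UPDRS-III improvement at ~5-year follow-up):
    a = 45 %, b = 7 %/mm, noise sd = 10 %.  With the contact-distance
    distribution this yields pipeline-level validation correlations of
    about 0.4-0.5 — the moderate, realistic regime for out-of-sample DBS
    outcome models.
  - LEDD changes mildly favour well-placed contacts (smaller medication
    increase / larger reduction near the target); amplitudes are drawn
    independently of placement.
* Tractogram: smooth cubic-spline bundles around jittered control points.
  On-target bundles pass within `target_sigma` (1.5 mm) of the target;
  off-target bundles keep every point beyond 4x that distance (offsets and
  jitter are clipped so both guarantees hold by construction and are
  re-verified at generation time).  Defaults: 2 on-target and 2 off-target
  bundles, 20 streamlines each, 40 points per streamline, 40 mm long.
* Determinism: one seed feeds three independent substreams (train, valid,
  tractogram) via `numpy` `SeedSequence.spawn`, so changing one cohort's
  size never perturbs another.  Fixed seed => bit-identical datasets and
  byte-identical pipeline CSVs.

What the generator does **not** emulate: real STN anatomy and its
surrounding nuclei, imaging/registration error, per-item UPDRS structure,
placebo and medication effects, negative (symptom-worsening) tracts with
their own outcome contribution, and correlated bilateral placements.
Passing tests therefore demonstrate that the pipeline recovers planted
spatial effects and is statistically calibrated — not that the simplified
field model or the linear-in-distance outcome model are clinically
accurate.

## Numerical and testing choices

* All rank computations use average-rank tie handling (scipy `rankdata`).
* Voxel-wise and streamline-wise correlation maps are computed as
  rank-then-Pearson in vectorized form; an independent hand-written
  rank-then-Pearson oracle and a triple-loop mask-counting oracle back the
  tests.
* The null-calibration test runs the sweet-spot arm on 200 null (b = 0)
  cohorts at 1.0 mm grid resolution — the map statistics are
  resolution-independent under the null, and the coarser grid keeps 200
  full pipeline repetitions cheap; the rejection count is checked against
  the exact binomial 95% interval around the nominal 5% level.
* Monotone-transform invariance of the Sweet Spot Score (cube, exp) is
  asserted bit-identically: ranks, not magnitudes, enter the score.
* Undefined scores propagate as NaN markers end-to-end and are excluded
  with explicit counts; nothing is silently imputed.

## Known limitations

* The point-source field ignores pulse width and frequency (they are
  carried as metadata only); amplitude is the single field-scaling input.
* The mA -> V mapping is a configurable constant, not a device model.
* The R-map peak is a voxel argmax; sub-voxel localization is not
  attempted.
* The flat LEDD table cannot express dose-dependent adjunct rules.
* `pool_bilateral` supports max/mean pooling of two fields on a shared
  grid; the synthetic cohorts are unilateral-after-mirroring, so pooling
  is exercised by unit tests rather than the default study.
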