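# Methods

## Model

The package implements three-level multilevel PCA (mPCA) for shape and
texture vectors. A dataset is labeled by a hierarchy of three nested
grouping factors. Two bindings are built in:

* **static faces** — top = group (e.g. biological sex), middle = subject,
  bottom = condition (e.g. neutral vs smiling);
* **smile frames** — top = subject, middle = smile phase, bottom = frame
  within phase.

One covariance matrix is formed per level:

* **bottom**: for every (top, middle) cell, the sample covariance of the
  cell's observations about the cell mean (divisor N − 1; a cell with a
  single observation contributes a zero matrix and is logged). For the
  static-faces binding these cell matrices are averaged directly over all
  middle units ("flat"); for the smile binding they are first averaged over
  phases within each subject and then over subjects ("nested"). The two
  conventions coincide for balanced designs.
* **middle**: within each top unit, the covariance of its middle-unit means
  about their (unweighted) mean, averaged across top units.
* **top**: the sample covariance of the G top-unit means about the mean of
  those means, divisor G − 1. Its rank is at most G − 1, so a two-group
  design retains exactly one component at this level.

Averages of covariance matrices are unweighted by default; a `weighted=True`
flag weights by the number of observations per unit instead. The model's
grand mean (the intercept of the reconstruction) is the mean of all
observation vectors; for balanced designs this equals the mean of the group
means used to center the top-level covariance.

Each level's matrix is eigendecomposed with `numpy.linalg.eigh`. Eigenvalues
are sorted descending with a stable tie-break on the original index, tiny
negative round-off values are clipped to zero (clipping is logged when it
exceeds −1e−8·λ_max), and each eigenvector's sign is fixed so its
largest-magnitude element is positive — eigen signs are arbitrary and the
convention makes runs and serializations reproducible. Retention defaults to
all eigenvalues above 1e−10·λ_max of the level; an explicit per-level count
(or a variance fraction for single-level PCA) overrides this, truncated to
the numerical rank with a log message.

## Joint coefficient fit

Eigenvectors are orthonormal within a level but in general not orthogonal
between levels, so the per-level coefficients of a new vector are fitted
jointly by minimizing the squared residual of the three-level
reconstruction. Two routes are implemented:

* **direct** — `numpy.linalg.lstsq` on the column-stacked per-level bases;
  if the stacked basis is rank deficient the minimum-norm solution is
  returned (logged).
* **gradient** — plain gradient descent `a ← a − κ ∂Δ/∂a` with κ = 0.01
  from an all-zero start. The iteration stops when the largest coefficient
  update drops below 1e−12 (cap 100 000 iterations, then a warning and the
  best iterate). An update-size criterion is used rather than a
  cost-decrease criterion because the cost plateaus at the positive residual
  of a partial model long before the coefficients stop moving; the update
  norm directly bounds the remaining coefficient error. Starting from zero
  keeps the iterate in the row space of the stacked basis, so both routes
  converge to the same minimum-norm solution and agree to ≤1e−6 per
  coefficient on generic instances (verified over 50 random models per run).

For κ = 0.01 the iteration is a contraction whenever the largest eigenvalue
of the stacked Gram matrix is below 100, which holds by a wide margin for
three orthonormal blocks. Convergence slows as the smallest positive Gram
eigenvalue shrinks; with near-degenerate stacked bases (e.g. retaining
components down to the rank tolerance on small datasets) the direct solver
is the practical route, and the CLI defaults to it.

Standardized scores divide each coefficient by √λ of its component;
components with eigenvalues at the rank tolerance are dropped from
standardization with a warning.

## Preprocessing

Static shapes are centered, scaled to unit *average point-to-centroid
distance*, and rotationally aligned by generalized Procrustes analysis: each
iteration rescales every shape and rotates it onto the running consensus
with the closed-form proper (det +1, reflections excluded) orthogonal
solution, then recomputes the consensus. The consensus is re-aligned to its
predecessor each iteration to remove the free global rotation — without
this the whole configuration drifts and convergence is artificially slow.
The loop stops when the consensus moves less than 1e−9 RMS (cap 100
iterations); a final pass aligns every shape to the converged consensus and
restores exactly unit mean point-to-centroid distance. Initialization from
the raw average makes the result invariant to row order. Degenerate shapes
(all points at the centroid) are rejected. Dynamic mouth shapes are only
centered ("center_only"), because scale and orientation changes are part of
the motion being modeled.

## Texture

Texture vectors are the intensities of the pixels inside a fixed binary ROI
mask, read in row-major order. Images are promoted to float in [0, 1] from
8- or 16-bit grayscale. Illumination is standardized per image by an affine
rescale of the ROI intensities to a common mean and SD (defaults 0 and 1);
a mean-only variant is available behind a flag. The affine form makes the
standardization idempotent and invariant to any per-image gain/offset. No
shape-normalizing warp is applied before sampling — texture models therefore
confound shape and appearance near moving boundaries, a known limitation of
warp-free appearance vectors. Polygon ROIs are rasterized with
`skimage.draw.polygon` (scanline fill over pixel centers), which matches
even-odd filling on the simple polygons supported.

## Smile amplitude and phase segmentation

The amplitude at frame t is the Euclidean inter-chelion distance divided by
twice the rest-frame distance, hence exactly 0.5 at frame 0. Series are
smoothed by a centered moving average (window 5 frames; the window shrinks
symmetrically at the edges), and the segmenter differentiates the smoothed
series with central differences *per frame* (thresholds are expressed per
frame, so the frame rate is deliberately not applied here) and smooths the
derivatives with the same window.

Default thresholds: rest band ±0.02 around the 0.5 baseline; sustained-rise
threshold 0.002/frame for at least 3 consecutive frames; apex band at 95% of
the peak elevation; all configurable. The seven phases are located as
follows:

* the **onset** limb is the sustained rise with the largest amplitude gain
  ending at or before the global maximum (mirrored for **offset**); its
  boundary sits immediately after (before) the last (first) frame that is
  *at rest* — amplitude inside the rest band with |d1| ≤ 2× the rise
  threshold — so noise excursions glued to the limb's tail cannot drag the
  boundary outward;
* **apex** collects the frames around the peak above the 95% band; a
  departure counts only if the amplitude stays below a confirmation level
  (5 percentage points of span lower) for the minimum run length, so brief
  noise dips do not split the plateau, and the boundary is placed at the
  95%-crossing leading into the confirmed departure;
* the **acceleration/deceleration** split of each limb is the smoothed
  second-derivative zero crossing nearest the limb's first-derivative
  extremum (ties resolve to the earlier frame).

A flat series raises "no smile detected"; multi-peak series are segmented
around the global maximum with a warning. Degenerate boundary orderings are
nudged deterministically so the seven phases are non-empty whenever the
series admits them. Because the thresholds are per frame, segmentation is
equivariant under temporal resampling only when the thresholds are rescaled
accordingly (e.g. doubling the rise threshold and halving the window after
dropping every other frame); the test suite checks this form.

## Synthetic data generator

The generator is the package's source of ground truth and mirrors the two
study designs the models target.

**Hierarchical shapes.** A stylized symmetric 21-landmark 2D face template
(standard anatomical landmark names, coordinates in mm) receives a fixed
group effect (±σ_group along a "sex-like" field: eye spacing, mouth width,
face length), a per-subject scalar effect (SD σ_subject along a face-
elongation field), a condition effect (σ_condition along a smile field:
mouth widens, corners rise, lids narrow, nose base widens), and i.i.d.
Gaussian landmark noise. Defaults: 2 groups × 10 subjects × 2 conditions,
σ_group = σ_subject = σ_condition = 5 mm, σ_noise = 0.5 mm — moderate,
clearly separated effects ten times the noise, the regime in which level
separation is an honest but non-trivial test. The three effect fields are
Gram–Schmidt orthogonalized by default (condition kept pure, then group,
then subject) so each level carries an independent planted direction; the
returned ground truth holds the actual unit fields used. With correlated
fields the levels would mix by construction and direction recovery would be
bounded by the field geometry rather than the estimator.

**Smile trajectories.** A 13-point 3D mouth-outline template follows an
amplitude profile: baseline 0.5 through rest, a rescaled-logistic rise
across onset whose inflexion sits exactly at the declared
acceleration/deceleration boundary, a plateau at the peak (default 0.75,
i.e. a 50% widening) through apex, a mirrored fall through offset. The smile
displacement field is normalized so the inter-chelion distance reproduces
the profile; the subject and smile fields keep mirror-symmetric chelion
components so that distance is exactly linear in the activation and the
zero-noise amplitude round-trips to machine precision. Defaults: 150 frames,
phase fractions (0.24, 0.033, 0.033, 0.22, 0.033, 0.033, 0.408), logistic
steepness 0.8/frame. The onset and offset are deliberately brisk (≈10
frames, ≈0.4 s at 24 fps): the construction boundaries of a logistic limb
are only detectable features of the curve when the limb's tails fit inside
the declared phases, and these fractions keep every boundary within the
segmenter's three-frame recovery band across seeds at landmark noise up to
5% of the mean smile displacement (≈0.42 mm). Landmark noise in the
recovery checks is expressed as a fraction of the mean per-landmark smile
displacement, the natural scale of the motion.

**Texture images.** A 48×48 face-like raster (face ellipse, eye and mouth
blobs) receives a cheek-patch group effect, a mouth-patch condition effect,
a smooth Gaussian random field per subject, optional per-image illumination
gain/offset jitter, and pixel noise; the ROI is the face ellipse. The images
are caricatures: they exercise the vectorization, standardization, and
level-separation machinery, not photorealism.

All randomness derives from named `SeedSequence` substreams keyed by effect
family and unit index, so enlarging a design leaves previously generated
units bit-identical.

**What passing these tests shows — and does not.** The generator's effects
are linear displacements with Gaussian noise, exactly the regime mPCA
assumes. Success on it demonstrates correctness of the covariance
construction, eigenmodels, joint fit, and segmentation logic; it does not
demonstrate robustness to outliers, non-linear shape variation, unbalanced
designs with informative imbalance, or landmark placement error structure in
real data.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: shape
designs of 2 × 10–20 subjects × 2 conditions (40–80 observations of length
42), 50 random joint-fit instances of length ≤ 40 with ≤ 5 components per
level, 20 seeds × 2 noise levels for phase recovery on 150-frame
trajectories, and 8–24 images of 48×48 pixels. These sizes keep every check
fast while leaving all claimed margins wide (direction cosines > 0.95 are
met at ≈0.99; separations > 2 pooled SD at ≈10–20).

## Known limitations

* Exactly three levels; no random-effects/REML estimation, no robust
  covariance, no significance testing of separations.
* Rank constraints at high levels (G groups → rank G − 1) limit how many
  modes those levels can express; interpret high-level eigenvalue magnitudes
  with care.
* The gradient route is slow on ill-conditioned stacked bases; use the
  direct solver there.
* Segmentation thresholds are frame-based conventions tuned for the
  generator's sampling; real video at other frame rates needs rescaled
  thresholds.
* No landmark detection, no missing-landmark imputation, no shape-to-texture
  warping.
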