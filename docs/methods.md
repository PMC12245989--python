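# Methods

`leafspec` analyses leaf-level hyperspectral reflectance campaigns from
free-air CO2 enrichment (FACE) experiments: it preprocesses raw
spectroradiometer output, summarises each leaf by vegetation indices and
integrated reflectance, tests for a CO2-treatment signal with nested
mixed-effects models, and probes the whole spectrum with PCA and a tuned
PLS-DA classifier.  This note documents the models, the numerical choices,
and what the bundled simulator does and does not emulate.

## Spectral preprocessing

Field leaf-clip spectra arrive as three overlapping detector sweeps (VNIR
350–1000 nm at 1.5 nm, SWIR1 1000–1890 nm at 3.8 nm, SWIR2 1890–2500 nm at
2.5 nm).  Preprocessing is: stitch the sweeps, linearly interpolate to the
inclusive integer grid 350..2500 nm (2151 points), and multiply by the
laboratory-calibrated reflectance of the leaf-clip reference panel to
convert relative to absolute reflectance.

Two stitching policies are provided because field-spectroscopy practice is
not unanimous about overlap regions:

* **cut** (default): detector-priority cut at the 1000/1890 nm nominal
  boundaries.  Deterministic and value-preserving; any detector step
  remains visible.
* **rescale**: SWIR1, then SWIR2, is multiplied by the ratio of segment
  means over the shared overlap window before the cut, removing detector
  steps at the cost of altering SWIR absolute levels.

Interpolation is linear rather than spline: it is monotonicity-safe and
introduces no overshoot near the sharp water-absorption shoulders.  No
extrapolation is performed; a shortfall greater than 5 nm at either end of
the 350–2500 nm range, or an inter-segment gap above 5 nm, is an error, and
smaller shortfalls hold the edge value.

Reflectance is stored as a fraction throughout (percent appears only in
rendered output).  Leaf-clip geometry can legitimately return values above
1 relative to the panel, so such values are retained up to 1.5 and flagged
per spectrum (`over_unity`) rather than silently clipped; negatives are
floored at 0.

## Vegetation indices

The eight indices (NDVI, MCARI, PRI, PSRI, NDNI, NDLI, NDWI, NPQI) are
evaluated from single 1-nm bands, with wavelengths rounded to the nearest
integer nanometre.  NDNI and NDLI use natural logarithms; their
log-reciprocal ratio structure makes the value independent of the log
base.  Integrated reflectance is the trapezoidal integral of fractional
reflectance over 350–2500 nm (on a 1-nm grid this is within half a band of
a plain sum), giving values around 400–450 fraction·nm for typical leaves.
An index whose formula cannot be evaluated for a spectrum (zero
denominator, non-positive band under a log) is flagged undefined and
excluded listwise from downstream models with a logged count.

## Mixed-effects treatment models

Each response (an index, integrated reflectance, or a standardized PC
score) is modelled as

    response ~ CO2 + (1 | tree) + (1 | tree:date)

with aCO2 the reference level, so the intercept is the aCO2 mean and the
single fixed effect is the eCO2 offset.  Estimation is REML.  The variance
ratios θ_j = σ²_j/σ²_e are profiled: the fixed effects and residual scale
have closed forms given θ, and the restricted criterion is minimised over
log θ by bounded L-BFGS-B from a method-of-moments start, followed by a
Nelder–Mead polish (the profiled surface is flat enough near the optimum
that quasi-Newton with numerical gradients can stop early; the polish
restores ~1e-6 relative reproducibility of the standard errors).
Convergence tolerance is 1e-12 relative on the criterion.  Variances are
kept non-negative through the log parameterisation with a floor of 1e-10
on the ratio; boundary fits are reported and flagged, not errored.  The
covariance matrix is block-diagonal over the coarsest grouping factor, so
each criterion evaluation factors small per-tree (or per-array) blocks.

Fixed-effect tests use Satterthwaite's approximation,

    df = 2·Var(c'β̂)² / Var̂[Var(c'β̂)],

with the denominator from the finite-difference gradient of Var(c'β̂) in
the variance components and the inverse REML observed information
(finite-difference Hessian, relative steps 1e-5 and 1e-4).  Components
estimated at the zero boundary (below 1e-6 of the residual variance) are
excluded from the approximation: they carry no information about the
contrast variance and destroy the conditioning of the information matrix.
In the no-random-effect limit this recovers the classical residual df
n − p; in the study-shaped design (treatment varying over 8 trees) the
treatment df sits near 6, which is why leaf-level replication does not
rescue power.  Against lme4/lmerTest on a fixture dataset the
implementation agrees to ~1e-8 in estimates, ~1e-3 relative in variance
components and ~0.01 in df.

The "multivariate" model for the first four principal components is
implemented as a stacked univariate model: scores are standardized per
component, stacked long, and fitted with a single common treatment effect
and shared residual variance.  Per-component univariate fits are reported
alongside.  A correlated multivariate formulation (per-PC residuals,
cross-PC covariance) would be a different model; both readings are
labelled, neither claimed canonical.  An array-level random intercept is
available (`array_col=`) but off by default; in nested designs of this
shape it tends to absorb no variance beyond the tree level.

## PCA and PLS-DA

PCA is computed by SVD of the centred matrix; by default columns are also
scaled to unit variance (a centre-only flag is provided — reproduction
against real campaigns should try both, since analysis software families
differ in their default).  Component signs are fixed by making each
component's largest-magnitude loading positive, so scores are reproducible
run to run.  Explained-variance fractions are reported over all components
and sum to one.

PLS-DA regresses the centred/scaled spectra on a 0/1 treatment coding
(aCO2 = 0, eCO2 = 1) with NIPALS partial least squares and classifies by
thresholding the continuous prediction at 0.5 — the standard dummy-coded
construction.  Tuning holds out a stratified 30% test split, scans 1..K
components (K ≤ 60) by stratified 10-fold cross-validation on the training
split only, selects the count with the highest mean CV accuracy (ties go
to the fewer-component model, matching a plain arg-max selection rule),
refits on the full training split and scores the untouched test split
once.  NIPALS components are nested, so the per-fold scan fits a single
K-component model and reads off all truncations from the leading
weight/loading vectors.  All randomness (split and folds) derives from one
seed.  Classifier evaluation reports the confusion matrix, exact
Clopper–Pearson 95% accuracy interval, sensitivity/specificity with eCO2
positive, the no-information rate with a one-sided exact binomial test of
accuracy above it, and an exact-binomial McNemar test on discordant
predictions.

Cumulative wavelength importance is defined as

    importance(λ) = Σ_k |w_λk| · v_k,   normalised to max = 1,

where w are the NIPALS X-weights and v_k is the fraction of class-code
variance explained by component k.  This particular weighting is a
declared package definition (several variants circulate under the same
name); the raw per-component weights are exposed so alternative
definitions can be computed.  Wavelengths dropped as zero-variance before
scaling reappear with importance zero.

## The campaign simulator

The simulator exists so every downstream stage is exercisable and
statistically testable without any external download.  It is a simplified
leaf optical stand-in, not a physical radiative-transfer (PROSPECT-class)
model:

    R(λ) = P(λ) · exp(−Σ_i c_i a_i(λ)) + ε(λ),  clipped to [0, 1]

with a smooth Gaussian-shaped plateau P (amplitude 0.46, centre 1060 nm,
width 630 nm, floor 2.5%), Gaussian absorption features per constituent
pool (chlorophyll at 390/430/620/680 nm, carotenoid at 490 nm, water at
1450/1940 nm, dry matter at 1720/2100/2300 nm), and white noise ε
(SD 0.004).  Feature centres and widths are fixed package constants chosen
so a mean leaf lands in realistic index brackets (NDVI ≈ 0.84,
MCARI ≈ 0.11, PRI and PSRI near zero, NDNI ≈ 0.1, integrated reflectance
≈ 425); they are documented here and not fitted to any external
coefficient library.

A campaign draws the study's hierarchy — 2 treatments × 2 arrays × 2 trees
per array × 4 dates × ~30 leaves — with independent Gaussian random
effects per pigment on the *log* concentrations (multiplicative biology;
guarantees positivity) at the tree (SD 0.077), tree-by-date (0.096) and
leaf (0.275) levels, and analogous effects on the log plateau amplitude
(0.02 / 0.044 / 0.139) that carry the broadband brightness variability.
These SDs were chosen once so the PSRI- and integrated-reflectance-scale
variance components land in the magnitude brackets a field campaign of
this design produces, with the leaf level dominant.  The default elevated-
CO2 treatment is a 1.28× carotenoid multiplier — expressing the raised
carotenoid:chlorophyll ratio that PSRI is sensitive to, worth about +0.024
PSRI — plus a 1.03× broadband brightening (~+3% integrated reflectance).
Setting `treatment_totals={"aCO2": 469, "eCO2": 463}` distributes realized
unbalanced totals round-robin over the tree × date cells.

Randomness is a splittable stream: the global seed spawns one substream
per tree, each tree spawns per-date substreams, each date cell spawns
per-leaf substreams.  Enlarging the design (more leaves, more dates) never
perturbs effects already drawn.

What the simulator does *not* emulate: wavelength-correlated instrument
noise, detector step artefacts, seasonal trends in pigments (dates differ
only through random effects, so the simulator has no phenology), covarying
pigment pools, or the true shape of oak reflectance beyond the qualitative
features above.  Tests passing on simulated campaigns therefore validate
the *statistical machinery* — estimator correctness, calibration of the
treatment test, CI coverage, classifier evaluation — not the biological
realism of any particular spectrum.

## Calibration properties enforced by the test suite

Three simulation-level properties are asserted, all at fixed seeds:

* **Null calibration** — with no injected treatment effect, the PSRI
  treatment test rejects at 5% nominal level within the central 99%
  binomial band over 200 replicates.
* **Coverage** — the 95% Satterthwaite CI for the PSRI effect covers the
  generative effect (computed by independent Monte Carlo over the
  generative equations) in ≥ 90% of 100 replicates.
* **Variance recovery** — averaged over 50 replicates, estimated PSRI-scale
  variance components sit within 50% of delta-method predictions from the
  injected log-scale SDs.

Replicated checks use 10 leaves per tree × date cell (320 spectra per
replicate): the hierarchy — and hence the df, the calibration and the
coverage behaviour — is identical to the full design, while a replicate
fits in well under a second.

## Known limitations

* Only the two-treatment, nested two-intercept (plus optional array)
  model family is supported — no crossed random effects, random slopes or
  general formulas.
* The Satterthwaite information matrix is obtained by finite differences;
  for responses whose variance-component surface is extremely flat the df
  carries ~1e-2 relative noise (the fallback on a singular information
  matrix is a normal approximation, with a warning).
* PLS-DA is strictly two-class.
* The simulator's dates carry no systematic seasonal signal, so
  time-series displays of simulated campaigns are flat apart from random
  tree-by-date effects.
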