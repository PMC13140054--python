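# Methods

## The section model and its synthetic emulation

A stem cross-section is modelled as an axis-aligned ellipse (semi-axes
`a ≥ b`, long axis horizontal) partitioned into three concentric zones of
constant normal thickness: a thin dense epidermis (EZ), a bundle-rich
periphery (PZ) and an inner zone (IZ). Zones are *offset bands* — the set of
points within a given Euclidean depth of the stem boundary — not shrunken
ellipses; the inward offset of an ellipse is not an ellipse, and using
depth bands keeps the simulator's ground truth and the segmenter's zone
partition (both computed from the distance transform) mutually consistent.
Analytic zone areas use the convex inward-offset identity
`A(t) = A − P·t + πt²`, valid while `t` is below the minimum radius of
curvature `b²/a`.

Vascular bundles are non-overlapping bright disks placed by bounded
rejection sampling. A disk is accepted when it lies entirely inside its
zone's depth band with a 50 µm margin and clears every placed disk by a
configurable edge-to-edge separation (default 150 µm). The rendered image
is 8-bit: background 20, ground tissue 100, epidermis 235, bundles 200,
followed by Gaussian blur (σ = 1 px) and additive Gaussian noise (σ = 6
grey levels). A contrast-inversion flag is provided.

Default scale emulates basal-internode stem CT: 15 µm/px, a 1,200 px field,
semi-axes 8.4 × 7.4 mm (a ~17 mm stem; a literal 9 mm semi-axis would touch
the border of a 1,200 px frame at this resolution), epidermis 0.24 mm,
periphery 2.0 mm, 140 periphery bundles (lognormal radius, median 150 µm,
log-σ 0.12) and 60 larger inner-zone bundles (median 260 µm). No published
spatial statistics exist for bundle layout at this scale, so these defaults
are scale-plausible choices, fixed once: they give a bundle area fraction
of ~12% of the section, several-fold larger inner-zone bundles than
periphery ones, and realistic crowding without contact.

What the simulator deliberately does **not** emulate: CT reconstruction
physics (ring artefacts, beam hardening), elliptic distortion of bundles,
the pith cavity, node anatomy, or 3-D continuity between slices. Passing
the synthetic recovery tests therefore demonstrates the correctness of the
geometry → traits machinery and the detector's behaviour under blur/noise,
not performance on real tissue with touching or irregular bundles.

## Segmentation

1. **Stem**: global Otsu threshold, morphological closing (disk r = 3 px),
   hole filling, largest connected component; components below 1 mm² raise
   an error.
2. **Zones**: Euclidean-depth thresholds at the configured EZ and PZ
   thicknesses (defaults 0.24 / 2.0 mm, rounded to pixels). The three bands
   tile the stem exactly; an empty IZ is a hard error. An optional adaptive
   mode re-derives the PZ/IZ boundary from the detected bundles instead:
   bundles are binned by stem depth and the boundary is placed where the
   radial profile of mean bundle area first crosses the section-wide median
   (periphery bundles are small, inner ones large). Its resolution is one
   depth bin (~10–15% here), so the fixed-thickness default remains the
   reference.
3. **Bundle candidates**: the image is flattened by subtracting a
   large-window median background (disk radius 600 µm — larger than any
   bundle diameter), Gaussian-smoothed (σ = 1 px) and restricted to the
   stem interior beyond a 250 µm rim: the epidermis carries no bundles by
   definition and its dense ring would otherwise shed watershed fragments.
   Foreground is thresholded at the in-stem median plus half of the robust
   bundle amplitude (99th percentile − median of corrected intensities);
   the half-amplitude contour of a blurred disk closely tracks the original
   disk boundary, which keeps detected areas unbiased. Markers come from
   h-maxima at an adaptive depth `h = 3.0 × 1.4826 × MAD` of in-stem
   smoothed intensities — deep enough that sensor noise cannot split one
   bundle plateau into several markers, shallow relative to the bundle
   amplitude so no bundle is missed — and a marker-controlled watershed
   floods the foreground. Labels are renumbered in raster-scan order so
   output is deterministic.
4. **Filter**: candidates are accepted when area ∈ [0.005, 1.5] mm²,
   solidity ≥ 0.70, eccentricity ≤ 0.97 and mean intensity is at or above
   the in-stem median; rejected rows are kept with the first failing
   reason. Accepted bundles take the zone label under their area-weighted
   centroid; an EZ centroid is reassigned to PZ (and logged), a background
   centroid is an error.

The candidate detector is classical by construction; it exposes the same
candidate-raster/bundle-table interface a learned semantic-segmentation
front-end would, so one can be substituted without touching downstream
code.

## Traits

The 32-trait registry fixes names, column order and units (mm, mm², mm⁻²,
mm⁴). Conventions that were genuinely open and the choices made:

- **Neutral axis for MOA** — default is the horizontal image axis through
  the section centroid (a bending rig loads the section vertically);
  configurable to the long or short principal axis. With the long axis
  chosen, MOA coincides with MOIAL, which is why the image-horizontal
  default is kept: it preserves MOA and MOIAL as distinct descriptors.
- **Point-mass convention** — bundles enter MOA/PMOI/MOIAL/MOIAS as
  (area, centroid) pairs; `ave*` traits divide by the bundle count VB_N
  (consistent with `VB_Aave` naming). With no bundles the `ave*` traits are
  emitted as missing values, never zero.
- **Zone thickness** — EZ_T and PZ_T are mean stem-depths of the zone
  interfaces, averaging boundary pixels on both sides of each interface
  (unbiased to ~half a pixel); IZ_T is the inradius of the inner zone (the
  maximum of its distance transform). An area/perimeter-based alternative
  was rejected because it degrades for non-circular sections.
- **Densities and ratios** — VB_D is count per *section* area; per-zone
  densities and area ratios (PZ_VB_D, PZ_VB_AreaRatio, …) are normalised by
  their own zone's area, so each ratio is a tissue fraction in [0, 1].
- Principal axes and axis lengths come from the stem mask's second central
  moments with the filled-ellipse normalisation (+1/12 px² per axis for the
  pixel footprint); the perimeter is Crofton's 4-direction estimate.

Every computed vector passes through an invariant validator (zone-area
conservation, count/area additivity, ratio bounds, `PMOI = MOIAL + MOIAS`
to 1e-9 relative, `ave`-trait consistency). Slice-to-sample aggregation is
the per-trait median (robust to occasional bad slices), with mean/SD/count
carried alongside.

## Bending

`BMMax = F_max·L/4` with the global maximum load (no failure detection —
instrument records here end at or shortly after failure);
`BM10mm = F(10 mm)·L/4` with the load at 10 mm obtained by linear
interpolation between the bracketing samples (instrument exports are dense;
higher-order fits add nothing). Spans are accepted in cm or m and
normalised to m; truncated curves raise an explicit "displacement not
reached" error. The elastic modulus is out of scope: it is read directly
from instrument software rather than derived from the curve.

## Variance components, BLUP, heritability

The multi-environment model is
`Y_ikm = μ + g_i + τ_k + (gτ)_ik + δ_(k)m + ε_ikm` with independent normal
random effects. REML is maximised over log-variances (which enforces
non-negativity; estimates at the lower bound are projected to zero) using
the mixed-model-equations form of the restricted likelihood,
`−2ℓ_R = n·log σe² + Σ q_j log σ_j² + log|C| + y'Py`, evaluated by Cholesky
factorisation of the coefficient matrix (L-BFGS-B, with a bounded Powell
polish when a boundary solution breaks the line search). On balanced data
the REML optimum coincides with the closed-form ANOVA
(expected-mean-squares) estimator whenever that estimator is inside the
parameter space; the ANOVA closed form is implemented independently and
used as the oracle in tests, alongside an lme4 cross-check run through
Rscript on a small fixture.

Genotype is random by default (true BLUP, shrunken line deviations summing
to ~0 on balanced data); a BLUE mode refits with genotype fixed for users
who want unshrunken line means — the two conventions coexist in practice
and both are exposed. Missing cells are dropped with a logged count, never
imputed; a single-environment table is rejected with a pointer to a
reduced model, since V_GL is then inestimable.

Heritability is the line-mean form `H² = Vg/(Vg + V_GL/L + Ve/(L·R))`,
which is scale-invariant and bounded in [0, 1] for non-negative components.

## Prediction protocol

Feature sets: all 32 traits; stem-related (5); vascular-bundle-related
(21 = 5 whole-section + 4 PZ + 4 IZ + 8 mechanics); zone-related (6); and
the top-five subset {VB_A, PZ_VB_A, PZ_T, PZ_A, MOA}. RFE eliminates one
feature per round under a ridge base estimator (|coefficient| on
standardised inputs; a random-forest importance mode is available).
Models: Ridge, ordinary least squares, random forest (100 trees, depth 10),
AdaBoost, RBF-SVR (C = 10) and a one-hidden-layer (64-unit) network; linear,
kernel and network models are wrapped with feature standardisation.
Scoring uses fivefold cross-validation with a fixed, recorded seed
(default 2021): RMSE and Ezekiel-adjusted R²
(`1 − (1 − R²)(n − 1)/(n − p − 1)`) per fold and pooled over out-of-fold
predictions, plus the out-of-fold Pearson correlation, since "precision"
summaries in this literature are sometimes correlations. Feature sets are
ranked by pooled adjusted R², with paired fold-wise RMSE differences and an
exact sign-flip significance summary against the best set.

The planted-signal benchmark draws 32 i.i.d. standard-normal traits and a
target carried by the top-five subset at a 70% explainable-variance level,
n = 400 — large enough that the cross-validated adjusted R² of a correct
model sits near the planted fraction, small enough to run in seconds.

## Problem sizes and numerical choices

The verification corpus is 20 full-scale synthetic sections (fixed seeds);
heritability recovery uses 100 simulated trials of 200 lines × 2
environments × 3 replicates; the prediction benchmark uses 20 seeds of
n = 400. REML convergence is declared at relative log-likelihood precision
~1e-13 in the optimiser; moment identities are asserted at 1e-9
(perpendicular-axis) and 1e-12 (against an explicit-loop oracle); image-
derived traits are verified within 5% of analytic truth (7% for moments,
which compound area and centroid errors).

## Known limitations

- The detector assumes bright, roughly convex, non-touching bundles; real
  sections with merged bundles or strong ring artefacts will need the
  filter thresholds (all exposed in `SegConfig`) retuned or a learned
  front-end slotted in.
- Zone thicknesses are fixed-parameter bands; biological sections have a
  gradual PZ/IZ transition that a fixed 2.0 mm boundary only approximates.
- The REML implementation targets the five-component crossed design above;
  it is not a general mixed-model engine (no kinship matrices, no
  heteroscedastic residuals).
- Trait tables aggregated by median assume ≥ 1 valid slice per sample and
  exchangeable slices along the internode.
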