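# Methods

## The phantom's motion model

Each short-axis slice is an annulus (endo 20 mm, epi 30 mm at end-diastole
by default) whose deformation is prescribed analytically so that exact
ground truth is available for every downstream metric — no biomechanics is
simulated.

The local midwall shortening fraction is

    s(θ, t) = a(θ) · p(t − d(θ))  (+ optional post-systolic term)

where `a(θ)` and `d(θ)` are the six per-sector peak amplitudes (%) and
delays (ms) as piecewise-constant profiles blended with a smoothstep over
±4° at sector boundaries (the motion must be continuous in angle), and
`p(τ)` is a raised-cosine pulse `½(1 − cos(πτ/t_AVC))` supported on
`[0, 2·t_AVC]`, so an undelayed sector peaks exactly at aortic-valve
closure and a delayed sector traces the *same* curve shifted in time.
Sectors inside the necrosis arc can receive an extra pulse of amplitude
`post_systolic_fraction · a(θ)` lagged by 90 ms — post-systolic shortening
without modelling electrophysiology.

Deformation splits into a uniform radial part and a tangential remap:

* radius: `R² = r² − r_m² + R_m²` with `R_m = r_m (1 − s̄(t))`, `s̄` the
  circumferential mean of `s`; annulus area is conserved *exactly* and the
  wall thickens as the cavity shrinks (EF ≈ 43% at 15% uniform csh);
* angle: `dφ/dθ = (1 − s(θ,t)) / (1 − s̄(t))`, zero-mean offset, so the
  *local* material arc element shortens by exactly `s(θ, t)`.

Both maps have closed-form (radius) or tabulated monotone (angle) inverses,
which lets the tag renderer pull every deformed pixel back to its reference
position exactly.  Sector csh of a material 60° sector is then the sector
mean of `s` up to the ±4° blending (≤ 0.25 percentage points for a
10-point amplitude contrast), and the dense polyline integration in
`ground_truth_csh` verifies this numerically rather than assuming it.

Frame 0 is always the undeformed reference; displacement at frame 0 is
identically zero.

## Tag and tissue rendering

Tags are 1-1 SPAMM: intensity `baseline · ½(1 + cos(2π e·X / tag_spacing))`
inside the deformed myocardium, where `X` is the reference-frame position
of the material point and `e` one of two orthonormal tag normals (7 mm tag
spacing, 1 mm pixels, 108² matrix by default).  Background is zero.  Noise
is Gaussian on the magnitude image (not Rician); at the SNR used (≥ 20)
the difference is negligible, and this is a documented limitation.  Tag
fading is off by default (complementary SPAMM suppresses it) but a linear
fading factor is available for robustness experiments.

T2w (3 slices: basal, midventricular, apical) and LGE (full stack) images
are rendered at end-diastole with crisp transmural angular arcs: edema
207° (57.5 %circ) enclosing necrosis 108° (30 %circ, and 30 %LV mass by the
annular-sector area ratio) by default, remote myocardium at mean 100 with
5 units of intra-tissue texture plus acquisition noise.  A 60°-wide remote
ROI sits diametrically opposite the edema centre and is validated to be
disjoint from both lesion arcs.

## HARP tracking

The first tag harmonic is isolated with a circularly symmetric raised-
cosine band-pass of radius `0.4 / tag_spacing` centred on the harmonic
peak (DC leakage < 1% by construction; the filter may not reach DC).
Landmarks are tracked frame-to-frame — inter-frame motion stays well below
half a tag period, which avoids phase jumping — by Newton iteration on the
two wrapped phase differences, with wrapped central-difference gradients,
a 0.01-pixel convergence step, at most 20 iterations, and bilinear
interpolation of the *complex* harmonic images (interpolating wrapped
phase directly is invalid).  All phase arithmetic is routed through a
single wrap-to-(−π, π] utility.  A point whose harmonic magnitude falls
below 5% of the slice maximum is a signal void; a step exceeding one tag
period is a divergence.  Failed landmarks are interpolated circularly from
their angular neighbours and flagged; more than 25% failures in a frame
rejects the whole track.  There is no manual correction step.

Midwall contours start at the midpoint of the endo/epi ray crossings from
the cavity centroid, 72 landmarks at 5°.  On noise-free phantoms the
tracked sector csh agrees with the analytic ground truth to < 1 percentage
point RMS over all sectors and frames (≈ 0.4 at uniform 15% shortening);
the residual is dominated by the finite band-pass, which slightly smooths
the deformation at peak contraction.

## Strain metrics

csh is the arc-length change of the landmarks in each 60° sector (the
closing segment to the next sector's first landmark is included so the six
arcs tile the circumference), relative to end-diastole, shortening
positive.  T_max takes the earliest frame on ties (determinism); segments
peaking in frames {0, 1, 2} or the last frame are flagged automatically —
the stand-in for observer inspection — and excluded from the T_max
mean/SD but not from CURE or CV_csh.  CV_csh requires |mean csh at AVC|
above 0.5% (below that the ratio is meaningless).

CURE uses the one-sided first-harmonic power `A1 = |c_1|²` by default;
the two-sided convention (`+ |c_{-1}|²`) is available via
`harmonic_convention="two_sided"`.  Both satisfy the analytic extremes
(uniform → 1, zero-mean first harmonic → 0) and all invariances (sector
rotation, positive scaling, slice duplication); they differ only in how
far intermediate fields sit from 1.  Temporal summation defaults to frames
1..AVC (systole anchors the other end-systolic indices) and is
configurable to any frame range.

## Tissue quantification

Intensity profiles are sampled along the mid-myocardial centreline (1°
steps at bin centres, bilinear interpolation) — the centreline avoids the
subendocardial region where stagnant-blood signal confounds T2w.  Extent
is the fraction of samples above `remote mean + k·SD`, averaged over the
three slices (pooling is available; the two coincide for equal sample
counts).  k = 2 for T2w edema; for LGE the automated default is k = 5,
standard practice for bright infarct cores when no observer corrects the
result.  No contiguity is imposed on supra-threshold samples.  On
noise-free phantoms the extents equal arc/360 up to at most one or two 1°
samples per arc boundary, where bilinear sampling blends across the crisp
edge; at SNR 20 with k = 2, noise false-positives add ≈ 1 point — both
well inside the 2-point recovery band the tests enforce.

Necrosis mass is the supra-threshold fraction of all myocardial pixels
over the full stack (uniform pixel volume, so pixel ratio = mass ratio);
a transmural 108° sector gives 30.0% by annulus symmetry.  Salvage is
edema − necrosis (%circ), clipped at zero with a warning if noise inverts
the nesting.  LV volumes use disc summation (area × (thickness + gap)),
EF = 100·(EDV − ESV)/EDV, and mass = myocardial volume × 1.05 g/ml (the
standard CMR density convention).

## Cohort generator

The measure-level generator draws, per subject: edema extent
N(57.5, 14²) %circ; the necrotic fraction of the edema territory
N(0.53, 0.17²); necrosis mass linearly linked to necrosis extent
(slope 0.6, noise SD 6); acute CURE by a negative linear link on edema
extent calibrated so the explained variance is ≈ 0.63 and the marginal
distribution is ≈ 0.91 ± 0.05; follow-up CURE as
`0.94 + 0.35·(CURE_acute − 0.91) + 0.0008·(necrosis − 30.6) + ε`,
ε ~ N(0, 0.02²) — dyssynchrony regresses more in ventricles with larger
necrosis, with marginal ≈ 0.94 ± 0.03; LV volumes/EF/mass from their
Gaussian marginals with ESV derived from EDV and EF.  All draws are
clipped to valid ranges and reproducible from a single seed.  Salvage is
definitionally edema − necrosis.  The exact link function is a modelling
choice: only its explained variance and the marginal moments are
constrained by the emulated study design.

The image-level fidelity (`subject_config_from_measures`) sizes the
phantom arcs from the drawn extents and makes sectors hypokinetic/delayed
in proportion to their necrosis overlap, so full image pipelines can be
run per subject when needed; it is much slower and not the default.

What the phantom does *not* emulate — and what passing tests therefore do
not show about patient data: through-plane motion and true 3D tag
geometry, Rician noise, receive-coil shading, tag fading (off by default),
breathing/misregistration between series, microvascular obstruction on
LGE, and anatomical variation between slices (all phantom slices share
one geometry).

## Statistics

Pearson correlation with the two-sided t-transform p-value and the
least-squares line; paired t / Wilcoxon and two-sample t / Mann-Whitney
with automatic selection by a Kolmogorov–Smirnov normality check
(p < 0.05 → nonparametric; the KS statistic uses estimated moments, which
is anti-conservative, but mirrors the emulated workflow).  Zero-variance
paired differences are reported as degenerate rather than erroring:
identical arms give statistic 0, p = 1.  The sample-size routine is the
two-group normal approximation `n/group = ceil(2((z_{1−α/2}+z_{pow})·σ/δ)²)`
returning the two-group total (δ = 0.04, σ = 0.03, α = 0.05, power 80% →
9 per group, 18 total).  No multiple-testing correction is applied.

## Numerical choices and problem sizes

* Angle remap tabulated at 1440 points, inverted by monotone
  interpolation; ground-truth arc lengths integrated at 3600 points.
* T_max tie-break: earliest frame.  Extent sampling: 360 bins at bin
  centres.  Remote ROI minimum: 20 pixels.
* Default problem sizes keep every stage desk-scale: 108² pixels,
  9 slices, 20 frames, 72 landmarks — a full simulate→track→metrics→tissue
  run takes a few seconds, and the whole test suite (including HARP
  recovery on three phantoms and 5000-replicate statistical calibration)
  runs in well under a minute.
* Determinism: every random draw derives from the config/CLI seed through
  `numpy.random.default_rng` with fixed stream keys; identical config and
  seed reproduce bit-identical outputs, which the run manifest checks via
  content hashes (gzip members hashed decompressed).

## Known limitations

* Gaussian (not Rician) noise on magnitude images.
* The band-pass shape/radius of the emulated commercial HARP tool is not
  public; 0.4/tag_spacing raised-cosine is a defensible default, not a
  reproduction.
* Landmark-based csh slightly underestimates peak shortening (< 1
  percentage point at 15% csh) through harmonic band-limiting.
* The edema→CURE link in the cohort generator is a calibrated modelling
  choice; only its moments are meaningful.
* No automatic myocardial segmentation: masks come from the phantom or
  the user.
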