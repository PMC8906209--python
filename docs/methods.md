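# Methods

This note documents the models, conventions and numerical choices behind
`duomlc`, what the synthetic generators do and do not emulate, and the
design decisions taken where the problem left them open.

## Machine geometry and conventions

The collimator model is a stacked pair of leaf banks: 29 proximal and 28
distal pairs, each projecting 10 mm at the isocenter plane, both banks
centred on the axis so that the distal leaf boundaries sit half a pitch
(5 mm) off the proximal ones.  Leaf positions are signed millimetres along
the travel axis at isocenter; bank A tips approach from the negative side,
bank B from the positive side, and a pair's geometric gap is `x_B − x_A`.
Closed pairs are represented by `x_A = x_B` — there is no "parked"
sentinel.  Travel limits are ±140 mm, maximum leaf speed 50 mm/s.

Positions are kept exact in memory; the one rounding step happens on
serialization, where every position is rounded to the nearest 0.1 mm
(half-up, toward +∞).  This mirrors how a planning system stores plans and
is why assignable DLG values come in 0.2 mm steps: a DLG change is twice a
per-bank opening, and openings must land on the 0.1 mm grid.

On read, layers are identified by pair count (29 → proximal, 28 →
distal).  Files whose two layers carry equal pair counts are rejected as
ambiguous; for nonstandard but distinct counts the larger bank is taken as
proximal and contradicting labels are an error.

## Strip decomposition and trailing statistics

The staggered stack is analysed on 58 strips of 5 mm tiling the proximal
extent; 56 strips carry one pair of each layer, the two outermost only a
proximal pair.  Per strip and control point:

* effective gap `g = max(0, min(x_B^prox, x_B^dist) − max(x_A^prox,
  x_A^dist))` — the dosimetrically relevant intersection of the two
  layers' gaps (the clinical tables do not say per-layer vs effective;
  effective was chosen for that reason);
* per bank, trailing distance `t = |tip_prox − tip_dist|` and a defining
  layer — the one whose tip is innermost (larger on bank A, smaller on
  bank B); `t = 0` is a tie ("complete overlap").

Statistics pool (control point, strip) samples for gap percentiles and
(control point, strip, bank) samples for the five trailing classes
(proximal/distal defining × short/long trailing, plus overlap; the
short/long boundary is the 5 mm saturation distance).  Closed strips carry
no aperture information and are excluded.  Comparisons are made in integer
hundredths of a millimetre so float rounding can neither break a tie nor
move a distance across the class boundary.  The default weighting counts
every control point equally; MU weighting (meterset increment × beam MU)
is available, as no weighting rule is canonical for such tables.

## Sequence editing

**Single-layer conversion.**  The defining layer is untouched; each pair
of the other layer retracts to `min(defining bank-A tips) − r` and
`max(defining bank-B tips) + r` over the (up to two) defining pairs it
overlaps, with `r = 5` mm by default, clamped to travel.  The
max-extension rule guarantees the tracking layer never encroaches on the
defining aperture, so the per-strip effective aperture equals the defining
layer's wherever clamping does not bind, and every open edge lands in the
defining layer's saturated (`t ≥ 5` mm) trailing class.  Closed defining
pairs get tracking tips at the closed position ± r; the strip stays closed
(gap 0), so this choice does not affect statistics.  The operation is
idempotent for a fixed defining layer.

**Leaf opening.**  `x_A ← x_A − δ`, `x_B ← x_B + δ` on every pair of the
selected layers (clamped with a warning), with meterset weights and MU
unchanged — the edit emulates recalculating with a DLG of `base + 2δ`, not
a different delivery.  The default opens all pairs, matching the tuning
procedure's "all leaf positions"; an `open_only` mode skips pairs with gap
≤ 0.1 mm because opening parked pairs creates leakage slits.

**Sweeping gap.**  A gap of width `g` travels `L = 120` mm symmetrically
about the axis at constant speed: cumulative meterset weight is linear in
tip displacement, with one control point per 5 mm of travel plus the start
(25 for the default sweep) — a density choice, since any linear
interpolation of tips between control points reproduces the same dwell.
Pairs inside the 100 mm square field participate; others park closed at
−100 mm, off the detector region, so their tip slit cannot contaminate
axis readings.  The trailing variant sets the other layer's same-bank tips
outward by exactly `t` (pair gap `g + 2t`); without a trailing layer the
other layer is fully retracted.

## DLG fitting

The corrected ratio removes transmission accumulated while the chamber is
blocked, using dwell fractions of the sweep: dual-shielded dwell
`(L − g − 2t)+/L` at the dual transmission (default 5·10⁻⁵ — effectively
zero, as the stacked design transmits < 0.01 %), and single-shielded dwell
`min(2t, L−g)/L` (trailing case) or `(L − g)/L` (plain sweep) at the swept
layer's transmission.  Geometrically the single-shielded region between
the leading and trailing tips is covered by the *leading* layer's leaf, so
the caller passes that layer's transmission.  The correction is a plain
function and pluggable: a user with measured leakage fields can substitute
their own.

The fit is unweighted ordinary least squares of corrected ratio on gap
width; `DLG = intercept/slope`, positive DLG ⇔ positive y-intercept, and
negative values are legitimate (coincident tips behave like a mono-block
edge).  A non-positive slope cannot arise from physical sweep data and is
an error.  On collinear input the fit is exact to machine precision.

With 0.2 % *relative* reading noise on the 10-gap grid, the x-intercept
standard error is ≈ 0.015 mm, so the fitted DLG stays within 0.05 mm of
truth in well over 95 % of replicates.  (Note: noise of 0.2 % *of the
reference reading*, i.e. an absolute ratio s.d. of 0.002, would propagate
to a ≈ 0.17 mm intercept s.d. — no fitting procedure could hold 0.05 mm
under it.  Chamber repeatability is relative to the reading, and that is
the noise model the simulator uses.)

## Verification

Measured detector points are the reference; the calculated distribution is
evaluated (the usual array-QA convention).  Dose difference is
`100·(D_calc − D_meas)/max(D_meas)` (global normalization; negative mean ⇔
calculation underestimates), with statistics over points at or above the
low-dose threshold (10 % of the measured maximum by default).  The
threshold is stated for gamma in the QA protocol; applying it to DD as
well is this package's choice for consistency, and an unthresholded mode
is provided because array software differs on this point.

The global gamma index searches, per reference point, over evaluated
positions within `3 × DTA` of the point, sampling the evaluated grid by
multilinear interpolation on a sub-grid of spacing ≤ 0.2 mm (both
exposed parameters).  The search is exhaustive over that sub-grid — no
early termination heuristics — so on small problems it reproduces a
brute-force implementation bit-for-bit, at the cost of being O(points ×
offsets); it is vectorized and chunked to keep memory flat.  Points whose
search sphere is not fully covered by the evaluated grid are excluded with
a warning rather than silently truncated.  Local (per-point) dose
normalization is available behind a flag but untuned.

Pooled histograms concatenate per-point values across verifications (the
pooling unit is the point, not the plan) and bin on a grid aligned to
multiples of the bin width, so pooling order cannot change the table.

## Tuning

Mean DD responds linearly to the emulated DLG, so the empirical value is
the zero crossing of an OLS line through the whole (DLG, mean DD) grid —
not a piecewise interpolation — with R² reported as the linearity
diagnostic and an explicit flag when the crossing extrapolates beyond the
grid.  Pooling across plans is an unweighted mean of per-plan mean DDs;
per-class and per-layer pools are all computed, since a planning system
that cannot assign per-layer values still benefits from seeing them.
Assignment rounds to the nearest `base + 0.2k` (ties upward, never below
the base), and the per-bank opening is `(assigned − base)/2`.

## Synthetic data: what it emulates, and what a green test establishes

**Tip model.**  The effective DLG of a bank edge is piecewise linear in
that bank's trailing distance: `dlg(t) = dlg_mono + (dlg_single −
dlg_mono)·min(t, 5)/5`.  Only the endpoints and the "sharp drop below
5 mm" are physically established; the exact shape between 0 and 5 mm is
not, which is why the function is pluggable.  Two stated models ship:

* `default_tip_model()` — sweep-bench magnitudes (0.42 / 0.32 mm per
  layer, −0.47 mm at `t = 0`), used for the sweeping-gap and
  trailing-curve emulation;
* `study_tip_model()` — plan-level truths of 0.97 / 0.87 mm per layer with
  a shallow drop (0.75 mm at `t = 0`).  A clinical machine's plan-level
  effective DLG is substantially larger than its sweep value (unmodelled
  tongue-and-groove, penumbra and small-field effects fold into it), and
  at the plan level the trailing dependence is empirically mild — dual-
  and single-layer sequences verify within a couple of tenths of a
  percent.  The shallow-drop value 0.75 mm was fixed analytically from
  that band (a plan-level dual-vs-single difference of ≈ −0.1 %) before
  any acceptance run.  Noteworthy: with the *bench* model and realistic
  trailing statistics, the trailing-averaged plan-level DLG lands at
  ≈ 0.1 mm — numerically indistinguishable from the planning default — so
  a tuning study under that model has no mismatch to correct.  That is a
  real property of the model family, not a bug, and it is why the study
  uses the plan-level model.

**Dose engine.**  A 2D fluence model at the isocenter plane: per control
point and strip, the open interval is the effective aperture with each
bank edge pushed outward by `dlg_eff/2` (trailing-dependent in "measured"
mode, the constant `dlg_calc` in "tps" mode — the latter deliberately
reproducing a planning system blind to leaf trailing); blocked regions
contribute single- or dual-layer transmission; negative-DLG slivers inside
the geometric gap are charged single-layer transmission.  The open
interval is rasterized by exact area-weighted cell coverage, so the
fluence integral is *exactly* linear in the DLG — sub-grid shifts of
0.1 mm matter, and hard-mask rasterization would quantize them away.
Control points are accumulated with midpoint meterset increments, blurred
once with a 2 mm Gaussian penumbra (blur is linear, so blurring the sum is
exact), scaled by 0.003 Gy/MU, and given a mild Gaussian axial falloff
(σ = 150 mm) so the sagittal detector plane is not flat.  Measured mode
adds seeded Gaussian noise (0.5 % of the maximum dose in the study —
typical array repeatability).

Not emulated: depth dose, beam divergence, phantom density, heterogeneity,
tongue-and-groove, output drift.  Every quantity the pipeline extracts is
a *difference* between two engine runs, which is what makes these
omissions tolerable: a green end-to-end test establishes that the analysis
chain (editing → engine → verification → tuning) recovers the parameters
of the engine's own world, not that the engine predicts a real machine.

**Plan generator.**  Per arc, a smooth per-pair aperture program —
lognormal widths whose median equals the clinical per-class gap median
(17.5 mm small targets, 33.5 mm large; spread set from the clinical
interquartile ratios, σ ≈ 0.65) and smoothly varying centres — defines the
effective aperture.  Per distal pair and bank, a defining-layer
configuration is drawn from a spatially correlated mixture calibrated to
the clinical trailing-class proportions; trailing tips sit outward of the
defining edge by a drawn offset (uniform 0–5 or 5–20 mm), and proximal
pairs retract only inside runs of distal-defining configurations, where no
neighbouring strip needs them at the edge.  Shared tips couple adjacent
strips, so realized class percentages resemble, rather than reproduce, the
drawn mixture — the calibration target under test is the gap median
(±20 %) and the partition property, not the class table.  All positions
are generated on the 0.1 mm grid, making serialization round-trips
bit-exact, and all randomness flows through one seeded generator.

**Detector.**  Two orthogonal planes through the isocenter with 5 mm
spacing in the central 60 mm and 10 mm outside (vendor-typical for
biplanar diode arrays, not a calibrated layout); the sagittal plane omits
the shared intersection line.  The study samples a denser (2–3 mm central)
layout to keep per-plan point counts near clinical practice at desk scale.

## Study defaults and runtime

The default study is a desk-scale cohort: 4 small + 2 large three-arc
plans at 60 control points per arc, DLG grid {0.1, 0.5, 0.9, 1.3} mm
(per-bank openings 0/0.2/0.4/0.6 mm), 2 %/2 mm gamma with 10 % threshold,
and the small-target assigned DLG applied in the final pass (reported
per-class values let a user choose otherwise).  It runs in ≈ 40 s on one
CPU.  Scaling down from a clinical cohort (dozens of plans, ~180 control
points/arc) leaves the recovered quantities unchanged because every
estimator in the chain is a mean or a regression whose bias does not
depend on cohort size, only its variance.

## Known limitations

* The engine's per-class tuning results coincide (both classes share one
  true tip model); the clinical observation that large-target tuning
  yields larger empirical DLGs arises from physics the engine deliberately
  lacks.
* Gamma cost grows with the offset count; 3D comparisons at 0.2 mm
  sub-sampling are expensive and better run at 0.5 mm unless bit-exact
  agreement with a finer search is required.
* The generator's interquartile spread is somewhat narrower than clinical
  tables because smoothing and shared tips pull adjacent strips together;
  only the median is a calibration target.
* Delivery constraints (leaf speed vs gantry speed, interdigitation) are
  not checked; generated plans are geometric objects, not deliverable
  beams.
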