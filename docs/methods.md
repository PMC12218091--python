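# Methods

This note records the models, parameter choices and numerical decisions
behind `flagkin`, and what the synthetic tests do and do not demonstrate
about real recordings.

## Beat model and generator

Planar beats are generated directly in the tangent-angle representation,

ψ(s, t) = A(s) · g(t) · sin(2π(f·t − s/λ) + φ₀ + J(t)),

with arc length s (µm), beat frequency f (Hz, default band 3–7), wavelength
λ (default 110 µm) and a non-negative amplitude envelope A(s) in radians.
J(t) is an optional Brownian phase walk (rad/√s) and g(t) an optional
Ornstein–Uhlenbeck amplitude modulation (relaxation time of one beat
period); both default to zero and model irregular beating.  Positions are
built by stepping segments of length ds along the midpoint tangent with the
head clamped at the origin, so every frame's polyline length equals the
total length (default 110 µm) exactly — the inextensibility invariant is
structural, not numerical.

The default envelope family is A(s) = c·(1 − e^(−s/τ))·[µ + (1 − µ)·σ((s −
35)/2)] with c = 1.45 rad, τ = 10 µm and a logistic gate σ.  The single
weight µ ∈ [0, 1] scales the midpiece: µ = 1 is a fully flexible cell,
small µ reproduces a stiffened midpiece whose distal tail still beats.  Two
constants were fixed by feasibility, not fitting: c stays below π/2 so the
tangent never turns past 90° and the cell cannot self-cross (which would
break skeleton tracing), and λ = 110 µm ≈ tail length because shorter
wavelengths dephase the midpiece enough that sweeps near the top of the
highly-flexible range (≈ 39–42 µm) become unreachable for any admissible
envelope.  The envelope vanishes at the head junction, so the tether pin
does no work on the filament — this is what closes the cycle-averaged
energy balance (below).

Rendering deposits sub-pixel samples of the centerline into the pixel grid,
blurs with a Gaussian PSF (default σ = 0.6 µm at 0.33 µm/px), and adds
Poisson shot noise on (background + ridge) plus Gaussian read noise — the
usual sCMOS model.  "SNR" throughout means ridge crest signal over total
noise rms at the crest; `OpticsParams.for_snr` solves the ridge peak for a
requested SNR (≈ 164 counts over a 100-count background at SNR 10).

## Amplitude definition

The amplitude of a tail section is defined as the **full peak-to-peak
transverse sweep of the section's distal set point**: the transverse
coordinate (perpendicular to the cell axis, the time-averaged tangent of
the head-adjacent 6.3 µm) of the material point at the section's distal
boundary (6.3, 28.7, 108.7 µm), max-over-time minus min-over-time,
interpolated in arc length.  Three considerations force this reading:

1. For a head-tethered cell, a material point at arc length s can never be
   farther than s from the anchor, so any *half* peak-to-peak measure is
   bounded by 28.7 µm at the distal midpiece boundary — yet observed
   midpiece amplitudes of highly flexible cells extend to 39 µm.  Only the
   full sweep width (bounded by 2s) can represent the upper categories.
2. Within the proximal half wavelength the sweep grows monotonically with
   arc length, so the midpiece set point is also the midpiece's widest
   excursion.  (Along the distal tail, phase mixing means the tip need not
   sweep widest; there the set point is simply the convention.)
3. Interpolating at the set point (rather than taking the maximum over grid
   stations) makes the read-out independent of where the resampling grid
   happens to fall, which keeps the generator's target solver and the
   traced measurement in agreement to ≈ 0.1 µm.

Under this definition a rigid transverse oscillation y = Y·sin(ωt) has
amplitude 2Y in every section.

## Flexibility classification and populations

Classifier bins are contiguous half-open intervals [0, 6), [6, 16),
[16, 27), [27, ∞) µm (highly stiff → highly flexible); the small gaps in
the conventional printed ranges (15→16 µm, below 0.6 µm) are treated as
rounding so that every amplitude classifies.  The population sampler draws
a category from mixture weights, a target amplitude uniformly from the
category's printed range (0.6–6, 6–15, 16–27, 27–39 µm), then bisects µ so
the ground-truth midpiece amplitude hits the target within 2% *and* inside
the category interval — sampled cells therefore land in their category with
certainty, and misclassification downstream can come only from imaging and
tracing noise.  The solver evaluates its metric on the same frame grid the
analysis will use, so finite temporal sampling of the sweep peak cancels
between generator and analyzer.

## Centerline tracing

Per frame: Otsu (or fixed) threshold → fill pinholes → remove small objects
→ require exactly one connected component → skeletonize → extract the
longest geodesic path through the 8-connected skeleton graph (two Dijkstra
passes; immune to corner-pixel junction artifacts) → orient the endpoint
nearest the tether anchor first → smoothing-spline fit → re-center each
point on the intensity ridge along its local normal → extend the distal
tip along the end tangent to the 50%-intensity crossing (the true endpoint
of a blurred line) → clamp arc length zero to the known tether point →
final spline and uniform resampling at ds = 1 µm up to 100 µm.  Off-path
skeleton residue longer than 3 µm (branches, self-crossings) fails the
frame; a recording is rejected when fewer than 80% of frames trace.  At
crest SNR 10 the round-trip tangent-angle error against ground truth is
≈ 0.02–0.03 rad rms and the set-point amplitude bias ≈ −0.3 µm.

The tangent-angle field is the finite-difference tangent direction,
unwrapped along arc length per frame and aligned across frames by 2π
multiples of the head angle.

## Kinematics

Curvature is ∂ψ/∂s by central differences (one-sided at the ends), with
optional Gaussian smoothing in s.  Beat frequency counts curvature turning
points (alternating extrema, prominence ≥ 10% of the station's range after
Savitzky–Golay smoothing) at 50% and 75% of the analyzed length; N turning
points spanning Δt seconds give f = (N − 1)/(2Δt) — consecutive turning
points are half a period apart, and normalizing by the span between the
first and last avoids the upward bias of dividing the raw count by the
record length.  The smoothing window default is 11 frames: at 250 fps a
5-frame window demonstrably lets 20%-amplitude noise through as spurious
extrema (a 4 Hz tone then reads ≈ 9 Hz), while the count is flat for
windows of 11–25 frames.

## Energetics

Quasi-static resistive-force theory: drag density f_h = −(ξ_t v_t t̂ +
ξ_n v_n n̂) with material velocities from central time differences.  With a
free distal end, the internal contact force and moment follow by
integrating the drag from the tip; the active (dynein) moment is the
remainder after subtracting the elastic moment EIκ and the internal
friction contribution η_i·κ̇:

m_a = M − EI·κ + η_i·κ̇.

The sign of the friction term is fixed by energy conservation: under the
moment convention used here the deformation power ∫M·κ̇ ds equals +D_h
(verified numerically against −∫f_h·v ds), and the cycle-averaged motor
power ⟨P_in⟩ − ⟨D_m⟩ must equal ⟨D_i⟩ + ⟨D_h⟩; the opposite friction sign
would instead yield ⟨D_h⟩ − ⟨D_i⟩.  The local motor power density
π = m_a·∂κ/∂t is split by sign: P_in = ∫max(π, 0) ds (motors drive
sliding), D_m = ∫max(−π, 0) ds (sliding drives motors).  D_i = ∫η_i κ̇² ds;
D_h = ∫(ξ_t v_t² + ξ_n v_n²) ds, with a segment-midpoint partition into
head/midpiece/principal windows so the regional values sum to the total
exactly.  Cycle averages truncate the record to the largest whole number of
beat periods it contains (partial cycles bias oscillating quantities) and
convert W → fW.

Material defaults are literature-scale placeholders (EI = 2×10⁻²¹ N·m²,
η_i = 10⁻²² N·m²·s, ξ_t = 0.7×10⁻³ N·s/m², ξ_n = 2ξ_t, interfilament
spacing 1.85×10⁻⁷ m), exposed in config.  Absolute fW outputs scale with
these parameters; with the defaults, study-band beats give cycle-averaged
motor inputs of order 30–180 fW, so only contrasts, scalings (D_h ∝
amplitude², ∝ f²) and the energy balance are meaningful, not absolute
values.  The energy balance closes within ≈ 2% at 250 fps and ds = 1 µm on
generated beats; it is the module's primary correctness gate.

## Shape modes

The time-mean profile ψ̄(s) is subtracted and the centered (time ×
arclength) matrix factored by SVD; modes are orthonormal under the
ds-weighted inner product.  For a pure traveling wave, two modes carry
> 99% of the variance and the coefficients are sinusoids in quadrature.
Circularity whitens (B₁, B₂) to unit variance and reports 1 minus the
coefficient of variation of the orbit radius, clipped to [0, 1];
coefficients that are collinear (|r| > 0.98) or have zero variance are
degenerate.  The score is a package definition — the circle/irregular
contrast it quantifies is qualitative in origin.

## Statistics

Cells are technical replicates: every group comparison first averages the
quantity within animal, then applies an unpaired two-sample Student t-test
(equal variance; Welch behind a flag) across animals.  Animals with no
valid cell value are excluded with a warning; fewer than two animals per
group is an error.

## Problem sizes and test strategy

Full study-scale recordings are 1000 frames at 250 fps.  Classification
only needs the amplitude sweep, which two beat cycles sampled at ~12 frames
per cycle capture (the generator's solver and the analyzer share the frame
grid, so the peak-sampling deficit cancels); population runs therefore use
fps = 48 and 0.5 s per cell.  The shipped acceptance script pushes 1000
cells per mixture through the full image pipeline; the test suite runs the
same machinery at 300 cells per mixture with tolerances at 3 binomial
standard errors for the n used.  Frequency and energetics tests use the
full 250 fps grid.

Passing tests show that the analysis chain is internally consistent and
recovers known ground truth through realistic imaging noise.  The generator
emulates planar, single-cell, tether-clamped beats with smooth envelopes
and stationary statistics; it does not emulate out-of-plane beating, head
occlusion, overlapping cells, debris, illumination drift, or envelope
shapes outside its family — accuracy on real recordings therefore must be
validated separately.

## Known limitations

* Planar (2-D) analysis only; out-of-plane motion projects into apparent
  amplitude changes.
* The amplitude definition (full sweep at section set points) is one of
  several defensible readings of "section amplitude"; comparisons across
  tools must check definitions.
* Energetics assumes local (resistive-force) hydrodynamics without wall
  effects — the slide proximity of a tethered assay is not modelled.
* The active-moment recovery inherits tracing noise through two spatial and
  one temporal derivative; the Savitzky–Golay window (default 5 frames for
  energetics) trades bias for variance and matters for traced (not
  generated) inputs.
* The frequency estimator assumes a single dominant beat; bi-harmonic or
  arrested beats report the dominant turning-point rate or fail with an
  explicit error.
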