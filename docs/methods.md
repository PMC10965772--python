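# Methods

## Geometry and coordinate conventions

The analysis plane is the transverse slice of the coelom at the electrode
belt. All geometry is in millimetres with x increasing from the subject's
right to left and y from ventral to dorsal. Pixel images follow radiological
display: row 0 is the dorsal-most row, column 0 the subject's right. All
physical computations (centre of ventilation, regional bands, shift
directions) use the y-up convention and convert for display only.

Contours are simple closed polygons, normalised to counter-clockwise
orientation. Resampling distributes n points equally by arc length, starting
where the ventral midline (the vertical through the centroid, below it)
crosses the contour, so homologous points line up across subjects. Mean
contours translate each centroid to a common origin before point-wise
averaging and place the result at the mean centroid; no rotation or scaling
is applied, because subjects are imaged in a fixed posture and absolute size
carries information. This alignment is a choice — nothing in the data fixes
it — and Procrustes-style scaling would distort the size differences the
mean model should retain.

The shipped chicken cross-section is a synthetic, parameterised stand-in
(elliptical outline of 90 × 80 mm, two dorsal lung lobes, a central-ventral
cardiac disc) for a CT segmentation that is not publicly available;
plausible for a ~1.9 kg hen, but not any individual bird.

## Mesh, electrodes and labels

The mesher combines boundary nodes (the 32 electrode positions, equidistant
in arc length and numbered counter-clockwise from the ventral midline, plus
subdivided inter-electrode arcs), an interior hexagonal grid at the target
element size, and resampled interior ROI rings, then Delaunay-triangulates
and keeps elements whose centroid lies inside the outer contour. Interior
ROI boundaries are therefore honoured approximately (through the inserted
ring nodes) rather than exactly; element labels come from centroid
containment, so the label partition is always exact and exhaustive.

The `airsac` label — needed only as simulation ground truth, never by the
reconstruction/analysis path, which uses the outer contour alone — covers
elements ventral of a band at the lungs' ventral-most extent, excluding the
cardiac region. The band (default 8 mm, configurable) represents the
non-ventilating tissue that lies between the lung face and the air-sac
spaces in this plane (mediastinum, tracheal bifurcation, oesophagus). It
also matters quantitatively: if ventilating elements sit flush against the
lung contour, no linear reconstruction can keep the lung ROI silent, because
the point-spread function of a 32-electrode difference image spans a few
pixels. With the band, the measured lung-ROI signal is ~3 % of the air-sac
mean; without it, ~13 %.

Electrodes are point electrodes at boundary nodes (gap model), not the
complete electrode model. Difference imaging largely cancels contact
impedance, and the phantom makes no claim about absolute voltages; this is a
stated fidelity limit.

## Forward model

Quasi-static real-valued conduction: ∇·(σ∇u) = 0 with linear triangular
elements, one sparse LU (or, on meshes under ~700 nodes, a dense Cholesky of
the grounded system — identical differential voltages, several times faster)
per conductivity field, reused across the 32 injections. The 192 kHz carrier
of the hardware is metadata; no complex admittivity is modelled. Potentials
are reported in the zero-mean gauge; all observables are pair differences,
which are gauge-independent. The default stimulation pattern is adjacent
drive with adjacent measurement, skipping any measurement pair that touches
an injecting electrode: 32 × 29 = 928 channels. (The device's true rotating
sequence is not published; the skip is configurable.)

Accuracy anchors: on a homogeneous unit disk at ~6 000 elements the boundary
voltages match the closed-form log potential u = (I/πσ) ln(|z−z_sink|/|z−z_source|)
to ~1 % of the largest channel; the adjoint Jacobian
J[ch,e] = −area_e ∇u_drive·∇u_meas matches central finite differences to
~1e−7 on a coarse mesh (the analytic adjoint product and the assembled
matrix agree to machine precision).

## Reconstruction

A linear matrix R minimising Σ_t ‖R y_t − d_t‖² + λ²‖R‖² over simulated
point targets: y_t is the normalised voltage signature (via the Jacobian) of
a small circular conductivity *decrease* at a random position, d_t a blob of
twice the target radius in the 32×32 raster. Defaults: 1000 targets, target
radius 5 % of the raster side, uniform channel-noise weighting. Targets are
drawn in right–left mirror pairs: a one-sided random cloud leaves ~10 %
lateral asymmetry in R, which is poison for a centre-of-ventilation
analysis; with pairing, the mirror-symmetry error of a symmetric scene is
~3 %. λ is set by bisection so the noise figure — the ratio of the image-
domain RMS gain for white channel noise (‖R‖_F/√C) to the signal gain for a
central target (‖Ry‖/‖y‖) — equals the requested value (default 0.5).
The vendor's "modified" consensus variant is proprietary; this is the
reference formulation.

Sign convention (the single source of truth, asserted by simulator and
analysis alike): positive reconstructed pixels mean conductivity decrease
relative to the reference frame, i.e. air filling during inspiration.
Reconstruction uses normalised differences (v − v_ref)/v_ref for robustness
to channel gain.

## Breath analysis and ventilation variables

The global curve is the per-frame sum of in-mask pixels. Cardiac flutter is
removed by a zero-phase 4th-order Butterworth low-pass (default cutoff
1.5 Hz — between the respiratory band, <0.5 Hz at anaesthetised rates, and
the cardiac band, >3.3 Hz). Breaths are trough–peak–trough triples found at
a prominence of 20 % of the median excursion (a permissive first pass
estimates the excursion). TIV is defined non-negative as
z(end-inspiration) − z(start-inspiration). Artefact-free selection keeps the
longest run of consecutive breaths whose TIV and duration both lie within
the median ± 50 %, truncated to ten (earliest run on ties), requiring at
least six; apnoeic gaps over 10 s break a run. The artefact rule is a
stand-in for an unpublished vendor criterion and every threshold is a
parameter.

Functional (tidal) images are end-inspiration minus start-inspiration
frames. For the distribution metrics, negative pixels are clamped to zero
(out-of-phase artefacts must not count as negative "ventilation"); the raw
image keeps them. The signed in-mask sum of the tidal image equals the
global-curve difference exactly; clamping adds only the reconstruction's
negative side lobes (<1 % on a ~4k-element phantom). CoV normalises pixel
centres to the mask bounding box (so padding cannot shift it): 0 % means all
signal at the right/ventral edge, 100 % left/dorsal. The RL midline is the
bounding-box centre (the analysis knows only the outer contour, not the
sternum); a pixel column straddling it is split half-and-half. The eight
regions are four equal-height bounding-box bands × the RL split, with rows
apportioned fractionally at band edges so the percentages sum to exactly
100.

## Breathing-pattern classification

Expiratory limbs are normalised to 1 at end-inspiration and 0 at
end-expiration on a unit time axis. Without a pause, the signed area between
the curve and the straight chord decides concave (BrP1, area ≥ 0) versus
convex (BrP2). A pause is a sustained near-zero-slope interval: slope is
estimated by a short Savitzky–Golay derivative (window ~5 % of the limb,
robust to residual flutter); samples with |dz/dτ| ≤ 10 % of the mean
absolute slope seed a region grown by hysteresis to 5× that threshold
(recovering plateau extent blunted by the low-pass filter); the region must
last ≥ 0.3 s, must not lie in the final 5 % of expiration, and must sit
strictly within exhalation — at least 10 % of the swing exhaled before onset
and 5 % remaining after offset. The last rule is what separates a true
plateau from the flat *start* of a concave limb or the creeping *tail* of a
convex one, whose slopes also vanish. Pause onset level > 0.5 gives BrP3,
≤ 0.5 BrP4. A recording is labelled with the modal category only when it
holds ≥ 95 % of analysed breaths, else `mixed`. The numeric pause thresholds
are design choices validated only against the simulator; the defining visual
criteria they operationalise are qualitative.

## Synthetic recordings

The generator emulates the study conditions: 120 s recordings at 48
frames/s, 5 mA adjacent drive on 32 electrodes, respiratory rate 10/min,
heart rate 240/min, per-breath period jitter ±5 %, inspiratory fraction
~N(0.4, 0.05). Inspiration is a half-cosine rise; expiration follows the
generating pattern (1 − τ² for BrP1, (1 − τ)² for BrP2, linear decays with a
0.15·T_e plateau at level 0.6 or 0.4 for BrP3/BrP4). Air filling lowers
air-sac conductivity: σ_e(t) = σ_base(1 − α v(t) g_e) with α = 0.15 by
default (no deposited raw signals exist to calibrate α; the absolute
σ_base = 0.3 S/m is arbitrary since difference imaging is scale-free).
Cardiac elements carry a heart-synchronous swing of 3 % of the tidal
amplitude ("minuscule but detectable"); lungs and background are constant.
Recumbency determines the axis of the spatial gain g_e ∈ [1−|shift|,
1+|shift|], which increases linearly towards the non-dependent side or
aspect (on the back → ventral; prone → dorsal; right lateral → left; left
lateral → right); no organ displacement is modelled. Channel noise is
zero-mean Gaussian with sd = noise_sd × mean |v − v_ref| (default 2 %).
Seeding uses independent sub-streams for waveform jitter and channel noise,
so switching noise on cannot move breath timing.

Frame rendering exploits that each frame's conductivity depends on two
scalars only — air-sac filling v(t) and cardiac phase. The forward map is
solved exactly on a 10 × 3 Chebyshev–Lobatto tensor grid over [0,1]² and
frames are evaluated by barycentric interpolation; the map is analytic in
both drivers and the observed interpolation error is at machine precision
(~1e−14). Every run spot-checks the peak-inspiration frame against a direct
solve and falls back to per-frame solves on mismatch; a unit test asserts
frame-level agreement at 1e−9.

What the generator does **not** emulate — and hence what passing tests do
not establish about real birds: 3-D (lens-shaped) sensitivity out of the
belt plane, organ motion between postures, caudal air sacs, belt slippage,
electrode-skin impedance drift, and any physiological coupling between
pattern and rate. It provides ground truth for the *pipeline's* correctness,
not a validation of avian physiology.

## Statistics

The two-sided Fisher exact test for r×c tables sums, under fixed margins,
the probabilities of all tables no more probable than the observed one
(with the customary 1e−7 relative threshold tolerance). Enumeration is a
row-by-row recursion whose states (row index, remaining column sums) are
memoised with the minimum, maximum and log-sum-exp of completion weights, so
whole subtrees are added or pruned without expansion; the 4×4
breathing-pattern table (N = 39) takes a few seconds and agrees with an
independent R `fisher.test` oracle to 1e−9. The Monte-Carlo fallback samples
fixed-margin tables via `scipy.stats.random_table` (Patefield) and reports
the plain proportion. Group summaries are means with t-based 95 % CIs;
mixed-model machinery is deliberately out of scope, and the summary table is
labelled as plain descriptive statistics.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: the chicken
phantom at 1.9 mm element size (~3 700 elements, ~1 900 nodes) for
forward-accuracy, reconstruction-quality and distribution-variable checks;
a 6.5 mm phantom (~300 elements) for the many-recording classifier and
shift-recovery suites, where only the global-curve shape and lateral moments
matter; 120 s recordings where the acquisition protocol is the point, 30–60 s
where only cycle-level behaviour is needed. Degenerate inputs fail loudly:
non-positive conductivities, overlapping ROIs, zero reference channels,
all-zero functional images, sub-minimum breath runs and infeasible exact
enumerations all raise with named context rather than propagating NaNs.
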