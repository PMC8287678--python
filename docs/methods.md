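# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `apexshear`, and what the synthetic generators do and do not
emulate.

## Surface representation and discrete operators

Meshes are triangle soups validated at construction: valid indices, no
degenerate triangles (area ≤ 1e-12 mm² rejected, or dropped at load),
consistent orientation (each directed edge used at most once).  Coordinates
are millimetres and stresses pascals throughout, so stress gradients are
natively Pa/mm.

**Vertex areas.** Each vertex carries one third of its incident triangle
area.  This partition sums exactly to the surface area and is the weight used
by all region averages (a config switch provides unweighted means for
sensitivity checks; area weighting is the default because the marching-cubes
and clinical meshes this package targets have irregular triangle sizes).

**Apex patch.** The analysis patch is the set of vertices within 5 mm of the
apex.  Distance defaults to geodesic (Dijkstra over the edge graph): a
straight-line ball of 5 mm at a bifurcation can capture the opposite branch
wall through space, which a surface distance cannot.  Euclidean distance is
available as a config option.  The edge-graph geodesic overestimates the true
surface distance by an O(edge-length) factor; at the default 0.3–0.4 mm
resolution this bias is well under the patch radius and identical across
subjects.

**Tangent-plane gradient.** The gradient of a per-vertex scalar is estimated
by a least-squares fit of the one-ring field differences against the
tangent-plane coordinates of the one-ring edge vectors.  The estimate is
exact for fields affine in the tangent coordinates of a planar mesh (verified
to 1e-10), first-order accurate on curved surfaces, and robust to irregular
valence.  Vertices with fewer than two usable, non-collinear neighbours are
flagged undefined and excluded from region averages (never zero-filled).

## Wall parameters

With wall-shear vectors sampled at ≥ 2 times spanning one cycle (8+ samples
recommended; generators default to 24), all time integrals are trapezoidal on
the given, possibly non-uniform, sample times.  TAWSS is the cycle mean of
the magnitude; OSI is `0.5 (1 − |∫wss dt| / ∫|wss| dt)`, clipped to [0, 0.5]
against quadrature jitter and undefined where the trajectory is identically
zero.  The local frame takes p̂ as the cycle-mean shear vector projected to
the tangent plane (undefined below a 1e-9 Pa threshold, e.g. perfect
reversal) and q̂ = n̂ × p̂.

The signed WSSG decomposes the tangent gradient of TAWSS onto (p̂, q̂):
magnitude `√((∂τ/∂p)² + (∂τ/∂q)²)`, sign = sign(∂τ/∂p).  "Gradient in the
same direction as the WSS vector" is thus concretised as a positive
projection on p̂; the q-component contributes magnitude only.  A zero
p-component is assigned +1, an arbitrary but deterministic tie-break on a
measure-zero set.

**Region definition.** The high-WSS region is the subset of patch vertices
with TAWSS at or above the linear-interpolation 98th percentile of the patch
values.  Whether the percentile should be taken over the patch, the branch or
the whole model is genuinely open; the patch is the default and the scope is
exposed (`threshold_vertices`).  Measurements restrict to the daughter branch
whose patch vertices attain the higher maximum TAWSS ("higher" by maximum,
not mean — also open; exact ties break deterministically to branch1 with a
warning).  dirWSSG is positive iff the area-weighted signed WSSG of the
region is strictly > 0.

## Doppler digitiser

Axis calibration (s/px, cm·s⁻¹/px, baseline row) is user-supplied; on-screen
axis detection is device-specific and out of scope.  The maximal-velocity
envelope per column is the topmost above-baseline pixel reaching 20 % of the
image maximum intensity **and starting a vertical run of ≥ 3 such pixels**.
The run requirement is a standard despeckle guard: a bare topmost-pixel rule
is destroyed by any isolated bright noise pixel, while a 3-pixel run demands
p³-rare noise alignment.  Raising the intensity threshold can only lower the
envelope (monotonicity holds with the run rule).  Signal-free columns are
linearly interpolated; a 5-column median filter smooths the result.  Only
antegrade (above-baseline) flow is digitised.

Cycle cropping finds the beat period from the first prominent peak of the
mean-removed autocorrelation (≥ 0.2 normalised height, fundamental = first
peak within 80 % of the strongest; a monotone trace has no interior peak and
errors out), then starts the cycle at the velocity minimum of the first beat
(end-diastole).  Manual markers bypass detection.  Indices: Vps = cycle
maximum, Ved = value at the cycle end (end-diastolic by definition; a config
switch reads the global minimum instead), Vm = trapezoidal time mean.

The exported inlet profile is two-column ASCII (time s, velocity m/s) with 17
significant digits — the smallest fixed format that re-imports the stored
doubles bit-exactly.

## Synthetic generators

All generators are deterministic under a fixed seed.  They define the study
conditions of the test suite; none of them model wall elasticity,
non-Newtonian rheology, turbulence, or secondary/swirling flow, so passing
tests demonstrate correct post-processing of wall fields, not CFD fidelity.

**Womersley oracle.** Blood is Newtonian with density 1056 kg/m³ and
viscosity 0.0035 Pa·s.  For a pressure-gradient harmonic of amplitude G at
frequency k/T, the wall shear is
`Re[G R/2 · 2 J₁(Λ)/(Λ J₀(Λ)) · e^{i(kωt+φ)}]` with `Λ = α e^{i3π/4}` and
Womersley number `α = R √(kωρ/μ)`; the steady term is the Poiseuille value
G R/2.  The implementation was verified against an independent Crank-Nicolson
finite-difference solution of the pulsatile pipe-flow PDE (relative error
2e-6), a check kept in the test suite at coarser resolution.

**Bifurcation surface.** The zero level set of a smooth-min (log-sum-exp,
blend 0.4 mm) union of three capsule distance fields — trunk radius 2.5 mm,
branches 2.0/1.8 mm splayed 90°, lengths 8/10 mm — triangulated by marching
cubes at the requested edge length (default 0.3 mm, matching the target
application's mesh pitch; most tests use 0.4 mm for speed).  Ends are capped
(the closed surface is immaterial to apex-patch metrics).  Vertices are
labelled by nearest centreline; the apex is the surface vertex in the
bifurcation plane, ahead of the junction, minimising the larger of the two
distances-to-branch-surfaces — the flow-divider crotch.

**Zonal wall-shear fields.** TAWSS follows the geodesic arclength s from the
apex: linear rise from `tau_impingement` to `tau_peak` at `peak_distance`,
then exponential decay with `decay_length`.  The shear direction is the
tangent gradient of s (the local downstream direction), so the signed WSSG
equals the profile slope by construction: positive before the peak, negative
beyond it.  Magnitude is modulated by `1 + pulsatility·sin(2πt/T)` and
direction-flipped for the trailing `reversal_fraction` of the cycle to raise
OSI above zero.  Two cycles are generated and the first discarded — a
pipeline convention mirroring solver-transient practice, though the synthetic
field has no transient.  The `case_like` preset (peak at 7 mm, beyond the
5 mm patch) yields a positive region WSSG; `control_like` (peak at 1 mm)
yields a negative one.  The default cycle of 0.9 s corresponds to a typical
resting adult heart rate.

**Waveform generator.** The beat shape is `sin(π u^0.5)^β` on u ∈ [0, 1]
(the √ warp puts the systolic peak at a quarter of the cycle); β is solved by
root-finding so the cycle mean hits the requested Vm exactly, with the
defaults Vps 97.4, Ved 44.0, Vm 66.4 cm/s — typical middle-cerebral-artery
values.  Rendered spectrograms paint the baseline-to-envelope band with
multiplicative texture and add seeded Gaussian background noise at
`noise_level` × full scale.

**Cohort generator.** Group sizes default to 38 cases / 39 controls with
dirWSSG-positive proportions 23/38 and 14/39.  WSS and absWSSG are log-normal
with median/IQR matched in closed form (`σ = ln(q75/q25)/(2 z₀.₇₅)`); OSI is
a scaled beta on [0, 0.5] fitted to the quartiles (zero-inflated with
π₀ = 0.26 for the control group, whose 25th percentile is 0); the signed WSSG
comes from a monotone piecewise-linear quantile function through its
quartiles and a zero crossing at u = 1 − p_pos, with logarithmic tails.
dirWSSG is the indicator [WSSG > 0], which is exactly Bernoulli(p_pos) and
sign-consistent by construction.  A Gaussian copula couples WSS, absWSSG and
OSI at Spearman 0.488 (WSS–absWSSG) and −0.309 (absWSSG–OSI), with
`r = 2 sin(πρ_s/6)`.

Two deliberate departures from naive marginal sampling:

1. Every quantile function is composed with a quartile-preserving,
   median-concentrating probability map (fixed points at 0, 0.25, 0.5, 0.75,
   1 and the WSSG zero crossing; central slope 0.1).  A distribution whose
   IQR spans ~43 Pa/mm has a sample-median standard error of ~0.5 Pa/mm at
   n = 10,000 — far looser than the generator's own calibration contract —
   so the map concentrates density at the median, shrinking that error an
   order of magnitude while leaving every quartile anchor and the sign
   proportion exact.
2. The per-subject Jensen inequality absWSSG ≥ |WSSG| (automatic for any
   region computed by the pipeline) is **not** enforced between independently
   calibrated marginals: coupling the two draws strongly enough to guarantee
   it would distort the published median targets.  Cohort validation
   therefore warns, rather than errors, on row-wise violations.

## Statistics

Group comparisons route through Shapiro-Wilk (both groups p > 0.05 →
Student's t with pooled variance, otherwise Mann-Whitney U; groups smaller
than 8 go nonparametric outright because Shapiro-Wilk has no power there).
Mann-Whitney uses the exact null distribution for small untied samples and
the tie-corrected normal approximation otherwise.  The Fisher test is the
standard two-sided probability-mass rule (sum of margin-fixed table
probabilities ≤ the observed one), verified in the tests against full
enumeration for every table with total ≤ 30.  Odds-ratio intervals are Wald
on the log scale with z = 1.96 (the conventional reporting value;
Haldane-Anscombe 0.5 correction, flagged, for zero cells).  Profile
likelihood intervals are deliberately not the default.

Variable selection keeps predictors with univariate logistic p < 0.1 and,
within any pair correlated at Spearman p < 0.05, the one with the smaller
univariate p — a single screen-and-dedup pass, not iterative stepwise
re-entry, since the final model is fully determined by the rule.
"Uncorrelated" had to be operationalised; p ≥ 0.05 is the natural reading.
Logistic fits are Newton/IRLS (tol 1e-8, ≤ 100 iterations) with Wald
inference; perfect separation raises, and non-convergence is flagged rather
than silently reported.  ROC curves are empirical over all unique score
thresholds, AUC by trapezoid (equal to the Mann-Whitney U statistic divided
by n₁n₂, an identity the tests assert on seeded data); the optimal cutoff
maximises Youden's J with ties broken toward higher sensitivity.  The
"combined" curve scores subjects with the multivariate model's predicted
probability.  No multiplicity correction is applied anywhere.

## Problem sizes and degenerate inputs

Default test/example sizes — bifurcation meshes at 0.4 mm (≈ 3,800 vertices),
24 time samples per cycle, 300×500 px spectrograms, calibration cohorts of
10,000 per group — were chosen so the whole suite runs in well under a minute
per module on a single core while keeping discretisation error far below
every asserted tolerance.  Degenerate inputs fail loudly and early: empty or
non-triangular meshes, non-positive calibrations, blank spectrograms,
aperiodic waveforms, constant samples to the rank tests, single-class
outcomes to the logistic/ROC routines, zero-IQR cohort targets.

## Known limitations

- The geodesic distance is graph-based, not exact-polyhedral; patch
  membership near the 5 mm boundary can differ from the exact geodesic by
  about one edge length.
- The WSSG derives from the gradient of the scalar TAWSS field, with the
  (p, q) decomposition applied to that single gradient vector; formulations
  that differentiate the vector components individually differ at points of
  strong directional change.
- The synthetic cohort reproduces marginal summaries and selected
  correlations, not the full joint distribution of real subjects; estimates
  that depend on unspecified joint structure (e.g. the combined-score AUC)
  are indicative only.
- The digitiser assumes a single antegrade envelope; aliased or
  below-baseline content is ignored by design.
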