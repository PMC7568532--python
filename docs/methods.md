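# Methods

This note documents the models, estimators and numerical choices behind
`rosetteroll`, and what the synthetic-data tests do and do not establish
about real tracking data.

## The physical picture

A *C. crescentus* rosette is modelled as a rigid sphere of radius R
(2–6 μm) whose single active flagellar motor applies a torque. Far from
boundaries a torque produces only rotation; near a no-slip wall the
rotation–translation coupling of Stokes flow drives a rolling
translation perpendicular to the rotation axis. The motor alternates
between CW and CCW states (a telegraph process with ~1 s mean
durations); a reversal flips torque, rotation and translation together,
so the track back-tracks with turning angle θ ≈ π. Chirality of the
flagellar propulsion near the surface curls the path: CCW circulation
for a CW motor and the mirror for CCW. Solitary swarmer cells instead
run–reverse–flick: reversal (θ ≈ π) on CW→CCW and a ~π/2 flick on
CCW→CW.

## Synthetic-data generator

The rolling-rosette generator is kinematic, not dynamic: the in-plane
rotation-axis angle α(t) performs a drift–diffusion walk
(dα = c·s(t)·dt + √(2D_a)·dW with the motor sign s(t) = ±1), and the
center moves at speed Q·ω·R perpendicular to the signed axis, flipping
at every switch. Defaults encode the observed study conditions: R = 4 μm,
ω = 1 rad/s, translation speed 3.6 μm/s, exponential(1 s) motor
durations (a lognormal option mimics the heavier duration tails the
aggregates show), 20 Hz sampling for rosettes and 208 Hz for swarmers
(camera rate), swarmer speed 45 μm/s. Where the experimental papers are
silent we fixed, once: additive per-frame positional noise 0.05 μm
(measurement-like, non-accumulating), axis rotational diffusivity
0.05 rad²/s, and a chirality drift c = 0.3 rad/s giving a path-curvature
radius ≈ 12 μm, the visual scale of published rosette tracks. Far from
the wall (d/R > 2) the rolling lock is released and the axis-to-velocity
angle is drawn uniformly per track, which reproduces the near-uniform
far-field β distribution.

What the generator does *not* emulate: rosette shape irregularity and
deformation, adhesion to the substrate (the reason measured slip ratios
exceed the hydrodynamic prediction), hydrodynamic interactions between
rosettes, phase-contrast image formation, or tracking-stage artefacts.
Passing recovery tests therefore validates the estimators under the
stated statistical structure, not the optics or segmentation of a real
microscope.

A consequence worth noting: with D_a = 0.05 rad²/s the chirality drift
is comparable to axis diffusion over 1–3 s segments, so motor-state
labels inferred from segment circulation are intrinsically uncertain on
such tracks; the pipeline surfaces this through "undetermined" states
and flagged same-state neighbours rather than hiding it. The chirality
rule itself is verified on clean arcs.

## MSD and crossover

The per-track MSD uses all overlapping time origins (FFT implementation,
checked against the direct sum); the ensemble curve is the mean over
units with SD-across-units error bars, and tracks shorter than 60 s are
excluded. The crossover fits MSD = a·Δt² on lags ≤ 0.5 s and
MSD = b·Δt on lags ≥ 5 s, both as fixed-exponent least squares in
log–log space, and intersects them at Δt_c = b/a. The windows are
configuration parameters; tests show Δt_c moves < 20% under ±20% window
changes. For a reversal telegraph with mean duration τ the analytic VACF
u²e^(−2t/τ) gives a long-time MSD slope u²τ, hence Δt_c ≈ τ; the
estimator recovers τ = 1 s within 0.2 s on nine 120-s tracks.

Statistics of single-track MSDs: the time-averaged MSD at lag Δt has
relative SD ≈ √(Δt/T), so per-lag agreement with closed forms is only
asserted for Δt ≪ T.

## PIV and 3D rotation reconstruction

The PIV is single-pass: zero-mean FFT cross-correlation per
interrogation window, per-lag overlap renormalization (removing the
triangular bias of padded correlation), a quarter-window displacement
limit, a primary-to-secondary peak-ratio test (default 1.2), and 3-point
Gaussian sub-pixel interpolation with a parabolic fallback when a
neighbour is non-positive. Measured accuracy on rendered sphere
textures: ~0.1 px/frame for gentle motion with 32-px windows, ~0.3
px/frame at 0.1 rad/frame rotation with 16-px windows, where the shear
across a window dominates. A multi-pass window-deformation scheme would
do better; it is not needed because the rotation fit averages hundreds
of vectors.

The rigid-rotation fit solves, in weighted least squares,

    vx = Ux + ωy·dz − ωz·dy
    vy = Uy + ωz·dx − ωx·dz

with dz = −√(R² − ρ²) on the lower (objective-side) hemisphere and the
center fixed at the independently measured image centroid (freeing it
makes the design nearly collinear). The depth term is the sole source of
identifiability for (ωx, ωy); geometries sampling a single depth shell
raise a degeneracy error rather than returning silently poisoned values.

Two measurement realities matter when the field comes from PIV rather
than from point samples. First, a PIV vector is a window average; since
the model is linear in position, the window-averaged velocity equals the
model at the window-averaged (x, y, dz), which the fit computes over the
footprint∩disk, weighted by the projected surface-texture density
R/|dz| (surface patches near the rim project densely) and by the focal
kernel. Second, near the projected rim the pattern compresses and
markers cross the visibility boundary, so PIV under-reads the surface
motion there; vectors beyond ρ = 0.8R are excluded. With both
corrections, per-pair in-plane components remain noisy (their signal is
the small depth variation of the inner disk), so
`fit_rotation_sequence` averages the per-pair fits over a frame
sequence; 30 frames recover |ω| ∈ [0.5, 2] rad/s within 10% even for
purely in-plane axes.

Axial positions use a calibration table mapping a scalar focus metric
(variance of the band-passed image — any strictly monotone metric works)
to depth, with monotone interpolation; 3D tracks add stage position,
in-image offset and the axial estimate, bridging stage gaps of at most
3 frames.

## Motor statistics

Switches are heading changes exceeding π/2 across a 0.25-s window
(computed only where speed > 0.5 μm/s on 5-frame-smoothed tracks),
placed at the local speed minimum; all three thresholds are exposed
configuration. Two true switches closer than the window cancel and are
undetectable by construction; recall/precision ≥ 0.95 holds for
resolvable (lognormal-duration) switching at default noise. Segment
states come from the sign of the mean signed curvature
κ = dθ/ds, estimated by regressing the unwrapped heading on time (the
textbook (v×a)/|v|³ estimator double-differentiates shared noise and is
bias-dominated on measured tracks). Same-state neighbours are flagged as
missed intermediate events, never merged. Restoring times pair
consecutive CW+CCW durations with overlap (both pairings), maximizing
samples. Mixture fits are maximum likelihood: Gaussians via EM
(scikit-learn, spherical covariance, variance floor), exponentials via a
hand-written EM with seeded multi-start; turning-angle fits on [0, π]
reflect the samples at both boundaries and keep components with means in
range.

## Rolling statistics

Coupling samples are 1-s intervals: u from the net displacement, ω̄ from
a trapezoidal mean of the angular-velocity series (consistent with the
displacement being a trapezoidal integral — an arithmetic mean biases Q
by O(1/N) per interval), β measured CCW from the axis to the velocity,
Q = u_⊥/(ω̄_{x−y}R), intervals with ω̄_{x−y} < 0.05 rad/s excluded. The
β density uses a circular histogram smoothed by a wrapped-Gaussian
kernel (bandwidth π/12 by default) before taking ρ_max/ρ_min — a raw
histogram makes ρ_min noise-dominated and P inflates; the von Mises
check P = 2·tanh(κ) passes within 5% at the default bandwidth halved for
κ ≥ 2. Q(d/R) is fitted as a·e^(−b·d/R) (no additive offset) with 95%
bounds from a seeded parametric bootstrap; percentile bootstrap
intervals undercover by a few points in small samples, which the
calibration test acknowledges by asserting ≥ 90% marginal coverage.
ANOVA and the OLS slope test are computed from their defining sums (and
cross-checked against an independent implementation in tests);
significance is declared at p < 0.05.

## Wall hydrodynamics

The mobility solver is a first-kind boundary integral with constant
traction panels on a latitude–longitude sphere mesh graded toward the
near-wall pole (grading exponent 3, 32×40 = 1280 panels by default). The
wall is exact through the image-system Green's function, verified to
satisfy no-slip on z = 0 at machine precision. Quadrature: exact
spherical patch areas; flat-disk analytic self-term; sub-panel
refinement (up to 21×21, adaptive in distance/panel-size ratio) for
near-singular direct and image interactions — without it the image
integrals at small gaps are wrong by factors of 2. The mobility problem
appends force/torque constraints to the collocation system and solves
densely (LU); the grand mobility is assembled from six unit loads. The
slip ratio Q = U_x/(Ω_y R) for a torque about y uses the direct coupling
entry M[0,4], whose convergence with panel count is markedly faster than
its transpose; the M[0,4]/M[4,0] asymmetry serves as an accuracy
diagnostic. Gradings above ~5 create sliver panels that defeat the
quadrature and are avoided.

Validation: free-space mobilities to < 1%; at d/R = 1 the coupling
agrees to ~2% with an independent two-reflection expansion
(rotlet image + Faxén laws + stresslet scattering, built directly from
the kernel and itself validated against the analytic (1/8)(a/h)⁴
far-field law); at small gaps the solver tracks the lubrication
asymptote Q(ε) = (2/15·ln(1/ε) − 0.2526)/(8/15·ln(1/ε) + 0.9588). The
resolved maximum over d/R ∈ [0.005, 5] is Q ≈ 0.12 at the smallest gap.
Note the contact limit: Q rises only logarithmically toward 1/4, passing
0.2 near ε ~ 10⁻⁶ — values quoted for "near contact" therefore depend
strongly on the smallest gap actually solved, and boundary-integral
solutions whose near-singular quadrature is under-resolved overshoot at
small gaps (a failure mode the quadrature tests here exclude).

The flagellated-sphere simulator closes force and torque balance each
step: Gray–Hancock resistive-force drag on a discretized helical
filament rotating at the motor speed about its axis, against the
wall-corrected grand resistance of the sphere (mobility interpolated in
d/R). Only the sphere feels the wall; filament–wall interactions are
neglected, so the simulator supports sign/chirality and qualitative
orbit statements, not quantitative orbit radii. The motor-sign
convention is fixed so that a CW motor (viewed from outside the cell,
looking in along the flagellar axis) yields CCW in-plane circulation
near the wall, as the chirality of the coupled system dictates.

The flagellation model treats the N_s member cells as independent
Bernoulli trials with active probability f = Δt_f/Δt_d (active-flagellum
window over division time; defaults 1 min over 100 min). P(≥2 active) is
an exact binomial tail. The window Δt_f is an assumption, not a
measured quantity; at N_s = 25, f = 0.01 the probability is 2.6%.

## Problem sizes used in tests

Simulated ensembles are 6–10 tracks of 60–120 s at 20 Hz; frame
sequences for the PIV chain are 31 frames of 96×96 px at 0.1 μm/px with
2000 surface markers; mobility validation meshes are 192–1280 panels
with 1280 used for the reported gap sweep; Monte Carlo calibrations use
200–500 seeded replicates. All randomness flows through explicit seeds,
and dataset-level runs derive per-operation seeds from the run seed by
hashing, so results are byte-reproducible.
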