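# Methods

This note records the models, conventions, numerical choices and known
limitations behind `phasereg`, in the order the data flow through the
package.

## Signal model and statistics

A voxel's complex-valued BOLD signal is treated as a paired magnitude/phase
timecourse.  The block design is alternating off/on blocks (reference: 14
blocks of 16 s); the hemodynamic response is a unit impulse with zero delay
in simulation, and a pure label shift otherwise: a delay of d seconds shifts
the condition labels backward by `round(d / sample_interval)` samples and
drops the unlabeled leading samples.  A pluggable HRF is deliberately out of
scope — the impulse is the only response model.

The functional SNR statistic used for single-voxel work is

    fSNR = (mean(S_on) − mean(S_off)) / (std(S_on)/2 + std(S_off)/2),

with *sample* standard deviations (ddof = 1).  The same ddof = 1 convention
is used for z-scoring.  This convention is applied uniformly; switching to
population sd changes third-decimal digits at the reference length (N = 224)
and nothing qualitative.  Volume-level contrasts instead use a conventional
pooled-variance two-sample t over delay-shifted volumes; the two statistics
are intentionally distinct and never mixed.

Simulation sampling is 1 s (N = 14 × 16 = 224 timepoints); phantom volumes
sample at TR = 2 s (N = 112).  Realized t magnitudes scale with √N, so any
comparison across designs must hold the design fixed.

Preprocessing order is fixed and tested: homodyne filter (volumes only) →
cubic polynomial detrend → z-score.

## PR and sPR

PR minimizes L(b₀,b₁) = Σ(S^m − b₀ − b₁S^p)²/(σ_m² + b₁σ_p²), with
σ_m = σ_p = 1 after z-scoring (both are exposed as parameters for
non-normalized inputs).  The sign convention r = sign(corr(S^m,S^p)) aligns
the phase before fitting, making the closed form
b₁* = r(√(2 + 2|ρ|) − 1); the stored quadratic coefficients satisfy
A·b₁*² + B·b₁* + C = 0 and are validated against numpy's polynomial roots
and a brute-force scan of the loss itself.  A historical variant of the
coefficient algebra whose constant term halves the cross term is available
as `coefficients="printed"`; it yields b₁* = r(√(2 + |ρ|) − 1), a slope that
*under*-shoots the correlation (√3 − 1 even for identical series), and is
retained for comparison and diagnostics only — it is not the default
because it does not exhibit the over-suppression behaviour that motivates
the OLS alternative.  Degenerate cases: exactly (to 1e-12) zero correlation
falls back to b₁* = 0 with a flag; a negative discriminant (not reachable
for real z-scored data) raises with the coefficients attached.

sPR selects the phase source k* maximizing |corr(S^m_i, S^p_k)| over the
1- or 7-voxel (self + six face-adjacent) neighborhood; ties prefer self,
then the lowest index.  Correlations are Pearson over the full
(delay-shifted) run.  At volume level the split-run protocol is enforced
structurally: slopes/correlations are estimated on the training run object
and applied unchanged to the test run, and a test asserts the fit report is
invariant to replacing the test data.  Boundary voxels use truncated
neighborhoods (padding would invent phase sources).  Degenerate voxels
(constant magnitude or all-constant neighborhood phases) are passed through
unsuppressed and flagged in the report.

In the simulation study configuration the fit is estimated on the same run
it is applied to, and sPR's neighborhood is the voxel itself — this isolates
the loss-function difference between the methods.

## Monte-Carlo regime statistics

One caveat recorded here because it is easy to trip over: in the
phase-only regime the PR artifact's *sign* is −r, and r is the sign of a
near-zero noise correlation — a fair coin.  The signed mean over seeds is
therefore ≈ 0 while the mean |t| is ≈ 0.7; per-realization-class reporting
(conditioning on r = +1) is used where a signed artifact value is wanted.
Under the closed-form fit the per-seed PR t is tightly concentrated
(sd ≈ 0.2 at N = 224), so single draws are representative of the mean to a
few tenths of a t-unit.

## Vein phantom

The vein is an infinite cylinder of radius R, tilt θ from B0, with
susceptibility difference Δχ = Δχ_do · Hct · (1 − Y): Δχ_do = 4π × 0.27 ppm
(SI) and Hct = 0.40 are literature defaults, Y = 0.54 at rest.  Activation
is modeled purely as a rise in oxygenation Y (shrinking Δχ); flow/volume
effects are not modeled — the oxygenation change suffices to produce the
magnitude/phase taxonomy the method exploits.  Field: outside,
(Δχ/2)f₀(R/r)²sin²θ·cos2φ; inside, (Δχ/6)f₀(3cos²θ−1); f₀ = 42.577 MHz/T ×
B0 (4 T default).  Two exact zeros anchor the geometry and are tested to
1e-12 Hz: parallel veins (no extravascular shift) and the magic angle
(3cos²θ = 1, no intravascular shift).  The two formulas are asserted
independently — the field is discontinuous across the wall except at the
magic angle.

Voxels are synthesized by midpoint integration over a 15³ subvoxel grid,
weighting blood vs tissue by exp(−TE/T2*) (blood 12 ms, tissue 40 ms at
4 T; TE 28 ms fMRI, 26 ms venogram).  The wall is antialiased: sample
points within one subvoxel spacing of the boundary mix the two compartments
by fractional coverage, turning the O(h) boundary error of a hard mask into
O(h²).  Convergence is checked in the refinement direction: doubling the
density (15³ → 31³) changes voxel signals by < 0.4%.  At *half* density the
signals still change by 3–5%, because near the wall the integrand oscillates
by several radians between sample points at 4 T — a hard floor set by the
physics, not the boundary treatment; 15³ is the default because it sits on
the converged side of that regime.  Complex Gaussian noise is added per
voxel and timepoint, and the exported phase is wrapped to (−π, π] so the
preprocessing path is exercised honestly.

### Frozen fixture geometry

The shipped single-vein fixture uses a 12 × 12 × 6 grid of
2.25 × 2.25 × 2.5 mm voxels, a R = 0.3 mm vein at the magic angle,
Y: 0.54 → 0.70, and complex noise sd 0.0033 (about 0.7% of the tissue
signal).  These values were calibrated once against the four-way taxonomy —
vein voxel: magnitude fSNR > 3 with |phase fSNR| < 1.5; one voxel lateral:
the converse — and then frozen; the taxonomy holds across 10 noise seeds
with wide margins.  The magic-angle tilt is not incidental: at 4 T and
TE 28 ms a *perpendicular* vein of voxel caliber spreads intravoxel phase
over ±9 rad, crushing the vein voxel's signal to a few percent of tissue —
the classic dark-vein regime that venograms exploit, and one in which no
noise level yields the taxonomy.  The magic angle removes the intravascular
phase swing and is precisely the "silent-phase vein" regime the
neighborhood phase source exists to handle.  The axis threads the vein
voxel slightly off-center so the symmetric near-field lobes cancel in the
voxel average (the centered geometry leaves a residual phase response from
the 2.25 vs 2.5 mm in-plane asymmetry).

The two-vein laterality phantom puts a R = 0.4 mm vein in the "right"
hemisphere and a R = 0.2 mm vein in the "left", both running along y at the
magic angle, plus one identical purely-parenchymal activation strip per
hemisphere (tissue signal scaled by 1.02 during on-blocks; a magnitude-only
response).  The strips sit at the outermost x columns, two columns from the
veins: a task-responsive magnitude voxel that face-touches a voxel with
task-correlated phase *will* be suppressed — both signals share the
stimulus boxcar, so the correlation is genuine — and that is method
behaviour, not an artifact.  Keeping the strips clear of the phase lobes is
what makes them "purely parenchymal".

## Homodyne filtering

Each complex slice is divided (phase-subtracted) by its low-pass version;
the low-pass window is a centered k-space rectangle of side
`kernel_fraction` × matrix size with a Hann taper, default fraction 0.25.
The variant is phase-only: output magnitude equals input magnitude to
1e-9, because the filter's job is to remove background phase wrap, not to
touch magnitude statistics.  Zero-magnitude pixels get phase 0 and a mask
flag.  Full 2D/3D phase unwrapping and B0-map estimation are out of scope.

Limitation worth knowing: on the phantom's tiny 12 × 12 matrix the low-pass
window cannot cleanly separate "background" from a task-phase pattern that
is only ~2 voxels wide, so a fraction of the vein's task phase is smeared
slice-wide and re-appears (sign-flipped) in distant voxels.  On realistic
matrices (≥ 64) the scales separate and the effect is negligible.  The
phantom tests were designed to be robust to it: the taxonomy, neighborhood
and laterality results all hold through the full preprocessing path.

## ROI metrics

T-maps threshold at t > 3 (p < 0.005 at the reference df); ROIs are the
largest 6-connected (face-adjacency, matching the sPR neighborhood) cluster
per hemisphere, hemispheres split at a configurable mid-sagittal x index.
Cluster-size ties break by higher mean t, then lower linear index —
determinism over arbitrariness.  An empty ROI is a valid outcome.

Vein contribution: N_norm = N_sPR/N_mag, percent vein = (1 − N_norm)·100,
metric 1 = N_mag − N_sPR (voxel count), metric 2 = mean-t difference with
each mean taken over its own ROI's voxels (the alternative — evaluating the
suppressed map over the magnitude ROI — is defensible; the own-ROI reading
matches "mean ROI t-values without vs. with suppression" and is what the
anomaly flag assumes).  N_sPR > N_mag is flagged, never clamped.  Laterality
indices are (right − left)/(right + left) of ROI size and of mean t;
positive = right-lateralized; zero denominators set a flag rather than
raise.

Metric 2 is well behaved only while the suppressed ROI retains enough
voxels for its mean to be stable: the monotonicity sweep (vein-contribution
metrics vs task-phase amplitude) therefore runs at 0.25/0.5/0.75 of the
fixture's oxygenation change, the range in which the suppressed ROI shrinks
progressively rather than collapsing to a single voxel.  Metric 1 is
monotone over the full range.

The group-level helpers (paired t, one-way F, Pearson r) are thin scipy
wrappers for tables of per-ROI measurements; they exist for parity with how
such tables are analyzed, and make no claims at phantom scale.

## Synthetic data: what it does and does not emulate

The generators cover: block-design complex signals at controlled expected
fSNR; the dipole field geometry and its zeros; T2* compartment contrast;
partial-volume mixing via subvoxel integration; wrapped phase; independent
complex Gaussian noise.  They do not cover: Rician magnitude statistics at
low SNR, physiological or spatially correlated noise, motion, flow/inflow
effects, multi-vessel trees, EPI/k-space artifacts, or real anatomy.
Passing tests therefore demonstrate the estimators' algebra, the
field-model physics, and the method's qualitative behaviour around veins —
not performance on real 4 T data, where noise structure and motion
correction dominate the error budget.

## Numerical conventions

Polynomial detrending uses numpy's scaled-domain `Polynomial.fit` for
conditioning.  Constant channels are flagged as degenerate *before*
detrending (afterwards only rounding noise remains, and z-scoring it would
produce garbage silently).  Randomness flows from a single master seed per
invocation: grid cells draw from `SeedSequence(seed, spawn_key=(i, j))`
substreams, so grids are reproducible cell-by-cell and order-independent.
Phase is wrapped to (−π, π] everywhere; integer-scaled phase conventions in
NIfTI inputs (e.g. ±4096) are auto-detected and rescaled with a log
message.
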