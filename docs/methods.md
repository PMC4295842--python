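# Methods

This note documents the models behind each analysis, the synthetic-data
generator that stands in for the microscope, the parameters that matter,
and the numerical choices made where the procedure was genuinely open.

## Focus detection and background statistics

A focus is a local maximum (26-neighborhood) of the 3-D stack whose value
strictly exceeds `mean_bg + 5·sd_bg`. The background statistics are the
mean and SD of all stack voxels after iterative 3σ clipping (at most 10
iterations): foci occupy a tiny fraction of the voxel population, so
clipping removes their bright tail without requiring a segmentation mask.
The clipping threshold is deliberately parameter-free; for a pure-Gaussian
background the clipped SD underestimates the true SD by ~2%, which is
negligible against the 5 SD detection margin.

Candidates closer than 3 px **laterally** (any z) are reduced to the
brightest; ties break by ascending (z, y, x), making detection fully
deterministic. The maximum filter uses wrap-around boundaries, which makes
detection exactly equivariant under cyclic shifts and is inconsequential
for real stacks (foci at the frame border are excluded from quantification
anyway via the edge flag). Coordinates are 0-based voxel indices in
(z, y, x) order. No subpixel localization is attempted: copy-number ratios
need intensities, not nanometer-precision centers.

## Intensity measurement and stoichiometry

Focus intensity is the voxel sum over a fixed cylinder — radius 3 px
(matching the minimum-separation scale), all z-planes — minus
`(outside_background + autofluorescence) × n_voxels`. Both correction
terms are passed explicitly; the pipeline helper uses the clipped
background mean for the first and the stack's autofluorescence reference
(measured from fluorophore-free cells, 0 in simulations) for the second.
A cylinder of radius 3 px captures ≈ 99% of a σ = 1 px lateral Gaussian;
what the acquired z-range misses for foci near the top or bottom plane is
*meant* to be missed — the same truncation affects target and reference
equally and cancels in the ratio. Corrected intensities may be negative
for noise-dominated ROIs and are reported as-is, never clamped. ROIs
clipped by the lateral frame border set an `edge` flag and are dropped
from stoichiometry.

The copy-number estimate treats each stack as one independent value:
per-stack mean intensities are averaged per group, and

    mean_copies = reference_copies × grand_mean(target) / grand_mean(reference).

`sd_copies` scales the **per-focus** intensity SD of the target group to
copy units. This convention is chosen because the dominant spread is the
per-focus focal-plane offset, not stack-to-stack variation; it describes
the width of the intensity distribution, not the uncertainty of the mean.

## FRAP model

The raw observable per frame is the triplet (I_S, I_B, I₀): spot ROI mean,
whole-cell ROI mean, extracellular background. The spot ratio
R = (I_S − I₀)/(I_B − I₀) cancels lamp intensity, exposure, and camera
gain; any affine transform of R leaves the analysis invariant (tested).

Normalization uses the mean of the 10 frames immediately before
(`R_pre`) and after (`R_post`) the bleach:

    N(t) = (R_pre − R(t)) / (R_pre − R_post).

N is the **unrecovered** fraction: ≈ 1 just after the bleach, decaying
toward `1 − mobile_fraction`. This direction is the only one consistent
with fit bounds start ∈ [0.9, 1.1] and end ∈ [−0.1, 0.4], and it maps an
~80% mobile fraction to a plateau end ≈ 0.2. Because `R_post` averages
frames during which some recovery has already occurred, the fitted start
typically sits a few percent above 1 — the bounds absorb this, and the
fitted τ and the mobile fraction (start − end)/start are unaffected
(the normalization is affine in R).

The model N(t) = start + (start − end)(exp(−t/τ) − 1) is fit by bounded
nonlinear least squares (trust-region reflective) with deterministic
multi-starts τ₀ ∈ {20, 60, 180} s to avoid local minima; tolerances are
set to 1e−14 so noiseless inputs recover parameters to ~1e−6 relative.
τ is an e-folding time constant; the recovery half-time is t½ = τ·ln 2,
an exact identity enforced on every fit. r² = 1 − SS_res/SS_tot is
computed on the normalized scale; fits with r² < 0.4, non-converged fits,
and zero-variance traces are flagged `excluded` (never raised as errors).
Group summaries report the mean and SEM of t½ over non-excluded fits;
conditions are compared with Welch's two-sided unequal-variance t-test.
Frames are weighted uniformly. Acquisition-photobleaching correction and
diffusion-coupled recovery models are out of scope — recovery here is
reaction-dominated subunit exchange.

## Single-particle tracking

Linking is per-frame-pair optimal: the assignment between open track ends
and next-frame localizations that maximizes the number of links with every
displacement ≤ `max_displacement` and, among those, minimizes the total
displacement (Hungarian algorithm with a prohibitive cost on gated pairs).
The default gate of 0.5 μm is ≈ 5σ of a single 0.15 μm²/s step at
15.26 ms. There is no gap closing: a missed frame terminates the track.
Tracks shorter than 5 frames are discarded.

Each track's single-step diffusion coefficient is
D\* = mean over consecutive steps of (Δx² + Δy²)/(4Δt). With independent
per-frame localization error σ_loc, E[D\*] = D + σ_loc²/Δt; no correction
is applied (the classification threshold is used as published, and the
bias is verified against this closed form in the tests). Classification is
per track: strictly D\* > 0.15 μm²/s ⇒ mobile, otherwise bound (a track at
exactly the threshold is bound). The pooled per-step D histogram is also
emitted for distribution-style plots. Bound-track mean positions are
reported; in the real system they concentrate in membrane foci.

## Ring geometry

n touching spheres of diameter d arranged in a closed circle have their
centers on a circle of circumference n·d, i.e. center-circle diameter
n·d/π; the outer envelope adds one d. The subunit diameter comes from the
monomer mass via the anhydrous-sphere model d = 2(3Mv̄/4π)^(1/3) with
v̄ = 0.73 cm³/g (1 Da · 0.73 cm³/g = 1.212 × 10⁻³ nm³). For a 34.4 kDa
monomer this gives d = 4.30 nm and, for 22 subunits, a ring diameter of
30.1 nm. Hydration shells and non-spherical subunit shapes are ignored;
mass and v̄ are exposed as parameters so refined inputs can be
substituted. The "diameter" reported is through sphere centers — the only
convention under which the 22-subunit ring is commensurate with the
~28 nm density footprint seen in cryo-tomograms of the machine.

## Export kinetics

The "linear increasing region" of a plate-reader trace is defined
operationally: among all contiguous windows of fixed length (default 10
points = 5 min at 30 s sampling), those whose OLS fit reaches r² ≥ 0.95
are eligible, and the maximal slope among them is returned. If no window
passes the gate the maximal-slope window is used with a low-linearity
warning. Flat windows (zero variance) count as perfectly linear with slope
0. Rates are expressed as percent of a designated reference sample with
replicate SEMs. The titration analysis is ordinary least squares of mean
foci per cell on the quantified protein amount; cohorts below 170 cells
warn.

## Synthetic data: what it emulates, what it does not

**Focus stacks.** Foci are pixel-integrated 3-D Gaussians
(σ_lat = 100 nm, σ_ax = 300 nm — the standard far-field approximation; the
real instrument's PSF is unknown but only intensity *ratios* matter) at
101.3 nm/px (so 3 px = 304 nm) and 150 nm z-spacing, 10 planes by default.
Total rendered photons per focus are `copies × unit_intensity`
(unit_intensity defaults to 200 photons/fluorophore — a free simulation
parameter, since the real photon budget and EM gain are not known);
rendering is truncated at ±4σ (< 1% loss). Focus z-centers are uniform
over the stack depth, so axial truncation produces the per-focus intensity
spread the reference-standard method must tolerate — this is the dominant
variance term in the real data too. Lateral placement is rejection-sampled
inside per-cell strips with a 6 px minimum separation (twice the detection
suppression radius; failure raises, never silently drops). The camera
model is Poisson shot noise on signal + 50 photons/px cytosolic
background, then Gaussian read noise (σ = 2). Not modelled: cell
morphology, fluorophore blinking/maturation, drift, EM-gain excess noise
(all gain factors cancel in ratios). Passing the stoichiometry recovery
test therefore shows the estimator is unbiased under Poisson noise and
focal-plane variance — not that it tolerates segmentation errors or
maturation artifacts.

**FRAP traces.** The post-bleach ratio follows
R(t) = 1 − B·(1 − m·(1 − 2^(−t/t½))) with bleach depth B = 0.8 and mobile
fraction m; this is exactly the exponential family the fitter assumes, so
FRAP tests probe estimator precision and the normalization path, not model
misspecification. Gaussian noise (σ = 0.05 by default) is added on the
ratio scale; raw I_S/I_B/I₀ columns are reconstructed around fixed camera
levels so the ratio computation is exercised. Acquisition schedules follow
the published movies (e.g. 25×1, 25×2, 25×4, 26×6 s for fast-exchange
conditions; 25×2, 25×4, 25×6, 25×10 s for slow), with 10 pre-bleach
frames.

**Trajectories.** Each molecule draws a population (fraction, D), a
geometric track length (mean 12 frames — memoryless photobleaching), and a
start frame uniform over a 15,000-frame movie, so few molecules are active
simultaneously (sparse photoactivation). Steps are isotropic Gaussian with
per-axis variance 2DΔt, reflected at the walls of a 2 × 1 μm box;
localization error (σ = 0.03 μm) is added independently per frame.
Reflection slightly depresses apparent D for fast molecules near walls;
with the default geometry this is ≪ the bound/mobile separation. Blinking
gaps and drift are not modelled, so the linker's no-gap-closing rule is
never stressed by fluorophore dark states.

All generators are driven by one `numpy` Generator per call; identical
seed + config reproduce outputs bit-for-bit.

## Problem sizes and defaults

The default study conditions mirror the experiments: 11 stacks per
condition with ~110 foci each (the real data had ≥ 100 spots per stack,
3,400–4,300 per condition); FRAP cohorts of 19/20/9/17 traces; 500–600
photoactivated molecules per PALM simulation. At these sizes the whole
test suite runs in well under a minute and the acceptance script in a few
seconds on one CPU, while keeping Monte-Carlo error comfortably inside
each tolerance (e.g. stoichiometry grand-mean CV ≈ 0.8% against a 5%
band).

## Known limitations

- The stoichiometry pipeline assumes equal fluorophore maturation and
  brightness between target and reference fusions; the simulation enforces
  this, the real experiment can only argue it.
- The FRAP fitter's bounds assume a normalization that lands start near 1;
  traces bleached by less than ~30% of the spot signal normalize noisily
  and are likelier to fall below the r² gate.
- D\* classification near the threshold is length-dependent (D\* of an
  n-step track is χ²-distributed with 2n degrees of freedom); the 5-frame
  minimum keeps misclassification of well-separated populations below a
  few percent but is not a general mixture deconvolution.
- The linker is optimal per frame pair, not globally over whole
  trajectories; at high simultaneous densities identity swaps become
  possible. The sparse-activation regime of PALM is the intended use.
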