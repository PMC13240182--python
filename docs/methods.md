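# Methods

This note documents the models, conventions and numerical choices behind
`dinolum`, and what the synthetic-data experiments do and do not show
about real recordings.

## Flash videos and cell counting

A stimulated dinoflagellate colony appears in a dark-room video as an
unresolved bright dot. The generator models it as an isotropic 2-D
Gaussian blob (σ = 2 px by default) in the **blue channel** — the flash
spectrum peaks near 470 nm, so red/green carry only background. After its
onset t_on a cell's amplitude follows the Kohlrausch law
I₀·exp[−((t−t_on)/τ)^α] with defaults τ = 238 ms, α = 0.85 (the
single-colony lifetime fit). Blob energy is truncated at the 4σ
footprint, and generated blob centres are kept ≥ 4σ apart so that every
cell presents a separable maximum — the regime in which counting is
exactly checkable against ground truth. Background noise is i.i.d.
Gaussian per pixel (mean 8, SD 3 on the 8-bit scale), clipped to [0, 255];
camera gain and noise statistics of the real setup are unknown, so this is
an assumption. Optional "reflection" artifacts are static bright pixels
outside the circular sample mask.

The counting chain is: blue channel → sample mask (auto-fitted circle, or
explicit) → subtract the 70/255 threshold, clipping at zero → total
intensity by the 2-D trapezoidal rule (unit pixel spacing) → cells as
strict 8-connected local maxima, plateaus represented by their row-major
first pixel, suppressed within a 5 px Euclidean radius (brighter-first,
ties row-major; the source analysis names neither the connectivity nor a
radius — 5 px is safely below the 8 px minimum blob separation).
De-duplication across frames uses the pixel-wise maximum projection; both
the maxima count on the projection (the cell total) and its trapezoidal
integral (an intensity-weighted alternative) are reported, since a
projected *integral* by itself yields an intensity rather than a count.

Two consequences of the 8-bit threshold model are worth noting. First,
raising the flash amplitude extends how long a cell stays above threshold,
so amplitude changes leave per-frame counts unchanged only on frames where
the dimmer variant is still visible. Second, a single flash can stay
visible at most τ·(ln(255/70))^(1/α) ≈ 0.32 s, so the 0.5–0.8 s decay of
the *population* count observed in experiments is reproduced only when
onsets stagger during loading (cells activate at different stresses); the
test suite forward-simulates exactly that configuration.

## Mechanics

The testing machine is modelled with a constant-acceleration trapezoidal
velocity profile; over a travel d it reaches v_peak = min(v_nominal,
√(a·d)), which is why short strokes at high nominal rates undershoot the
commanded speed. The **effective rate** is the maximum consecutive-sample
displacement rate over the loading phase only (retraction is excluded to
avoid sign ambiguity), computed on raw samples at 200 points/s — no
smoothing by default, with an optional 3-point median filter for noisy
real records. Finite-difference rates at 200 points/s resolve the peak of
a triangular profile to better than 1 % only when the acceleration phase
lasts many samples; the recovery tests use gentle accelerations
accordingly.

Stress and strain are engineering quantities (initial area, initial
height); the source protocol never corrects for barreling. The synthetic
gel is a linear spring (default 22 kPa, matching agar-gel stiffness) in
parallel with one Maxwell branch — the simplest constitutive model that
produces closed hysteresis loops. The branch stiffness defaults to 25 %
of the gel modulus with a 2 s relaxation time; both are fixture values,
not measured ones. During a ~1 s compression the branch is mostly
unrelaxed, so the fitted 1–3 % modulus of the default gel reads
E + E_maxwell ≈ 27.5 kPa; modulus-recovery tests therefore switch the
branch off. The Maxwell stress is integrated with an exponential
integrator exact for piecewise-linear strain.

## Spectroscopy

Spectra are photon counts on an energy grid per 125 ms integration
window. The generator distributes a photon budget over (energy, window)
bins proportionally to a sum of Gaussian peaks times the Kohlrausch
kernel integrated over each window, applies the detector transmission
QE·10^(−loss_dB/10), and Poisson-samples. The default three peaks sit at
2.617, 2.51 and 2.35 eV (blue/cyan/green) with 0.05 eV widths and
1:0.6:0.3 amplitudes.

Deconvolution fits a sum of Gaussians by nonlinear least squares (lmfit,
trust-region reflective with non-negative amplitudes). Initial centers
come from the most prominent maxima of a Gaussian-smoothed spectrum with
half-prominence widths; because two overlapping peaks merge into one
smoothed maximum, the widest initial guess is split into shoulder
components when fewer maxima than peaks are found, and several starts
(found maxima, split variants, even spacing over the signal support)
compete on residual cost. Fitted centers are reported descending in
energy together with the residual RMS.

The decay fit minimises inverse-variance-weighted residuals
(Var = max(counts, 1), the Poisson scaling) of I₀ exp[−(t/τ)^α] on the
post-peak segment, with the time origin at the sample of maximum
intensity (the origin convention is otherwise unspecified). α is free in
(0, 1] by default and can be pinned (e.g. at the global 0.85). When the
samples are window-integrated counts rather than instantaneous
intensities, pass `window_s`: the stretched exponential falls steeply
right after onset, so the pointwise model overestimates τ by ~10 % at
125 ms windows, while the window-averaged model (8-point midpoint rule
per window) is unbiased.

Emitted photons are detected counts divided by the energy-wise
transmission; with a typical spectrometer QE and the 1.0 dB interconnect
loss the transmission stays below 21 %, so emitted ≈ 5× detected.
Peak-splitting wave numbers use 1 eV = 8065.54 cm⁻¹. Note that splittings
computed from *rounded* printed centers (e.g. 2.51/2.35 eV → 1290.5 cm⁻¹)
need not match values derived from unrounded fits; no benchmark is
attached to them.

## Depletion model

The published analysis fits a "logistic growth model" combining the
positive rate–luminescence correlation with luciferin exhaustion, but its
equations live in supplementary material that is not part of this
package's sources. The recursion implemented here is this package's own
concrete instantiation — the simplest form with both ingredients:

    E_k     = P_k · yield_max · L(rate_k)
    P_{k+1} = max(P_k − E_k + regen, 0),   P_1 = pool_initial
    L(r)    = (s(r) − s(0)) / (1 − s(0)),  s(r) = 1/(1+exp(−slope·(r−r_half)))

L is rescaled so an unloaded sample emits nothing, forced by the observed
activation threshold. `regen` defaults to 0: compression cycles are
seconds apart while metabolic luciferin regeneration takes far longer.
With regen = 0, ΣE_k ≤ P₁ exactly for every schedule — a conservation law
the tests exercise on random schedules — and the infinite-slope limit
degrades gracefully (via floating-point underflow) to a hard step at
r_half. Observed counts add Poisson noise clipped sequentially to the
remaining pool so conservation also holds sample-wise. Fitting uses
bounded least squares over (pool, r_half, slope, yield) with a multi-start
grid on r_half, the parameter most prone to local minima; all-zero
observations are flagged unidentifiable. Only qualitative agreement with
the published rise-then-fall behaviour is claimed, not equivalence with
the unpublished supplementary model.

## Sensor decoding

The simulated sensor has a tall stabilising pillar p0 and shorter
indicator pillars of decreasing height; the printed device's numeric
heights are not published, so the defaults (10 mm p0, indicators spanning
5–9.5 mm, 1.6 mm diameter) are fixtures. A pillar's cells fire when the
global displacement reaches (h_p0 − h_pi) + 0.02·h_pi: the puncher first
closes the height gap, then compresses the pillar to the 2 % minimum
actuation strain. The force record is the sum of engaged pillar springs
(piecewise stiffening).

Actuation is the first frame whose ROI-mean intensity exceeds the
baseline mean by 5 baseline SDs; a zero SD gets a floor of 1 intensity
unit. The baseline SD is *estimated*, so its quality sets the
false-positive rate: with ~12 baseline frames the SD is underestimated
often enough that dark traces occasionally cross 5σ, while ≥ 40 frames
makes false positives negligible. The generator therefore records a 1.5 s
dark lead-in before the puncher moves, and the analyses use a 40-frame
baseline. Synchronisation maps p0's onset frame to displacement
0.02·h_p0 on the loading branch of the force record; other onsets map
through the shifted record with linear interpolation, so recovered onset
displacements are accurate to about one video-frame displacement
(rate/fps), and pillars whose onsets would coincide within one frame are
not resolvable. Pillars that never cross 5σ are reported non-actuated
rather than interpolated. Force decoding requires the lit indicators to
form a prefix of the height ordering (a skipped taller pillar flags an
inconsistent readout) and returns [F_onset(last lit), F_onset(next)),
open-ended above the last calibrated pillar; the intervals partition the
force axis.

## Problem sizes and determinism

All generators are deterministic given a seed (identical seed and config
reproduce outputs bit-exactly). The test suite runs the counting oracle
on 50 seeded 120×120×60 stacks, depletion conservation on 1000 random
schedules, sensor geometry on 20 trials, and the decay/deconvolution
recoveries on 20 replicates / 501-point grids — sizes chosen so the whole
suite completes in well under a minute while leaving the statistical
checks meaningful. `scripts/acceptance.py` re-runs the recovery
experiments at the same sizes.

## Limitations

Passing tests demonstrate correct recovery under the generator's
assumptions — separable Gaussian blobs, i.i.d. Gaussian camera noise,
linear-viscoelastic gel, Poisson photon statistics — not performance on
real videos with overlapping colonies, motion, bleed-through or
structured reflections. Cell tracking, sub-pixel localisation,
poro-viscoelastic constitutive fitting, hysteresis-area quantification
and the mechanistic fluorescence/phosphorescence assignment of the
emission bands are out of scope.
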