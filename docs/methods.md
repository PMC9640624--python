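# Methods

This note documents the models inside `protonfocus`, the choices made
where the design was genuinely open, and what the package's synthetic
beams do and do not share with a clinical beamline.

## Beam model

Each transverse plane carries a centred bivariate Gaussian in (u, u′)
with covariance Σ = ε[[β, −α], [−α, (1+α²)/β]]; both planes are identical
(round beam). Units are mm, rad and MeV throughout the core; the
quadrupole estimate alone uses SI because magnet gradients are quoted in
T/m.

* **Focused beams** (CEFP/HEFP) are defined at the phantom entrance by
  (σ₀ = 15 mm, α₀, d_T); β₀ = d_T(1+α₀²)/α₀ and ε = σ₀²/β₀ follow from
  the waist relation. No upstream magnet is simulated — the entrance
  phase space *is* the model of the focusing system.
* **Collimated beams** (CECP) are parallel with σ₀ = 6 mm, α = 0 and a
  machine beta of 18.8 m; slopes are set exactly to zero since the
  implied µrad divergence is unobservable across the 70 mm geometry.
* **Energy spread**: Gaussian with relative sigma 1% of the nominal
  kinetic energy. The alternative reading of "1% spread" as FWHM was
  rejected in favour of sigma; at 150 MeV the difference moves the Bragg
  peak width by ~1 mm and nothing else.
* Sampling uses one `numpy` Generator per run via the Cholesky factor of
  Σ; every public entry point takes a seed, and derived seeds are
  obtained by hashing (seed, label) so sub-runs are independent but
  reproducible.

## Interaction models

The engine replaces a general-purpose Monte Carlo physics list with the
standard desk-scale models for protons of 1–400 MeV:

| model | form | parameters |
|---|---|---|
| stopping power | relativistic Bethe, exact kinematic W_max, no shell/density corrections | water: Z/A 0.55509, I = 78 eV, ρ = 1; lead: Z/A 0.3957, I = 823 eV, ρ = 11.35 |
| CSDA range | trapezoidal ∫dE/S from the 1 MeV cutoff | cached log-spaced table |
| MCS | Highland, θ₀ = 13.6 MeV/(βcp)·√(x/X₀)·(1+0.038 ln t/X₀) | X₀ = 360.8 mm (water), 5.612 mm (lead) |
| straggling | Bohr variance, Ω² = 0.1569·(Z/A)·ρ·dx·(1−β²/2)/(1−β²) MeV² | additive over steps |
| nuclear removal | exp(−λ·ds) survival weighting | λ = 0.012 cm⁻¹ water, 0 lead |

Checked against the published PSTAR/ICRU-49 water tables, stopping power
and CSDA range agree within 2% at 50–350 MeV (tests vendor the table
values). Protons below 1 MeV deposit their remaining energy in place
(residual range < 25 µm, far below the 0.2 mm voxel pitch).

Numerical choices that matter:

* **Highland log term.** The 0.038·ln(t/X₀) correction is not additive
  over sub-steps; evaluated naively per 0.2 mm step it suppresses the
  accumulated scattering angle by ~25% in water. The engine therefore
  evaluates the log at the particle's cumulative traversed thickness, so
  the summed step variances reproduce the single-slab Highland value for
  the full path (the property is tested exactly). The transported lateral
  spread agrees with an independent Fermi–Eyges moment integration to 1%.
* **Correlated lateral displacement.** Each step samples the standard
  Fermi–Eyges pair: Δu = ds·θ₀(z₁/√12 + z₂/2), Δu′ = θ₀z₂. A pure angle
  kick would underestimate the lateral spread by up to √3.
* **Straggling clip.** The Gaussian straggling sample is clipped
  symmetrically to [0, 2·ΔE_mean]; a one-sided clip at zero would bias
  the mean loss upward by several percent at 350 MeV, where the per-step
  sigma is comparable to the mean loss.
* **Survival weighting.** Nuclear removal attenuates a per-proton
  statistical weight instead of killing protons at random (implicit
  capture). This keeps the narrow-cylinder tallies smooth at desk-scale
  proton counts and makes the removal exactly deterministic. The removed
  weight's kinetic energy is discarded from the scoring (tracked in the
  bookkeeping): the secondaries of a therapeutic-energy nonelastic event
  spread their energy over decimetre scales, so depositing any of it at
  the removal point would grossly mislocate it on the 0.2 mm tally scale
  — at 350 MeV a half-energy point deposit would rival the per-step
  ionisation loss itself. A local fraction remains available
  (`PhysicsOptions.nuclear_local_fraction`) for sensitivity studies.

## Transport and geometry

Fixed 0.2 mm steps along z (the spec'd maximum step; fixed steps give
per-step variances that are trivially additive and a deposit grid that
matches the voxel pitch). Deposits land at the step midpoint. The water
phantom is a cylinder of radius 200 mm and length 400 mm with its
entrance face at z = 0; broad-beam runs at 350 MeV extend it
automatically to contain the ~666 mm range. Protons leaving the phantom
radially or distally are terminated and their energy booked as exiting;
per run, entering = tallied + exiting + discarded closes to numerical
precision (tested to 0.1%).

The CECP collimator (lead, outer radius 200 mm) sits directly upstream
with its exit face flush with the phantom (the gap is unstated in the
study design; zero was chosen and is encoded in the geometry). Its length
is the CSDA range of the 250 MeV design energy in lead, rounded up to the
next mm, so on-axis protons of the design energy cannot punch through.
The source plane is 1 mm before the collimator entrance. Inside the
collimator, bore (r < R) and outside-world positions are vacuum; the lead
annulus applies the full condensed-history physics but its deposits are
not scored (the tallies are phantom dose only). Protons that scatter out
of the bore wall with degraded energy and re-enter the bore are the
model's stand-in for the collimator's scattered/secondary proton
component; actual nuclear secondaries (protons, neutrons) are not
produced, which is the main known gap for narrow-bore entrance dose.

## Scoring and metrics

* **Tallies**: 2D central slice (0.2 mm thick, 0.2³ mm³ voxels, lateral
  half-extent 40 mm), narrow (r = 0.5 mm) and wide (r = 200 mm) cylinders
  in 0.2 mm discs; Eq-style dose D = ΣδE/(ρV), reported per proton
  entering the phantom (1 MeV in one voxel = 2.003e−5 Gy).
* **Surface dose** = the first narrow disc (0–0.2 mm). **Target dose** =
  the narrow disc at the located peak for CECP/CEFP, or at the configured
  d_T for HEFP, whose elongated focal peak has no sharp maximum. The
  peak is located on the narrow profile for focused beams; for collimated
  beams on the wide profile, because a narrow bore's central-axis profile
  peaks at the entrance while the beam still stops at the Bragg depth.
* **σ_T** is the sigma of an unconstrained three-parameter Gaussian
  least-squares fit to the lateral slice profile at the target, summed
  over a ±0.4 mm depth window (five voxel rows). The window — and the
  3-bin (0.6 mm) moving average applied before the 80–20% penumbra
  crossing search — tame single-deposit noise at the package's default
  proton counts; both are parameters. FWHM = 2√(2 ln 2)·σ. The penumbra
  is the 80%→20% lateral distance, linearly interpolated and averaged
  over both sides; for an exact Gaussian it equals 1.126σ (tested in
  closed form).
* Plot-style normalisation follows the study conventions: 2D slices to
  max 1; longitudinal curves per entering proton, then group-scaled so
  the highest curve peaks at 1.

## Default problem sizes

The package's working point is 2×10⁵ protons per scenario (10⁵ at
350 MeV broad-beam, whose track length is ~4× longer), which resolves
peak depths to a fraction of a mm and dose ratios to a few percent in
minutes on one core. The collimated Table-column runs use 10⁶ source
protons because only ~6% survive the R = 2 mm bore into the phantom.
Monte Carlo standard errors for the scalar narrow-profile metrics are
available by splitting a run into 10 independent sub-batches
(`run_table1(..., n_error_batches=10)`); fit-based metrics are computed
on the merged tally only, since sub-run fits at a tenth of the
statistics are unstable.

## Known limitations

* No explicit nuclear secondaries (protons, neutrons, fragments), no
  delta-ray transport, no LET or RBE scoring: the removal-plus-local-
  deposit model preserves the fluence loss and roughly half the energy
  redistribution of nonelastic events but not their spatial spread. For
  narrow collimated beams this under-represents the secondary-proton
  entrance-dose elevation and the collimated beam's central-axis dose at
  depth.
* The Highland kick is a single Gaussian. The reference-quality Molière
  distribution has a slightly narrower core and a single-scattering
  tail; a Gaussian-core engine therefore spreads the core a few percent
  wider and yields slightly flatter lateral shoulders. The transported
  lateral sigma agrees with the engine's own Fermi–Eyges prediction to
  1%, but for the collimated scenario it leaves the central-axis dose at
  the Bragg peak ~5–10% below the reference-quality value, and the
  80–20% penumbra runs ~0.2 mm wide of the Gaussian closed form on the
  fitted sigma.
* Collimator transmission (the count of degraded edge-scattered protons
  entering the phantom, ~17% above the direct-bore count at R = 2 mm) is
  the least constrained quantity: it sets the per-proton normalisation
  of the collimated column and has no published reference value.
* The quadrupole feasibility estimate treats a single thick-lens
  quadrupole in its focusing plane; no doublet/triplet matching, fringe
  fields, dispersion or chromatic effects.
* Synthetic beams are ideal Gaussians: no halo, no σ_x ≠ σ_y asymmetry,
  no spot-scanning time structure, no FLASH dose-rate effects. Passing
  tests demonstrate fidelity to the stated analytic models, not to any
  specific clinical beamline.
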