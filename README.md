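# protonfocus

A lightweight condensed-history Monte Carlo for comparing three ways of
producing narrow proton beams for high-precision radiotherapy:

* **CECP** — conventional-energy (100/150 MeV) beams shaped by a **lead
  collimator** of bore radius *R*;
* **CEFP** — conventional-energy beams **magnetically focused** so their
  waist coincides with the Bragg peak;
* **HEFP** — high-energy (350 MeV) *shoot-through* beams whose Bragg peak
  lies beyond the phantom, so the dose peak is created purely by focusing.

The package is aimed at medical-physics researchers who want a fast,
seeded, fully scriptable sandbox for beam-shaping trade-off studies —
dose profiles in a water phantom, target-to-surface dose ratios, spot
sizes and penumbras — without running a full Monte Carlo stack.

## Model

A beam is a round bivariate Gaussian in each transverse phase-space plane
(u, u′), parameterised by the Twiss parameters α, β, γ = (1+α²)/β and the
RMS emittance ε:

    Σ = ε [[ β, −α ], [ −α, γ ]],    σ = √(εβ)

Choosing the entrance size σ₀, the focusing strength α₀ and the target
depth d_T fixes the entrance state through the waist relation
d_T = α₀β₀/(1+α₀²); in vacuum the spot at the waist is demagnified by
σ_T/σ₀ = 1/√(1+α₀²). Protons are transported through a cylindrical water
phantom (r = 200 mm, length 400 mm, entrance at z = 0) in fixed 0.2 mm
steps; per step the engine applies

* Bethe mean energy loss plus Gaussian (Bohr) straggling,
* a Highland multiple-Coulomb-scattering kick with the correlated
  Fermi–Eyges lateral displacement,
* nuclear removal of primaries as deterministic survival weighting
  (exp(−λ·ds), λ = 0.012 cm⁻¹ in water).

Dose is scored per the study geometries: a 0.2 mm central slice of
0.2³ mm³ voxels, and narrow (r = 0.5 mm) / wide (r = 200 mm) cylinders in
0.2 mm discs, D = ΣδE/(ρV), normalised per proton entering the phantom.
The collimated scenario adds a lead collimator (outer radius 200 mm,
length ranged for 250 MeV protons) directly upstream of the phantom, with
the parallel Gaussian source 1 mm before its entrance face.

## Worked example

The three-beam comparison at a ~155 mm deep target (CECP: 150 MeV,
R = 2 mm; CEFP: 150 MeV, α₀ = 20; HEFP: 350 MeV, α₀ = 20):

```bash
protonfocus table1 --n 200000 --seed 11 --batches 0 --out results/
```

prints (doses in nGy per proton entering the phantom; the collimated
column automatically runs 5× the proton budget because only ~6% of its
protons survive the bore; ~10 min on one core):

```
                  CECP   CEFP   HEFP
beam_energy_mev    150    150    350
target_depth_mm    156    153    155
surface_dose_ngy  7.15 0.0561 0.0337
target_dose_ngy   4.69   5.56   3.48
tsdr             0.656   99.3    103
fwhm_mm           7.25   7.35   3.39
sigma_t_mm        3.08   3.12   1.44
penumbra_mm       3.84   4.14   1.58
```

Reading the table: the collimated beam wastes most of its protons in the
collimator and scatters the survivors, so its central-axis dose at the
Bragg peak is *lower* than at the skin (TSDR < 1) — collimation alone
cannot deliver a narrow beam to a deep target. The focused 150 MeV beam
reaches the same depth with a ~100× lower surface dose (TSDR ≈ 100), and
the shoot-through beam adds the smallest spot (σ_T ≈ 1.4 mm) and sharpest
penumbra, at the price of dose behind the target. Single-scenario
profiles and R / α₀ sweeps are available as `protonfocus profile` and
`protonfocus sweep`, or from Python:

```python
from protonfocus import SweepSpec, run_sweep
frame = run_sweep(SweepSpec(scenario="CEFP", values=(5, 11, 20),
                            energy_mev=150.0, d_T_mm=155.0, seed=1))
print(frame[["value", "tsdr", "sigma_t_mm", "sigma_t_vacuum_mm"]])
```

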