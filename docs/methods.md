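# Methods

`hifusim` simulates the thermal lesions produced by single pulses and
pulse groups of a 3 MHz spherical-cap HIFU transducer (curvature radius
38 mm, aperture 56 mm, f-number 0.68, rectangular cutout for a confocal
imaging probe) in layered media: a water standoff, an optional
superficial-tissue layer, and liver. The pipeline is

1. linear steady-state beam (or an imported field),
2. volumetric heat deposition with energy conservation, an
   absorption-to-attenuation ratio `A` and a lateral defocusing blur
   `sigma_defoc`,
3. explicit finite-difference solution of a generalized Pennes bioheat
   equation with temperature-dependent specific heat and dose-dependent
   perfusion, coupled to an equivalent model of the boiling bubble
   cloud,
4. CEM43 thermal-dose lesion extraction and morphometry, plus
   calibration and errors-in-variables regression analyses.

## Acoustic stage

The cap is discretized into quasi-uniform equal-area ring elements
(default pitch one third of a wavelength; the preset configurations use
half a wavelength, which changes the focal pressure by less than
0.05 %, as the convergence test shows). Two evaluation paths exist:

* **Direct Rayleigh summation** over all voxel/element pairs, with
  straight-ray per-layer amplitude attenuation and phase slowness. It
  matches the closed-form focused-cap axial solution to better than 1 %
  in water and is used for oracle checks.
* **Hybrid production path**: Rayleigh summation onto the grid entrance
  plane over a wide lateral window (the converging beam is much wider
  than the simulation box), then one-way angular-spectrum marching
  plane by plane with the complex wavenumber of the local layer.

Nonlinear propagation is deliberately absent: harmonic generation
steepens and localizes the heat deposition in ways a linear model
cannot reproduce, and its net effect is folded into the calibrated `A`
(see Calibration). Externally computed fields (e.g. from a nonlinear
solver) can be imported from an HDF5 container instead.

Intensity on the production grid is computed **spectrally** (the
gradient operators are `i k` in the angular spectrum), because
centered differences at the carrier wavenumber on a 200 µm grid lose a
factor `sin(k dx)/(k dx) ≈ 0.31` — a three-fold error in the deposited
power. The centered-difference route (`intensity_from_pressure`)
remains for imported fields and is accurate at fine sampling.

Pressure is normalized so that the radiated source power
(`½ ρ c u₀² S`) equals the requested acoustic power. Two axial power
profiles are kept:

* the side-flux-compensated box profile `P(z)` — its `-dP/dz` is
  exactly the power absorbed inside the box per voxel layer, which is
  what the conservative heat source distributes. On a box smaller than
  the beam this quantity is pure accounting and can be negative;
* the true beam power per plane, evaluated on the wide window by a
  Parseval sum over the propagating spectrum — this is what "power
  reaching the plane `z_shield`" means for the boiling model.

Known limitations: no refraction-free path exists through a layered
stack — the straight-ray and angular-spectrum phases both reproduce
the flat-interface focal shift (~2 mm toward the transducer with the
tabulated water/liver sound speeds) and the associated spherical
aberration, which axially elongates the focal lobe; transmission
coefficients at the interfaces are neglected (the water/liver
intensity transmission is 99.7 %); the transducer surface velocity is
assumed uniform.

## Heat deposition

`Q_PWlin = 2 α_att |p|²/(2 ρ c)` is the local plane-wave form. The
energy-conserving form spreads each voxel layer's absorbed power
(from the box `P(z)`) across the plane proportionally to `|p|²`; its
volume integral telescopes exactly to `P(z_min) − P(z_max)`. On the
production beam the two agree to ~1 % (median 0.3 %), mirroring the
negligible differences reported for this comparison. Artefactual
negative-loss layers are clipped to zero and their magnitude logged.
The naive `−∇·I` is exposed as a diagnostic only; it is locally
negative on focused beams.

The deposition is multiplied by `A` (fraction of attenuation that is
absorption) and convolved per xy-plane with a unit-mass 2D Gaussian of
standard deviation `sigma_defoc` (tissue-heterogeneity defocusing);
each plane is rescaled to its pre-blur total so the blur redistributes
but never loses power. Focus steering is a lateral translation of the
source (bilinear, sub-voxel), with out-shifted power dropped.

## Thermal stage

Generalized Pennes equation, explicit Euler in time, 7-point centered
Laplacian, Dirichlet 37 °C boundaries (the heated region is several
millimetres from every face at the reference grid size):

`ρ_t C_t(T) ∂T/∂t = k_t ∇²T + ω_b(D) ρ_b C_b (T_b − T) + Q`

* `C_t(T) = C₀ + C_denat(T) + C_boil(T)`. The excess profiles are
  truncated Gaussian bumps whose *integrals* are the physical
  contract: 22 kJ/kg for protein denaturation (bump at 60 ± 6 °C) and
  `0.75 × 2260` kJ/kg — tissue water fraction times the vaporization
  enthalpy of water — for progressive boiling over 37–140 °C. The
  boiling bump is centered at 105 °C with σ = 8 °C so that 99.4 % of
  the vaporization enthalpy lies above `T_boil` = 85 °C: vaporization
  at 60–80 °C would be unphysical, and the 85 °C threshold is chosen
  to coincide with where the specific-heat variation engages.
* Perfusion shuts down linearly with thermal dose,
  `ω_b(D) = max(1 − D/14400, 0) ω_b(0)`, vanishing at the destruction
  threshold.
* Blood parameters (not tabulated): ρ_b = 1050 kg/m³,
  C_b = 3800 J kg⁻¹ K⁻¹, T_b = 37 °C, configurable.
* Stability: `dt_max = dx² ρ C₀/(6 k)` = 44.7 ms for liver at 200 µm.
  The default `dt` = 40 ms respects it; a 50 ms step runs with a
  warning (the rising `C_t` relaxes the limit at high temperature).
* The specific heat is evaluated at the pre-step temperature
  (explicit scheme); the dose update uses the post-step temperature
  and runs at every step, including cooling intervals.
* Water and superficial-tissue thermal properties are not tabulated in
  the source material; standard values are used (water 4180 J kg⁻¹ K⁻¹
  / 0.6 W m⁻¹ K⁻¹, superficial tissue 3600 / 0.5) — only liver is
  heated appreciably in the reference exposures.
* A fused numba kernel accelerates the step when numba is available; a
  pure-numpy step is the reference implementation and the two are
  asserted equal.

## Equivalent boiling model

Above `T_boil` a vapor bubble cloud reflects most of the beam — a
regime no tractable acoustic solver captures — so the deposition is
rewritten by rules with four calibrated knobs (shipped at their
literature values: `R_SE` = 2.5 mm, `η_intercept` = 0.31, `W₊` = 10,
`θ_cone` = π/18):

* cloud `B` = {T > T_boil} (strict); deposition inside `B` is zeroed
  (energy spent on mechanical/thermal damage);
* shielding `r_shield` = max over xy-planes of the in-cloud fraction
  of the deposited power (ties resolve to the most proximal plane);
* enhanced zone `H` = dilation of `B` by the Euclidean ball of radius
  `R_SE` (computed via the exact distance transform on a cropped box);
* redistributed power `P_H = η_intercept · r_shield · P(z_shield)`,
  with `P(z_shield)` the true beam power through that plane;
* weights on `H \ B`: `W₁` = inverse distance to `B` (voxel units);
  `W₂` = 1 up to `z_shield`, `r_shield` beyond; `W₃` proportional to
  the unmodified source when the cloud top is locally convex, and on
  concave tops uniform with a `W₊` boost inside a pre-focal cone of
  half-aperture `θ_cone`;
* `Q_boil = P_H W₁W₂W₃ / Σ(W₁W₂W₃)`, so the redistributed power
  integrates to `P_H` exactly, every step; it is *added* to the
  cloud-zeroed base source (replacement is never stated in the model's
  description, and replacement would make boiling reduce net heating,
  contradicting the observed negative size-vs-onset slopes).

Convexity compares the global minimum-z of `B` with the minimum-z on
the focal column. The reference point is the pulse's *nominal* focus
(trajectory center plus pulse offset), not the instantaneous steering
position: the hot spot always trails a moving focus (thermal lag), so
an instantaneous reference misclassifies the cloud as concave at
essentially every step and the model locks into the concave regime;
with the nominal reference the two regimes alternate as expected. For
stationary pulses the choices coincide.

An optional flag additionally attenuates the base source beyond
`z_shield` by `(1 − r_shield)`; it is off by default because the
model as originally described modifies only the in-cloud source and
adds `Q_boil`
(the residual downstream double counting is part of the equivalent
model). Residual bubble clouds from previous pulses carry no special
treatment: the cloud is always re-derived from the instantaneous
temperature.

## Dose, lesion, HEM

CEM43 dose `D = ∫ 0.5^(43−T) dt` with the single base 0.5 at all
temperatures (the conventional R = 0.25 branch below 43 °C is *not*
applied — fidelity to the model as displayed); destruction threshold
14 400 s (inclusive). The lesion is the largest 6-connected component
of the destroyed mask; sizes are bounding-box extents (the manual
segmentation this approximates does not prescribe a caliper rule).
Boiling onset is the first `T_boil` crossing of the peak temperature,
linearly interpolated between steps. The hyperechoic-mark (HEM)
analogue is the cumulative boiling mask; its area is counted in the
central xz plane through the focus (the imaging plane), one voxel
thick, with a projected variant behind a flag.

## Calibration and analysis

Two-stage calibration against the experimental boiling-onset medians:
an inner bisection adjusts `sigma_defoc` to the stationary 4-s onset
(3.0 s), an outer bisection adjusts `A` to the moving 12-s onset
(8.1 s), exploiting the verified monotonicities (onset decreases with
`A`, increases with `sigma_defoc`, and `sigma_defoc` affects
stationary pulses much more than moving ones). Tolerance 0.05 s.

With the built-in linear beam the calibration lands at `A ≈ 0.23`,
`sigma_defoc ≈ 258 µm` (the reference values obtained with a nonlinear
acoustic stage are 0.37 and 290 µm). The low effective `A` reflects
everything the linear stage idealizes — uniform cap drive, no
transmission losses, no smoothing from a wave-solver discretization —
and `A` absorbs it by construction; recovering the literature `A` is
explicitly not a goal, since its value depends on the acoustic stage
it was calibrated with.

Lesion-size-vs-onset slopes: the onset is varied the way it varies in
the experiments — through local defocusing — by scaling `sigma_defoc`
around its calibrated value; each run yields (onset, extents) and a
closed-form Deming fit per axis with variance ratio `(σ_y/σ_x)²` from
the stated measurement uncertainties (0.1 mm, 0.1 s), with a seeded
nonparametric bootstrap for the 90 % CI. All slopes are negative
(later boiling, smaller lesion).

## Reference exposures and problem sizes

All reference runs use the 71×71×111 grid at 200 µm (focus centered
laterally, at 60 % of the z extent — its position relative to the grid
is otherwise unconstrained), `dt` = 40 ms:

* stationary 4-s pulse, 43.3 W, 16 mm deep in liver immersed in water
  (ex vivo; no superficial layer);
* 12-s pulse, 49 W, 14 mm below the skin, focus on a 1.3-mm circle
  (1 s/revolution; the angular speed is unreported), 2 mm superficial
  layer (in vivo);
* 19 pulses of the 4-s exposure in vivo on a hexagonal pattern (rows
  of 3/4/5/4/3) with 1.8 mm × 1.6 mm spacing, 22 s inter-pulse
  cooling, temperature and dose carried across pulses. The exact
  pattern of the 19 positions is unreported; hexagonal packing matches
  the stated spacings and overlap.
* 30 s of cool-down precede the final dose evaluation (dose accrual is
  essentially complete by then).

## What the synthetic generator does and does not show

The fast test fixture is a separable-Gaussian focal beam with
plane-wave intensity on a 31×31×41 grid at 0.4 mm. It exercises every
thermal/boiling/dose code path (onset monotonicities, regime
switching, energy bookkeeping, lesion growth) at interactive speed,
but it has no sidelobes, no aberration pedestal and no layered
attenuation, so quantitative agreement with the reference lesion
sizes is only meaningful for the full beam pipeline.

Passing the full-pipeline checks shows the *calibrated* model
reproduces the reference onsets, the composite-lesion height and the
regime phenomenology. It does not show the linear beam substitutes for
a nonlinear acoustic stage: the bubble-cloud area remains
hypersensitive to the spatial sharpness of the deposition, because
after onset-matched calibration the focal region sits on a temperature
plateau just below `T_boil` whose conversion costs almost no energy —
the simulated 12-s cloud area comes out several times the reference
value, and the unitary 4-s lesion cross-section overshoots by ~40 %.
The boiling-model knobs could absorb this only by recalibration
against 3D lesion shapes, which is out of scope here.
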