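# Methods

## Scope and model

`mcbacksim` simulates steady-state photon transport in a semi-infinite
homogeneous turbid medium (surface at z = 0, medium filling z ≥ 0, no
lateral or bottom boundaries) and records the diffusely reflected flux
on the surface as a radial intensity profile around the incident point.
The intended physical system is a laser-backscattering vision setup:
a narrow beam (radius ~0.5–1 mm), a camera above the surface in the
normal direction, intensity averaged over concentric one-pixel-wide
rings.

Photon packets carry a continuous weight (implicit capture).  The
five-step trajectory — launch, move, bounce, absorb, scatter — follows
the conventions of the MCML family of codes, with two deliberate
departures described below (oblique launch, Lambertian scoring).

### Launch

Weight starts at 1 − r_s with r_s = ((n−1)/(n+1))², the normal-incidence
specular reflectance: specular loss is a one-time weight deduction, not
a separate photon.  r_s is applied regardless of the incident angle,
also for tilted beams; for the 10–20° range the error against the
angle-dependent Fresnel value is below 1% of r_s.  Launch position is
uniform over the beam disc (r_b·sqrt(U), 2πU in polar form); for a beam
tilted by φ₁ the y coordinate (tilt axis) is divided by cos φ₂, where
φ₂ = asin(sin φ₁/n) is the refracted angle — the elliptic footprint of
an oblique beam, using the in-medium angle for the stretch.  Initial
direction is (0, sin φ₂, cos φ₂); the tilt plane is y–z.

### Move, bounce, absorb, scatter

* **Move**: step s = −ln ξ/μt, μt = μa + μs; ξ guarded away from 0.
  A step ending at z < 0 has crossed the surface.
* **Bounce**: position and direction are mirrored (z ← −z, w ← −w) at
  the full-step endpoint.  If the direction cosine w exceeds the
  critical-angle cosine sqrt(1 − 1/n²), the Fresnel transmittance
  (unpolarized average) of the weight escapes: it is added to the total
  diffuse reflectance rd and — multiplied by the cosine of the external
  exit angle (Lambertian correction, modelling a normal-viewing
  camera) — scored into the ring at radius round(r/rpx).  The
  Lambertian cosine is computed through the trigonometric chain
  |w| → n·sqrt(1−w²) → sqrt(1−·²), with a failsafe that zeroes the
  factor if the intermediate square exceeds 1 (unreachable past the
  critical-angle check but retained as a numerical guard).  Escapes
  beyond the observed radius count toward rd but are not binned.  Both
  the Lambertian-weighted tally (`heat`) and the raw escaped weight per
  ring (`heat_rd`) are kept.
* **Absorb**: weight is multiplied by the transport albedo
  a = μs/(μs+μa); the complement is tallied as absorbed energy.
  Packets are terminated by a deterministic cutoff once the weight
  falls below the limiting energy level (default 10⁻⁹), with the
  residual scored as absorbed — exact pre-allocation bound
  maxlen = round(ln limit / ln a) + 1 (banker's rounding) and a bias
  below `limit` per photon.  An optional Russian-roulette mode
  (survival 0.1, weight ×10) is available but off by default; with it,
  the per-run energy balance holds only in expectation.
* **Scatter**: deflection cosine from the Henyey–Greenstein inversion
  (uniform on [−1,1] at g = 0); azimuth by rejection sampling on the
  unit disc from (rx1, rx2) ∈ U(−1,1)², avoiding trig calls; standard
  local-frame rotation, with the degenerate near-vertical update at
  |w| > 0.99999.

Energy is conserved exactly in the default mode: specular + rd +
absorbed = launched weight to ~10⁻¹² relative per run (tested at 10⁻⁶).

### Random numbers

All randomness derives from one root seed through numpy
`SeedSequence`/PCG64.  Launch coordinates come from a dedicated
sub-stream; the scalar reference path gives each photon five private
sub-streams (step length, survival, two azimuth coordinates, HG
deviate) derived from (seed, photon index), so any subset of photons
can be re-simulated independently in any order.  Streams are
pre-generated in blocks per stream, which is numerically identical to
on-demand draws in consumption order (each stream owns its generator);
this equivalence is tested.  The compiled kernel draws on demand from a
single run-level generator in photon-major order — deterministic for a
fixed seed but on a different stream layout, so the two engines agree
statistically rather than bit-for-bit (also tested).

### Engines

The scalar Python path (`engine="python"`) is the readable reference
implementation; the numba kernel (`engine="kernel"`, default)
reproduces the same physics at production photon counts (10⁶ photons of
the isotropic phantom in ~20 s on one CPU; the forward-scattering
parameterization is ~8× slower because its albedo of 0.9958 implies
~5000 interaction events per packet).

## Profile normalization

Ring k of width rpx collects radii that round to k, i.e.
[(k−½)rpx, (k+½)rpx).  Two area conventions are provided:

* `edge` (default): areas from the true bin edges, so
  flux × area × N exactly inverts the tally; bin 0 is a disc of radius
  rpx/2.
* `inner`: the bin-label radius k·rpx is treated as the ring's inner
  edge, A = π(2r·dr + dr²) — the convention of vision-system
  post-processing pipelines, which distributes each ring's flux over a
  half-bin-shifted annulus and damps the central bins (bin 0 by 4×).

Flux is divided by the number of launched photons so that profiles from
different N are comparable, giving cm⁻² per launched photon — the same
scale on which the diffusion reference is defined.

## Diffusion reference and validation statistics

The closed-form reference is the Farrell–Patterson–Wilson dipole: an
isotropic source at depth z0 = 1/(μa+μs′) and its image above the
extrapolated boundary at z0 + 2zb, zb = 2AD, D = 1/(3(μa+μs′)), with
the internal-reflection parameter A from the empirical polynomial
ri ≈ −1.440/n² + 0.710/n + 0.668 + 0.0636n.  A single-source variant
("point", after Jacques) is available for sensitivity analysis.  This
is the canonical spatially resolved steady-state model for this
geometry; which exact variant a given external reference used is rarely
printed, so comparison statistics should be read with model-choice
tolerance in mind.

`validate_against_diffusion` compares the Monte Carlo profile and the
model on the MC grid after dropping the central bin (the incident-point
disc, where the vision system saturates and the diffusion approximation
is least valid; configurable).  Pearson correlation is scale-invariant;
RMSE is reported on three scalings — absolute per-photon cm⁻² flux,
0–1 min–max normalized, and unit-sum — because published comparisons
rarely state their scaling.  The default validation protocol uses the
Lambertian-corrected profile under the `inner` area convention, i.e.
the profile a vision-system pipeline would produce.

For the solid reference phantom (μa = 0.1056 cm⁻¹, μs′ = 2.529 cm⁻¹,
n = 1.35, 10⁶ photons, 0.05 cm bins to 3 cm) this protocol gives a
correlation of ≈ 0.973 for the isotropic parameterization and ≈ 0.951
for the forward-scattering one (g = 0.9, μs = 25.29 cm⁻¹): both
parameterizations share μs′, but the near-field profile depends on g
and μs separately, so the isotropic run fits diffusion theory better —
the expected similarity-relation breakdown near the source.

### Effective attenuation from the profile tail

μ_eff = sqrt(3μa(μa+μs′)) governs the exponential tail, but a naive
log-slope of ln(r²·R) over 1–3 cm badly underestimates it: at these
radii the image source (height z0 + 2zb ≈ 1.9 cm for the phantom)
decays much more slowly than the buried source and dominates the
visible tail; even the analytic dipole model has a local slope of only
≈ −0.6 cm⁻¹ there against μ_eff = 0.914 cm⁻¹.  `fit_mu_eff` therefore
fits the full two-source radial kernel with known (z0, zb), leaving
only amplitude and μ_eff free; on the analytic profile this recovers
μ_eff exactly, and on the simulated phantom profile to within ~2%.

## Conservative-limit behaviour

With a matched boundary (n = 1, no specular or Fresnel reflection) and
vanishing absorption, all launched weight eventually escapes and
rd → 1.  The approach is slow: the deficit 1 − rd scales as
sqrt(μa/μtr) (deep random walks absorb before returning; diffusion
theory gives ≈ (4/√3)·sqrt(μa/μtr)), so at μa = 10⁻⁴ μs the simulator
and theory both give rd ≈ 0.97, and μa = 10⁻⁶ μs is needed to pass
rd > 0.99.  The test suite checks the limit at 10⁻⁶.

## Problem sizes and numerical choices

* Validation runs use the phantom's stated conditions: 10⁶ photons,
  beam radius 0.05 cm, limit 10⁻⁹, 3 cm window, 0.05 cm/pixel; the
  isotropic correlation/RMSE statistics average three seeds.
* Shot-noise scaling (per-bin CV ∝ 1/√N) is checked across
  N ∈ {10⁴, 10⁵, 10⁶} with four seeds each, on the 0.5–1.5 cm band.
* maxlen rounding is round-half-to-even; the difference against
  round-half-up is at most one event and immaterial at limit 10⁻⁹.
* μa = 0 is allowed for limiting-case studies; the albedo-based
  trajectory bound then degenerates and a hard cap (default 10⁶
  events) applies.
* Ring index round-half-to-even ties are measure-zero events of the
  continuous radius distribution.
* The step-length deviate is clamped to the smallest positive double
  when a generator returns exactly 0.

## What the tests do and do not show

All validation is against synthetic configurations and a closed-form
model: passing tests demonstrate internal consistency (energy balance,
distributional correctness of the samplers, determinism), agreement
with diffusion theory at diffusion-valid radii, and reproduction of the
similarity-relation behaviour.  They do not validate against measured
camera images of physical samples — real measurements add detector
response, saturation near the incident point, background light and
surface roughness, none of which are modelled.  Multi-layer media,
time-resolved transport and polarization are out of scope.
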