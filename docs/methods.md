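# Methods

This note documents the models, numerical choices and limitations of
`layerlut` in enough detail to audit or re-derive them.

## Geometry and transport

Media are stacks of plane-parallel layers over a semi-infinite bottom layer;
z increases downward from the surface, the source is a pencil beam entering
at the origin, and the detector is an annulus of radius `sds` (default 25 mm)
and half-width `detector_half_width` centred on the source.  The in-vivo
preset is skin (1 mm, tone-dependent μa/μs′), adipose (0–6 mm) and muscle;
the phantom preset mirrors a stackable silicone/intralipid phantom set.
Classification of skin tone uses the individual typology angle: ITA > 41° is
light, ITA < 10° is dark, and the closed interval [10°, 41°] — including both
boundary values, which the threshold definitions leave open — is medium.

Photons propagate MCML-style: exponential steps in optical depth, carried
across layer boundaries; unpolarized Fresnel reflection/refraction at index
steps (boundaries between index-matched layers are crossed without consuming
a random number, which makes splitting a layer into identical sublayers an
exact photon-by-photon no-op — a tested invariant); Henyey–Greenstein
scattering with per-layer anisotropy g and μs = μs′/(1−g).  Per detected
photon the engine records per-layer pathlengths `L_j` (mm) and per-layer
dimensionless momentum transfer `Y_j = Σ(1−cos θ)` accumulated in the layer
where each scattering event occurred.  A weight ledger (specular, escaped,
absorbed, path-capped, roulette) balances the launched weight to better than
1e-6 relative and is asserted in tests.

**Reduced (similarity) mode.**  `SimConfig(phase_mode="reduced")` replaces
Henyey–Greenstein sampling with isotropic scattering at μs = μs′.  By the
similarity relation this preserves the diffuse reflectance at ρ ≫ 1/μs′ and
the expected momentum transfer per unit path (μs′·L in both modes), while
costing ~10× fewer scattering events per photon.  The two modes agree on
detected counts and phase within Monte Carlo error for the media used here;
a residual few-percent amplitude difference appears for sub-millimetre
highly scattering layers, where similarity is least accurate.  Desk-scale
runs (tests, the acceptance script) use reduced mode; `"hg"` is the default
for production LUTs.

**Termination.**  `max_total_path` (default 3000 mm; 1800 mm in desk-scale
runs) caps the trajectory length; under Beer weights the discarded tail
carries relative weight exp(−μa·L_max) ≲ 1e-4 for μa ≥ 0.005 mm⁻¹.
`max_depth` (default 150 mm) kills photons that have diffused too deep to
return within the path cap (a depth-z excursion costs ≳ 3 z² μs′ of path to
return).  An optional `max_radius` absorbing side boundary emulates finite
slabs or bounded simulation volumes; it is off (infinite) by default and its
effect on the 25-mm-SDS observables was measured to be negligible down to a
35 mm radius.  Russian roulette (threshold 1e-4, survival 0.1) only engages
when absorption is baked in.

## White Monte Carlo and forward observables

Propagation is absorption-free by default; every layer's μa is applied post
hoc as `w_s = exp(−Σ_j μa_j L_{s,j})`.  This is exact (not approximate) for
continuous absorption weighting, because scattering trajectories are
independent of μa, and it means one simulation per bottom-layer μs′ node
serves the whole μa axis.  Equivalence with baked-in absorption is a tested
property.

* FD reflectance: `t_s = Σ_j n_j L_{s,j} / c`;
  `R(ω) = Σ_s w_s e^{−iω t_s}`, normalized per launched photon per mm² of
  detector area.  The public path bins t into a TOF histogram (default 10 ps
  bins to 12 ns) and Fourier-transforms it; the builder uses the equivalent
  direct phasor sum (the zero-bin-width limit; both routes are tested to
  agree).  The reported phase is `−arg R`, positive and increasing with
  modulation frequency, μs′ and ρ.
* DCS: `G1(τ) = Σ_s w_s exp(−2τ Σ_j k0_j² BFi_j Y_{s,j})` with
  `k0_j = 2π n_j/λ` (per-layer n by default, a bulk override available),
  normalized to `g1 = G1/G1(0)` — the normalization convention cancels there.
  `g2 = 1 + β g1²`.  The DCS laser (850 nm) lies outside the tabulated
  wavelengths; the 830 nm optical properties drive its transport by default
  (configurable).

## Diffusion oracles

For homogeneous semi-infinite media the package bundles extrapolated-boundary
diffusion solutions used as *independent* validation oracles, never as the
primary forward model: the FD solution with complex absorption
`μa + iω n/c`, evaluated as the standard fluence+flux hybrid with boundary
coefficients obtained by integrating the internal Fresnel transmission over
the exit hemisphere (for n = 1.4 they evaluate to ≈0.118 and ≈0.306); and the
correlation-diffusion g1 via the dynamic-absorption substitution
`μa → μa + 2 μs′ k0² BFi τ`.  At 25 mm SDS the Monte Carlo engine matches
these within ~1 % in amplitude, < 0.5° in phase, and < 0.01 RMS in g1 at 10⁶
photons; the acceptance gates are 5 % / 1° / 0.02 RMS.  During development
the layered engine was additionally cross-checked against an exact two-layer
FD diffusion solution computed in Hankel space, agreeing within ~10 % in
amplitude and 5° in phase in a strongly layered regime where the diffusion
approximation itself is stressed.

## LUTs and inversion

Axes follow the tabulated ranges: bottom-layer μs′ 0.1–1.0 mm⁻¹ at 0.1 mm⁻¹
nodes, densified by linear interpolation to 0.001 mm⁻¹ (FD) and 0.05 mm⁻¹
(DCS); μa 0.01–0.2 mm⁻¹, evaluated on a 0.001 mm⁻¹ grid by reweighting
(effectively continuous and free); BFi 0.1–40 ×10⁻⁶ mm²/s.  Ten
independent-seed repeats per node are pooled by default (seeds derive from a
`SeedSequence` of the base seed and the node index, so builds are exactly
reproducible).  FD interpolation acts on the real and imaginary parts of the
complex reflectance, not on amplitude/phase.  The DCS LUT stores a compressed
per-node photon record (upper-layer-weighted exit weight, bottom pathlength,
upper and bottom decay-rate coefficients), so g1² curves for *any* BFi and
any bottom μa are evaluated analytically at query time; μs′ enters by linear
interpolation of g1² between bracketing nodes, and β is applied at query
time, never baked in.  LUTs persist to HDF5 with a schema version and a
SHA-256 content hash verified on load.

FD inversion minimizes `(Δln A/σ_A)² + (Δφ/σ_φ)²` (σ = 1 by default; the
measurement enters through an optional complex calibration factor) over the
dense grid, ties broken toward the smallest μa then μs′, boundary hits
flagged.  The single-frequency objective has a shallow valley along which a
sub-grid μa offset trades against a many-step μs′ offset, so the plain grid
argmin resolves μa only to its grid step; `refine="continuous"` follows the
argmin with a bounded least-squares on the bilinearly interpolated LUT and
recovers off-grid optima to high precision.  It is used wherever recovered
values must resolve sub-grid shifts (sensitivity analysis, round-trip
checks).  DCS inversion least-squares over BFi (41-point log scan plus
bounded golden-section refinement) within a τ window where the measured
g2 − 1 exceeds 1 % of β; β is fixed or profiled out analytically; g2 values
below 1 − 0.05 raise a data-quality error.

## Hemodynamics

The two-wavelength Beer–Lambert system uses base-10 molar extinction
coefficients (the ln 10 factor is applied explicitly) over fixed water
(62.5 %) and lipid (20 %) backgrounds; coefficients are packaged as a CSV
data table so alternative literature values can be swapped without touching
code.  Negative concentrations are returned flagged, not clipped.  StO2 is
the oxygenated fraction of total [Hb+Mb] in percent.  MRO2 =
(HGB/mw_Hb)·BFi·(SpO2 − StO2)/venous-ratio with defaults HGB 14/16 g/dL
(female/male), SpO2 0.98, venous ratio 0.75, mw 64 500 g/mol; its pseudo-units
(mol·mm²·L⁻¹·s⁻¹) inherit BFi's area/time scale and are meaningful in ratio
and trend.

## Sensitivity analysis

Each of eight assumed upper-layer parameters (skin thickness 10 %, skin μa
75 %, skin μs′ 25 %, adipose thickness 10 %, adipose μa 30 %, adipose μs′
30 %, skin BFi 30 %, adipose BFi 25 % — magnitudes set by reported
population variability) is perturbed one at a time, one-sided positive and
multiplicative, in the forward medium; the perturbed forward data are
inverted with LUTs built from the *unperturbed* medium, and
`S = ((recovered − truth)/truth × 100 %)/perturbation %` is averaged over ≥ 3
independent-seed replicates (2 at desk scale) with a standard error.  The
evaluation point is 1 mm adipose with a representative resting-muscle truth
(μa 0.02 mm⁻¹, μs′ 0.6 mm⁻¹ at 830 nm, BFi 5×10⁻⁶ mm²/s — interior of every
axis); sensitivities in %/% depend on this normalization point, which the
source tables specify only as a range.

## Synthetic data generator

The generator emulates two study designs.  (1) Phantom sweeps: stacked
skin/adipose mimics over a silicone (FD) or intralipid (DCS, β = 0.45)
bottom, forward-modelled by the layered MC with embedded ground truth.
(2) Breathing protocols: baseline 60 s / load 60 s / recovery ≥ 60 s sampled
at 0.5 Hz, with muscle oxy/deoxy [Hb+Mb] and BFi following a
smoothed-trapezoid load response (10 s cosine ramps — the transient shape is
phenomenological), converted to per-frame (μa730, μa830, BFi), pushed through
the subject's multi-layer LUTs, and corrupted with seeded noise:
multiplicative Gaussian on FD amplitude (1 %), additive on phase (2 mrad),
additive heteroscedastic on g2 (1e-3, shrinking ∝ τ^(−1/4) toward long delays
where correlator bins average more samples; amplitude/phase noise
independent).  In-vivo β is 0.35.  All generators are pure functions of
(configuration, seed).  What this does *not* emulate: real instrument noise
covariance (amplitude–phase coupling), calibration-transfer errors, probe
pressure, motion, physiological variability beyond the prescribed
trajectories, and inter-slab air gaps in physical stacks — so green
round-trip tests demonstrate self-consistency of the pipeline, not field
accuracy on real instruments.

Time-series summaries follow the protocol definitions: baseline = mean of
the first 50 s; perturbation magnitude = largest absolute deviation from
baseline within the load window(s).

## Problem sizes

Production-scale defaults are 10⁶–10⁷ photons per run and ten repeats per
LUT node.  The test suite and the acceptance script run the same code at
reduced sizes chosen for convergence at their stated tolerances: 0.75–2×10⁵ photons
per run, pooled repeats from 2 (screening properties) up to 18 (round-trip
recovery, whose μs′ gate sits close to the Monte Carlo noise floor), reduced
μs′ axes where the truth is interior, reduced-mode transport except for the
oracle-equivalence gate (run in Henyey–Greenstein mode, where similarity
error would otherwise contaminate the comparison), a 2 mm detector
half-width and a 1800 mm path cap.  Each report records the photon count it
used.

## Known limitations and open points

* The ambient refractive index (probe coupling) is not specified by the
  preset tables; it defaults to 1.0 (air) and is configurable.  Its effect on
  the 6-mm-stack single-layer biases was measured to be small.
* Detector geometry (annulus half-width) is a modelling choice; forward data
  and LUTs built with the same geometry cancel its bias in inversion.
* For strongly layered media with a low-absorption, high-scatter overburden,
  detected light at 25 mm SDS channels through the overburden; the
  single-layer inversion of such stacks converges to overburden-like
  properties, and the resulting bias magnitudes are large and sensitive to
  the exact layer absorption/scattering contrasts; reported bias values
  should always be read together with the layer properties that produced
  them.
* Only Brownian dynamics are modelled for DCS (no flow/hybrid models), and
  hemoglobin is not separated from myoglobin.
* Sensitivities are one-at-a-time, not global; interaction terms are not
  quantified.
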