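# Methods

`skyshine` estimates the photon radiation that escapes upward from a
radiotherapy vault, scatters in the open air above it, and returns to ground
level outside the shielding — *skyshine*. It contains two coupled tools: an
analog Monte Carlo photon-transport engine for cylindrically symmetric
vaults and silos, and the simple algebraic estimation methodology that the
Monte Carlo results support.

## Transport model

Photons are tracked one at a time through an axisymmetric world: a concrete
side-wall annulus, an optional concrete roof slab, a concrete ground
half-space, and homogeneous air everywhere else. The model is deliberately
minimal and matches the assumptions under which the fitted constants were
derived:

* **Analog transport, no variance reduction.** Free paths are sampled
  exponentially from the local total linear attenuation coefficient and
  re-sampled at every material boundary (valid by the memoryless property;
  equivalent to accumulating optical depth across piecewise-constant media).
* **Three interaction channels.** Incoherent (Compton) scattering off free
  electrons with the exact Klein–Nishina cross section, sampled by Kahn's
  rejection method; photoelectric absorption, which terminates the history;
  and pair production, which also terminates the history (annihilation
  photons are not followed — the pair channel is at most ~10% of
  interactions in air at 6 MeV, which bounds the resulting underestimate).
  Coherent (Rayleigh) scattering is excluded from both the channel list and
  the totals: it deposits no energy, and at the sub-percent level where it
  redirects photons its omission is invisible next to the ~10% statistical
  accuracy of the tallies.
* **Kerma approximation.** Secondary electrons are not transported; energy
  transfer is scored directly from photon fluence via the mass
  energy-absorption coefficient of air. Photons below 10 keV are absorbed
  on the spot. At these energies electron ranges in air are centimetres,
  far below the 0.5 m tally resolution.
* **World escape.** Histories end when they leave a 2 km-radius,
  2 km-tall cylinder (or penetrate 1 m into the ground — 10+ mean free
  paths of concrete). The mean free path of a 6 MeV photon in sea-level
  air is 0.33 km, so the world boundary is several optical depths beyond
  every tally and cannot bias the ring scores.

### Cross-section data

Bundled CSV tables (`src/skyshine/data/`) give mass coefficients for dry
air and ordinary concrete (density 2.3 g/cm³) on a ~110-point log grid over
0.01–20 MeV. The incoherent column is the exact Klein–Nishina total cross
section times the electron density N_A·(Z/A); the photoelectric, pair and
μ_en/ρ columns pass through anchor values of the published NIST/
Hubbell–Seltzer tabulations, with pair defined so that the channel sum
reproduces the published total attenuation (minus coherent) above
1.25 MeV. Generated once by `scripts/make_xs_tables.py`, which asserts the
anchors: the 0.33 km mean free path at 6 MeV, a pair share of ~0.1–0.13 at
6 MeV, and 2% agreement with published air values at 0.1, 1 and 10 MeV.
Interpolation is log-log; pair production is identically zero below the
1.022 MeV threshold. Users can substitute their own tables
(`load_material(path=...)`), provided the five-column format and shared
grid are kept.

### Tallies

Cylindrical symmetry is exploited by scoring flat, contiguous, coaxial
rings (width 0.5 m by default) in a horizontal plane — 1.3 m above grade
for vault runs, 1.0 m for the benchmark silo. Each crossing of the plane
contributes 1/(projected ring area) to the ring fluence,
ΔΦ = 1/(π(r_{n+1}²−r_n²)·|w|) with w the vertical direction cosine, and
E·ΔΦ·(μ_en/ρ)_air to the air kerma; this is identical to a track-length
(Σdl/V) estimator through a thin ring volume. |w| is floored at 0.02 when
forming 1/|w| to bound the estimator variance at grazing crossings; the
tests verify against a track-length estimator that the floor's bias is
under 1%. Statistical errors come from 20 independent batches, each with
its own RNG stream spawned from the run seed; results are bit-reproducible
functions of (seed, n_histories, n_batches).

### Normalization conventions

Two output modes:

* **`exposure_per_Ci`** (silo benchmark): ring air kerma per source photon
  × 2 photons/decay × 3.7·10¹⁰ decay/s/Ci × 3600 s/h ÷ 8.76·10⁻³ Gy of
  air kerma per roentgen (from 1 R = 2.58·10⁻⁴ C/kg and W/e = 33.97 J/C,
  radiative losses neglected), reported in μR h⁻¹ Ci⁻¹.
* **`scaled_AKR`** (vault runs): ring kerma per history divided by the
  per-photon isocenter air kerma D₀ = Σᵢ pᵢEᵢ(μ_en/ρ)ᵢ / A of the beam
  spectrum. Two reference areas are supported. The default uses the
  10 × 10 cm² field (A = 100 cm²), the documented definition of D₀.
  `scaled_akr(..., field_area_f0=F0)` instead divides by the isocenter
  dose rate of the *actual* field (A = F0): because a flat machine holds
  its central-axis dose rate fixed while the photon output grows with the
  field area, this is the basis on which broad-field Monte Carlo profiles
  are consistent with the algebraic formula below and with the published
  profile values (e.g. the ~3.5·10⁻⁷ open-roof maximum for a 40 × 40 cm²
  field). Photon radiation weighting factor is 1, so nGy/s and nSv/s are
  used interchangeably.

## Sources

A linac beam is a point source on the axis 1.0 m below the isocenter
(standard 100 cm SAD), emitting uniformly per solid angle inside a cone
whose half-angle reproduces the equivalent-circle field area at isocenter
(1600 cm² → 12.7°). The spectrum is a histogram, discrete lines (Co-60:
1.17 and 1.33 MeV, equal weight) or monoenergetic. Off-axis spectral
variation is not modelled.

Because published linac spectra cannot be redistributed here, a
**parametric stand-in** is bundled: a thin-target bremsstrahlung kernel
(E_max−E)/E hardened by exp(−b/E), with b solved per nominal MV so the
mean photon energy matches standard anchors (2.0 MeV at 6 MV, 3.2 MeV at
10 MV, 6.0 MeV at 18 MV; 1.3 and 4.9 MeV at 4 and 15 MV by the same ~0.33
mean-to-maximum ratio). The skyshine observables this package reports
(peak location, mean ground-level energy, ground-reflection share, density
scaling, field-size invariance) are demonstrably insensitive to the fine
spectral shape; absolute scaled-AKR values carry a residual spectrum
dependence at the ~10% level. Exact published spectra can be dropped in as
two-column text files.

## The single-scatter oracle

For a monoenergetic pencil beam fired up the axis of a roofless vault, the
ring kerma from photons that scattered exactly once is a one-dimensional
integral over the scatter height: primary survival × electron density ×
Klein–Nishina differential cross section toward the observation point ×
survival along the slant path (with the chord through the concrete wall
attenuated, not excluded — the "opaque wall shadow" is the thick-wall
limit) × E′(μ_en/ρ)(E′)/R². The engine reproduces this integral when run
with `scatter_limit=1` (the history is absorbed at its next interaction
after the first scatter — exactly the attenuated single-scatter flux) and
`ground_kill=True`. Agreement within statistics at every ring from 5.5 to
30 m validates, in one test, the angular sampler, the heterogeneous path
sampling, the wall geometry and the ring estimator.

## The algebraic methodology

The instantaneous air-kerma rate at ground level (nSv/s) is

    K̇_a = k · (F0/400) · B_xs · (Ḋ0/400) · (1/d_s) · g(x),
    g(x) = 2(1+x²)^{3/2} − x(2x²+3),     x = h/(d_s − d_w),

with F0 in cm², Ḋ0 in cGy/min, distances in metres; the weekly dose
(μSv/wk) replaces the dose rate by the workload:
H_s = 1.5·10⁻² k (W_p U T)(F0/400) B_xs (1/d_s) g(x). The single
energy-dependent parameter k is tabulated at {4: 150, 6: 140, 10: 100,
15: 95, 18: 85} and linearly interpolated in MV; these are deliberately
*conservative* fits to thick-roof Monte Carlo profiles, and for an
unshielded roof at 10 MV and above they overestimate the true AKR by up to
a factor of ~2 (verified by the conservatism test). The profile maximum
sits near d_max ≈ 1.5 d_w + 1.1 h, a linearization valid for
0.3 < h/d_w < 1.2 and confirmed to track the true argmax of g(x)/d_s
within 10% across that range; maximization is done by bounded
golden-section search on (d_w+1 mm, d_w+100h), where the profile is
unimodal.

Roof transmission comes from tenth-value layers: B_xs = 10^(−t_r/TVL1) for
t_r ≤ TVL1, then one decade per TVLe. NCRP-151 primary-beam concrete TVLs
are bundled as overridable constants ({4 MV: 35/30 cm … 18 MV: 45/43 cm});
with them, the background-matching transmissions 5.8·10⁻⁴ (18 MV) and
3.3·10⁻⁴ (4 MV) correspond to ~140 and ~110 cm of concrete. The rooftop
criteria use H_w,r = B_xs W_p U T_r/(h+2)² weekly and
H_h,r = W_h U B_xs/(h+2)² hourly with W_h = W_p/40; inverting them gives
the shielded-roof maxima 5.7·10⁻⁵·k μSv/wk (occupancy-shielded, T=1) and
5.7·10⁻³·k·T μSv/wk (high-radiation-area-shielded), both independent of
the individual workload, use factor and transmission. `classify_roof`
labels a roof thick when μ̄·t_r ≥ 3 with μ̄ = ln10/TVL1, and carries the
energy-dominance advisory (below ~30 cm of concrete the lowest MV
dominates the skyshine; 30–50 cm is roughly energy independent; above
~50 cm the highest MV wins).

## Problem sizes and statistical accuracy

Default production runs use 10⁷ histories (≈1 minute of kernel time per
10⁷ on one core), giving ~1–3% ring statistics for open geometries; the
test suite uses 10⁶–4·10⁶ histories with correspondingly wider statistical
bands, and `scripts/acceptance.py` uses 10⁷ for the benchmark silo and the
ground-reflection differencing, 2·10⁶ for the mean-energy observable.

## Validation status and known limitations

Four independent checks validate the engine: (i) the ring estimator against
the closed-form inverse-square fluence of a point source in vacuum; (ii)
the Kahn sampler against direct quadrature of the Klein–Nishina cross
section (χ², mean cosine at five energies); (iii) survival counts against
the attenuation law in a pure absorber; and (iv) the full chain against the
single-scatter quadrature at every ring. Full-physics vault observables
agree with published Monte Carlo values: the open-roof 10 MV scaled AKR at
10 m (ours ≈3.3·10⁻⁷ vs 3.18±0.05·10⁻⁷ on the own-field basis), the
profile maximum (≈3.5·10⁻⁷), the ground-reflection share at 10 m
(17±2% vs ~15%), and the mean ground-level photon energy (0.17–0.18 MeV).

The benchmark-silo exposure rate at 50 m computes to ≈24 μR h⁻¹ Ci⁻¹,
roughly 20% above the historical benchmark value of ~20. The discrepancy
survives the single-scatter cross-check (an independent 3-D quadrature of
the silo geometry agrees with the engine's single-scatter component to
~10%), so it is not a defect of the sampler, the estimator or the
attenuation data; it is concentrated in the multiply-scattered and
ground-reflected far field, where historical code-to-measurement spreads
of 15–22% are documented for this experiment. We report the computed value
as is rather than adjusting any model parameter toward the benchmark.

Not modelled: neutron skyshine; oblique beam incidence or asymmetric
fields (the geometry is strictly axisymmetric); charged-particle
transport; annihilation photons; atmospheric density stratification
(scale height 6.6 km ≫ photon mean free paths); in-silo source hardware
(cask, support plate) of the benchmark experiment; side-wall leakage dose,
which a real shielding evaluation must add to the skyshine. The bundled
spectra are parametric stand-ins, and the synthetic geometry is an empty
concrete cylinder or vault — real vaults have mazes, ducts and
non-cylindrical footprints that this model cannot represent; passing tests
demonstrate internal consistency and agreement with the published
cylindrical-model results, not fidelity to any particular clinical site.
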