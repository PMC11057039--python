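# Methods

`crowdiff` models the diffusion of nanometre- and subnanometre-sized
tracers ("metabolites") in macromolecularly crowded media. This note
records the models, the numerical choices behind them, and what the
synthetic data used by the test suite does and does not emulate.

## Units

Internal units are nm, µs, K and mPa·s; diffusivities are in nm²/µs
(1 nm²/µs = 10⁻¹² m²/s). This keeps Brownian step lengths of order
10⁻³–10⁻¹ nm and exponential arguments of order one. Boltzmann's and
Avogadro's constants are hard-coded at full CODATA precision. Volume
fractions are decimals internally and are only rendered as percentages
at I/O boundaries. The default solvent viscosity is 0.89 mPa·s (water
at 298 K); it is configuration, not a measurement, and every
`PhysicalEnvironment` consumer accepts an override.

## Dilute-limit transport

The Stokes–Sutherland–Einstein (SSE) relation D₀ = k_BT/(6πηR_H) maps a
hydrodynamic radius to a dilute-limit diffusivity and back
(`sse_diffusivity`, `hydrodynamic_radius_from_d`; exact algebraic
inverses). Note the inverse direction is *inverse* in viscosity: at
fixed D, a larger η implies a smaller inferred R_H.

## System construction

Mixtures are hard-sphere fluids in a cubic periodic box (minimum-image
convention everywhere; the box edge must exceed twice the largest
particle diameter). Initial configurations come from random sequential
addition (RSA), inserting the largest species first, which keeps
insertion feasible up to occupied fractions near 0.4 in polydisperse
systems; each particle gets up to 10⁵ candidate positions before the
builder raises a packing error naming the species. Above φ_occ = 0.35
the builder switches to a compression protocol: the system is assembled
by RSA in a proportionally larger box and the box is then shrunk in
0.5 % steps, restoring hard cores after every step. RSA configurations
are not exactly equilibrium hard-sphere fluids; production runs
therefore begin with an equilibration segment (below).

The packaged cytoplasm composition (`data/ecoli_cytoplasm.csv`) is a
**synthetic** stand-in for a measured E. coli composition: nine species
spanning 0.8–13 nm, including GFP-like (2.4 nm) and ribosome-like
(13 nm) particles, with counts that put the macromolecule occupied
fraction at 0.426 once the box edge is chosen by the builder. Users
with a measured composition should supply their own CSV.

## Brownian dynamics

Propagation is overdamped forward-Euler without hydrodynamic
interactions: each particle takes an independent Gaussian step with
per-axis variance 2·D₀·dt, with D₀ from the SSE relation at the
particle's radius. Hard cores are restored after every step by an
elastic displacement correction in the Heyes–Melrose spirit:
overlapping pairs are moved apart along their centre line exactly to
contact, the displacement shared in proportion to the particles' D₀
(mobility-proportional; equal spheres split symmetrically), sweeping
until no overlap remains (at most 100 sweeps — exceeding the cap
signals a timestep too large for the packing). Inertia, rotations,
torques, interparticle attractions and hydrodynamic coupling are all
outside the model.

Timestep: dt is chosen so the fastest species' RMS free step is a set
fraction of the smallest radius in the system — 0.05 by default, and
the propagator refuses anything beyond 0.10. A bias study at the worst
case used in the tests (0.8 nm tracers among 5.1 nm crowders at
φ_occ = 0.3) found no resolvable difference in long-time D between
fractions 0.05 and 0.07 (Δ(D/D₀) = +0.009 ± 0.019), so production-style
test runs for the small tracer use 0.07; runs where the *measured*
species is large (2.5 and 5.1 nm) keep 0.05, because larger absolute
steps at φ = 0.3 can overflow the overlap-resolution sweep cap.

Randomness: Gaussian displacements are drawn from a single
`numpy.random.Generator` stream per run (chunked, outside the compiled
kernel), so trajectories are bit-reproducible for a given seed and
recorded in every output's metadata.

## MSD analysis and long-time D

`compute_msd` averages squared displacements of unwrapped coordinates
over all frame pairs at each lag (FFT autocorrelation decomposition,
verified against a brute-force double loop). `long_time_d` fits a
weighted straight line over the last half-decade of the available lags
and reports slope/6. The fit carries a free intercept: crowded-system
MSDs have a short-time offset, and forcing the line through the origin
over a late window would bias D upward. A local-exponent guard warns
when d log MSD/d log τ < 0.9 in the window (not yet diffusive).
Uncertainties come from block averaging — 10 blocks over particles when
there are enough tracers (calibrated against free-walk ensembles:
reported SE within ~10 % of the empirical scatter), otherwise over
contiguous time segments.

Choosing the window matters more than any other analysis knob. Profiling
D(t) for a 0.8 nm tracer among 5.1 nm crowders showed the plateau is
reached only after displacements of ~4–5 crowder radii (≈ 0.1 µs here);
windows earlier than that overestimate D by several percent. The
BD-based tests therefore set windows in *absolute* time per tracer size
(0.095–0.3 µs for 0.8 nm; scaled up for slower tracers), with total run
lengths ≥ 20× the window end so each lag averages many independent
segments.

## Slowdown laws

* Linear law: D/D₀ = 1 − κ·φ_occ with the intercept pinned at 1 (a
  tracer at zero crowding diffuses at D₀ by definition). `KappaModel`
  estimates κ by (optionally 1/σ²-weighted) least squares through the
  fixed intercept; the (0, 1) anchor is inserted exactly if the input
  curve lacks it and a free-intercept fit is available as a diagnostic.
* Excluded volume: a tracer of radius R_H cannot centre itself within
  R_c + R_H of a crowder, so it effectively sees φ_ex ≥ φ_occ.
  Closed forms: φ_ex = φ_occ(1 + R_H/R_c)³ (shell overlaps neglected;
  low-φ only) and its linearization φ_occ(1 + 3R_H/R_c). The
  Monte-Carlo estimator inserts uniform random points into crowder-only
  configurations and counts overlaps; with ≥ 2 configurations the SE is
  taken over configurations, otherwise binomial.
* Effective medium: the point-tracer Maxwell–Garnett treatment reduces,
  in linear form, to D/D₀ = 1 − φ_ex/2. Composed with the linearized
  φ_ex this is exactly the linear law with
  κ(R_H) = ½(1 + 3R_H/R_c) — κ = ½ for a point tracer, κ = 2 at
  self-crowding. The rational effective-medium expression and this
  linear form agree to the two decimals at φ = 0.1 at which the
  checkpoint (0.95) is stated.
* Nanoviscosity: D/D₀ = exp[−b(R_eff/ξ)^a], with ξ = R_g·ψ_rcp(1−φ)/φ
  for hard spheres (ψ_rcp = φ/(1−φ) at random close packing ≈ 1.76) and
  R_eff interpolating between R_H (small tracers) and R_c (large).
  The interpolant is R_H·R_c/√(R_H²+R_c²) by default; only its two
  limits are contractual, and a harmonic-type alternative
  R_H·R_c/(R_H+R_c) is selectable. An optional minimal length R_min
  (R_eff evaluated at R_H + R_min) keeps point tracers coupled to the
  medium; with a = 1 it linearizes at small R_H and φ to the linear law
  with κ linear in R_H. An optional step-like exponent a(R_H) blends
  a(0) = a_zero into the large-R plateau with a logistic in ln R_H of
  configurable width (only the two plateaus are physically motivated).
  `NanoviscosityModel.fit` ties ξ to the fitted effective crowder
  radius (R_g = r_c_eff), runs trust-region least squares from 8
  log-spaced starts (local minima are a real hazard), reports SEs from
  the Jacobian, and breaks cost ties toward the smallest b so flat
  curves return b → 0 rather than a degenerate large-r_c_eff ridge.

## Synthetic data generators

The generators stand in for raw measurements and give every fitter a
known ground truth:

* `simulate_series`: Stejskal–Tanner attenuation
  I/I₀ = exp[−D·γ²g²δ²(Δ−δ/3)] plus additive Gaussian noise on the
  normalized intensity. Adequate for the high signal-to-noise regime of
  modern PGSTE data; a Rician floor, solvent corrections, actual pulse
  shapes, spectra and peak integration are not emulated. Default
  acquisition (δ = 2 ms, Δ = 100 ms, 16 gradients to 0.5 T/m, ¹H γ) is
  plausible-modern-spectrometer configuration, not a measured protocol.
* `generate_free_walk`: Gaussian random walks of known D — the
  calibration oracle for the MSD chain.
* `generate_slowdown_table`: noisy curves from the linear-φ or
  nanoviscosity laws with the generating truth recorded.

Passing recovery tests on these generators demonstrates estimator
correctness and calibrated uncertainties *under the stated noise
model*; real attenuation data with baseline distortions, peak overlap
or convection artefacts can of course violate it.

## Test-suite study conditions

The BD-based tests run scaled-down conditions, fixed in advance: 30
crowders (R_c = 5.1 nm) + 30 tracers, φ_occ ∈ {0.1, 0.2, 0.3}, 6.5 µs
per run for the 0.8 nm tracer (12 µs and 45 µs for 2.5 and 5.1 nm,
whose windows scale with their slower relaxation), 8 replicate seeds
per φ for the small tracer (3 for the larger; per-point uncertainties
are standard errors of the replicate mean), ~1000 recorded frames per
run. The free-diffusion calibration uses 50 tracers and 10⁵ steps.
At self-crowding (R_H = R_c) the crowders themselves are the measured
species, since a separate same-size tracer population would add
non-negligible crowding of its own. Monte-Carlo excluded-volume checks
use 60-crowder configurations and 5 × 10⁵ insertions.

## Known limitations

* No hydrodynamic interactions: experimentally, HI deepen the slowdown
  of small tracers; κ values here are systematically below what a
  Stokesian treatment would give.
* Hard spheres only: no attractions, shape anisotropy, polymer
  porosity, or temperature-dependent viscosity.
* The linear slowdown law is an empirical summary; hard-sphere D(φ) has
  genuine curvature that a single κ cannot absorb, which bounds the R²
  of a constrained linear fit even with perfect statistics.
* The packaged cytoplasm table is a synthetic approximation; results on
  it characterize the model class, not E. coli.
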