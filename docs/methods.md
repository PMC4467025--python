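# Methods

This note documents the models, estimators and numerical choices behind
`ssxcorr`, and what the bundled validation does and does not demonstrate.

## Pair cross-correlation

`C(r, τ) = M(r, τ) / (ΔA(r)·ρ₀·W(r))` estimates the relative probability of
finding a colour-1/colour-2 pair at separation `r` and frame lag `τ`,
normalized to a uniform co-distribution. Assumptions:

* the system is **stationary within the analysis window** (the steady-state
  assumption) — pooling same-frame pairs over the window is only meaningful
  if the underlying co-distribution does not change across it;
* localizations are point samples of the underlying molecule positions;
  finite localization precision and registration error broaden short-range
  structure but conserve the area under `C(r) − 1`;
* over-counting from fluorophore re-blinking affects same-channel
  statistics, not the cross-channel curve, because blink events of different
  fluorophores are independent.

**Bins.** Radial bins are half-open `[c − Δr/2, c + Δr/2)` with the first
center at `Δr/2`, so every non-negative distance belongs to exactly one bin
and `ΔA = 2πcΔr` is the exact annulus area. Default `Δr` is 25 nm, matching
the 25 nm reconstruction pixels; both are configurable. Distances exactly on
a bin edge go to the upper bin (enforced with `searchsorted`, and with
strict-inequality cumulative counts in the KD-tree path, so the two paths
agree bin by bin).

**Edge factor.** `W(r)` is computed from the ROI raster: the mask is
subdivided to a pixel no coarser than `min(Δr, 25 nm)`, zero-padded to at
least twice its extent (and to the largest requested lag), autocorrelated
with FFTs, and normalized to one at zero lag. The per-bin value is the
*area-weighted mean* of this set covariance over the annulus, sampled by
bilinear interpolation at deterministic sub-annulus points (8 radii × 72
angles, radii spaced uniformly in `r²`). With the exact `ΔA`, this makes
`μ = ΔA·ρ₀·W` the exact expected uniform pair count up to interpolation
error (<1% against the closed-form set covariance of a square). Bins where
`W = 0` are flagged undefined and excluded from fits and averages, never
propagated as NaN arithmetic.

**Variance.** `σ_M² = M`, `σ_N² = N` (Poisson), giving
`σ_C² = C²(1/M + 1/N)`, implemented as `σ_M²/μ² + C²/N` so empty bins stay
finite. Sparse mode substitutes `σ_M² = M + 1` to keep an error estimate in
empty bins; it switches on automatically when a histogram holds fewer than
100 pairs. The model treats `M` and `N` as independent, which is accurate
when the binned range covers a small fraction of the ROI; the
scrambled-frame resampling study verifies the prediction to within ~10% per
bin under well-sampled conditions. The resampling study itself uses 200
windows because the empirical standard deviation carries a relative error
of `1/√(2(K−1))` — with 50 windows the comparison would be dominated by
estimator noise rather than by the variance model.

**Image route.** The time-averaged curve can equivalently be computed from
reconstructed count images as the annulus average of
`Re{IFFT(FFT(I₁)·conj(FFT(I₂)))}` divided by the annulus average of
`ρ₁ρ₂ × (mask set covariance)` — density normalization with the edge factor
folded into the denominator. The pairwise and image estimators agree to
<1% for `r ≥ 2` pixels on 10⁴-point datasets; the package treats the
pairwise route as primary and the image route as a cross-check. The
same-channel image correlation carries a self-pair density spike at
`r → 0` and is not interpreted there.

**Combining lags.** `average_over_tau` is the per-bin inverse-variance
weighted mean with the variance of the weighted mean attached; it is
appropriate when `C(r, τ)` is constant over the averaged lags (immobile or
slowly rearranging structures). `extrapolate_tau_zero` fits `C` versus `τ`
per bin (weighted constant or straight line) over non-excluded lags and
evaluates at `τ = 0`; it is the repair for bleed-through, which inflates
the smallest lags.

**Conversions.** `PMF(r) = −ln C(r)` in `k_BT` units with
`var = σ_C²/C²`; bins with `C = 0` are flagged rather than mapped to ±∞.
`ρ(r) = C·⟨ρ⟩`, and the cumulative excess partner count prefix-sums
`(C−1)·⟨ρ⟩·ΔA`; the mean density `⟨ρ⟩` must be supplied (molecular counting
is outside this package's scope).

## Mobility analysis

`G(r, τ)` reuses the pair machinery within one channel at lag `τ ≥ 1`
(`τ = 0` only reports instantaneous emitter density and is flagged).
Normalizing `G` to unit two-dimensional area gives the step-length
probability density. One population of Brownian diffusers fits
`exp(−r²/MSD)/(π·MSD)`; two populations fit the mixture with slow fraction
`α` (bounds `0 ≤ α ≤ 1`, components ordered `MSD₁ ≤ MSD₂` after the fit,
ratios below 2 flagged weakly identifiable). Fits are weighted by the
Poisson-propagated per-bin errors; mixture initialisation is
method-of-moments split at the half-mass radius with five seeded restarts,
keeping the best weighted SSE. `α(τ)` is fit to `α₀·exp(−τ/τ₀)`; under
two-state binding kinetics `τ₀` estimates `1/k_off`.

Two systematic effects are reported, not corrected:

* localization noise adds `≈ 4σ_loc²` to every apparent MSD (two
  localizations, two coordinates each); the immobile-population test pins
  this offset at `2·(2σ_loc²)`;
* pairs of *different* molecules contribute a flat `G ≈ 1` background that
  the normalization folds into the PDF. The analysis is therefore designed
  for SMLM-sparse data: the background fraction scales as `n·π r_max²/A`
  (visible molecules per frame times the analysis area over the field
  area). At typical single-molecule densities it is a few percent; dense
  datasets need a smaller `r_max` or fewer simultaneous emitters.

The trajectory route (for cross-checks) links localizations greedily
frame-to-frame within 500 nm, terminating any ambiguity (≥2 candidates in
either direction); `D` comes from a straight line through the 2nd–4th MSD
points, and per-trajectory values are reported for tracks longer than 10
segments. `correlated_steps` selects steps whose start and/or end has a
same-frame partner of the other colour within `r_c` (default 50 nm; the
both-endpoints rule is available by flag).

## Preprocessing

Drift is estimated per 500-frame group from coarse (50 nm) two-channel
histograms: consecutive groups are cross-correlated, and the peak is found
by local DFT upsampling after smoothing each histogram by one pixel —
the smoothing band-limits the otherwise box-binned peak, without which the
sub-pixel estimate is biased toward integer lags. The raster carries a
16-pixel margin so the circular FFT correlation cannot couple opposite
edges. Offsets accumulate from the first group and correction applies
block-constant shifts (no within-group interpolation). Per-group shifts
well below one pixel retain a mild (~15%) shrinkage toward zero; cumulative
drift across many groups is recovered within the spec of half a raster
pixel after correction.

Channel registration fits a bivariate polynomial (default degree 2 — enough
for chromatic warp, not enough to overfit 20–40 beads) by least squares on
fiducial pairs; coordinates are centred and scaled internally so the normal
equations stay well conditioned over tens of micrometres. The transform
reports its RMS residual, which is the honest precision bound for
registered two-colour distances.

## Simulators

**Lennard-Jones MD** (reduced units, σ = ε = m = 1): 64 atoms at density
0.05 σ⁻² (box ≈ 35.78 σ), velocity Verlet at dt = 0.005, periodic
minimum-image boundaries, force-shifted potential at the 2.5 σ cutoff
(force and energy continuous there, giving NVE energy drift < 10⁻³ over
200,000 production steps). Initial positions on a lattice; initial
velocities Gaussian with zero net momentum rescaled to the target reduced
temperature (default T* = 1.0, configurable; the measured production
temperature is reported and used when converting PMF depths to ε).
Velocities are re-rescaled every 200 steps during the 40,000-step
equilibration only; production is pure NVE. Full equilibration matters: at
this dilute density the pair structure is carried by a few transient
dimers with long correlation times, and a 10,000-step equilibration leaves
the well at roughly half its equilibrium depth (verified against an
independent Metropolis Monte Carlo oracle). For the same reason the
validation analyses the full 200,000-step production run; 20,000-step
windows show ±50% seed-to-seed spread in the apparent well depth.

**Brownian binding**: particles in a reflecting square box switch between
free (`D_free`) and bound states with exponential waiting times. Without
anchor sites, switching is exact in continuous time and each frame
displacement uses the exact time-in-state variance
`2(D_free·t_free + D_slow·t_bound)` per axis; completed dwell times are
returned for direct kinetic checks. With anchor sites, binding is gated on
proximity (50 nm capture radius by default) and the bound particle co-moves
with its anchor.

**Observation model**: per-frame Bernoulli blinking with probability
`P_on`, Gaussian localization noise, and spectral bleed-through in which a
channel-1 localization spawns a simultaneous channel-2 record at the same
(jittered) position. Bernoulli blinking is memoryless — real fluorophores
have correlated on-times and photobleaching, which this model omits. One
consequence: a bleed copy contaminates `C(r→0, τ)` at lags `τ > 0` only
through its parent's motion (the contamination decays as ~1/MSD(τ)), so the
bleed-through validation uses lipid-like mobility (2 µm²/s, one-frame step
≫ first bin) and excludes `τ ≤ 2` from the extrapolation. For slow movers
with long fluorophore on-times, the real contamination extends further in
`τ` and the exclusion window must grow accordingly.

## Validation studies and their scope

The studies in `ssxcorr.validation` (run by `scripts/acceptance.py` and the
acceptance-style tests) are end-to-end: generator → observation →
analysis → comparison against the generator's ground truth.

| study | conditions | checks |
| --- | --- | --- |
| LJ PMF | full 200k-step run, Δr = 0.1 σ, square-box ROI | PMF minimum in [1.05, 1.20] σ, depth within 25% of ε |
| variance model | uniform channels, 90/frame, 200 × 20-frame windows | resampled s.d. within 20% of `σ_C` per bin |
| estimator equivalence | 10⁴ points/channel, half clustered at 30 nm | pairwise vs image `C` within 5% for r ≥ 2 px |
| null calibration | uniform channels, 5 seeds × 40 bins | ~95% of bins inside `1.96 σ_C` |
| mobility | 40 sparse binders, k_off = 2/s, 4000 frames | (α, MSD₁, MSD₂) within 2 s.e.; τ₀ within 20% |
| bleed-through | 5% bleed, fast lipid-like movers | `C(τ=0)` spike, flat `C(⟨τ⟩)`, extrapolation within 2σ |

Passing them shows the estimators are unbiased and correctly calibrated
under the stated generative models. It does **not** establish robustness to
what the generators omit: correlated fluorophore on-times, photobleaching
gradients, localization-precision heterogeneity, out-of-focus background,
or non-stationarity inside an analysis window. Those enter real data and
are the user's responsibility to bound (shorter windows, wider exclusion
lags, fixed-sample calibrations).

## Degenerate inputs and tie-breaks

Half-open pixels and bins (right/top edge belongs to the next cell);
channel labels restricted to {1, 2}; `N = 0` windows raise rather than
return NaN curves; `C = 0` bins give undefined PMF; `W = 0` bins are
undefined and excluded; empty drift groups carry the previous offset with a
warning; trajectories terminate at any linking ambiguity rather than
guessing. All stochastic components draw from `numpy` Generators with
explicit seeds; identical seeds give bit-identical outputs.
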