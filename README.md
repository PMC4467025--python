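# ssxcorr

Steady-state cross-correlation analysis for two-colour super-resolution
localization microscopy (PALM/STORM).

In fixed samples, the co-distribution of two spectrally distinguishable
labels can be quantified by cross-correlating their reconstructed images.
In live samples that fails: molecules move large distances during the
minutes it takes to collect a well-sampled localization dataset, so the
time-averaged cross-correlation of mobile species washes out to 1.
`ssxcorr` implements the steady-state alternative: correlate only pairs of
localizations detected **simultaneously** (or at a controlled time lag),
pooled over a window in which the system is stationary. This recovers the
true co-distribution of mobile interacting species — receptors and kinases
on a cell membrane, lipid-anchored probes on a vesicle — together with
calibrated statistical errors, an effective interaction energy, and a
trajectory-free mobility analysis. It is aimed at single-molecule
microscopists who already have drift-corrected localization tables and want
quantitative, model-independent interaction readouts.

## The estimator

For localizations of colour 1 and colour 2 inside a region of interest
(ROI) of area `A`, the cross-correlation at separation `r` and frame lag
`τ` is

```
C(r, τ) = M(r, τ) / μ(r),        μ(r) = ΔA(r) · ρ₀ · W(r)
```

* `M(r, τ)` — histogram of pairwise distances between colour-1
  localizations in frame `i` and colour-2 localizations in frame `i+τ`,
  summed over a steady-state window of `F` frames;
* `ΔA(r) = 2πrΔr` — the annulus area of the radial bin;
* `N = Σᵢ n₁,ᵢ n₂,ᵢ₊τ` — the number of pairs counted (`n₁n₂` in the
  time-averaged `⟨τ⟩` mode), and `ρ₀ = N/A`;
* `W(r)` — the radially averaged, normalized autocorrelation of the ROI
  mask (computed with FFTs), which corrects for pairs lost across the
  boundary of a finite or irregular ROI.

`C = 1` means no correlation; `C > 1` enrichment; `C < 1` exclusion.
Poisson counting statistics give the per-bin variance

```
σ_C² = C² (σ_M²/M² + σ_N²/N²) = C² (1/M + 1/N)
```

with `σ_M² = M` (optionally `M+1` for sparse data) and `σ_N² = N`. Under an
equilibrium steady state, `PMF(r) = −k_BT ln C(r)` is the potential of mean
force between the labels, and `ρ(r) = C(r)·⟨ρ⟩` converts the curve into the
density of partners at distance `r`, whose integral counts excess partners.

The same machinery applied within one colour gives the displacement
correlation `G(r, τ)`; normalized so its two-dimensional area is one it is
the step-length probability density, fit by one- or two-population Gaussian
models (`MSD = 4Dτ`), with the slow-population fraction `α(τ)` decaying as
`α₀·exp(−τ/τ₀)` when the slow state unbinds at rate `1/τ₀`.

Everything is validated end to end against bundled simulators: a 2-D
Lennard-Jones molecular-dynamics fluid (64 atoms, reduced density 0.05,
velocity-Verlet, periodic boundaries) whose cross-colour PMF must reproduce
the pair potential, and Brownian/two-state-binding dynamics observed
through a stochastic blinking model (`P_on`, localization noise, spectral
bleed-through).

## Worked example

Two hundred frames in a 10 µm field; each frame holds 40 "receptor"
localizations (channel 1) and 40 channel-2 localizations of which half sit
within ~30 nm of a receptor and half are free:

```python
import numpy as np, pandas as pd
import ssxcorr as sx

rng = np.random.default_rng(0)
box, n_frames, per_frame = 10_000.0, 200, 40
rows = []
for f in range(n_frames):
    red = rng.uniform(0, box, (per_frame, 2))
    bound = red[: per_frame // 2] + rng.normal(0, 30.0, (per_frame // 2, 2))
    free = rng.uniform(0, box, (per_frame - per_frame // 2, 2))
    rows += [(x, y, f, 1) for x, y in red]
    rows += [(x, y, f, 2) for x, y in np.vstack([bound, free])]
table = sx.LocalizationTable(
    pd.DataFrame(rows, columns=["x", "y", "frame", "channel"]), frame_interval=0.03
)

roi = sx.make_roi_mask({"type": "rectangle", "bounds": [0, 0, box, box]}, pixel_size=100.0)
binning = sx.RadialBinning.from_max(25.0, 500.0)
curve = sx.cross_correlation(table, roi, binning, tau=0)
pot = sx.pmf_from_correlation(curve)
dens = sx.density_from_correlation(curve, mean_density=table.n(2) / (n_frames * roi.area))

for i in range(6):
    print(f"r = {curve.r[i]:5.1f} nm   C = {curve.C[i]:6.2f} +- {curve.sigma[i]:.2f}"
          f"   PMF = {pot.pmf[i]:+.2f} kT")
i100 = np.searchsorted(binning.edges, 100.0) - 1
print(f"excess partners within 100 nm: {dens.cumulative_excess[i100]:.2f}")
```

prints

```
r =  12.5 nm   C = 187.57 +- 5.48   PMF = -5.23 kT
r =  37.5 nm   C =  99.34 +- 2.31   PMF = -4.60 kT
r =  62.5 nm   C =  26.42 +- 0.92   PMF = -3.27 kT
r =  87.5 nm   C =   4.68 +- 0.33   PMF = -1.54 kT
r = 112.5 nm   C =   1.31 +- 0.15   PMF = -0.27 kT
r = 137.5 nm   C =   0.96 +- 0.12   PMF = +0.04 kT
excess partners within 100 nm: 0.50
```

The simultaneous correlation resolves the 30 nm binding shell (the
time-averaged curve of a mobile system would not), the PMF well reports the
apparent binding energy, and the integrated excess recovers exactly the
constructed 0.5 bound partners per receptor.

## Command line

The `ssxcorr` entry point wraps the library for shell pipelines:

```
ssxcorr simulate lj --steps 20000 --out lj.csv
ssxcorr xcorr --input locs.csv --roi roi.json --dr 25 --rmax 1000 --tau 0 --out curve.csv
ssxcorr pmf --curve curve.csv --out pmf.csv
ssxcorr density --curve curve.csv --mean-density 1e-5 --out rho.csv
ssxcorr mobility --input locs.csv --roi roi.json --channel 1 --two-pop --tau-max 10 --out fits.json
ssxcorr drift / register / track / autocorr ...
```

Subcommands write a `.meta.json` sidecar with parameters and versions;
identical seeds give identical outputs.

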