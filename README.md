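# netarch

Quantification of cross-linked actin network architecture and its
dynamics from fluorescence microscopy, for in-vitro reconstitution
assays of actin cross-linkers (e.g. CaMKII holoenzymes) imaged by
epifluorescence or TIRF.

Networks of filaments and bundled "cables" are traced by an external
active-contour program (SOAX) into *snakes* (ordered, intensity-bearing
point sequences) and *junctions* (filament crossover points). `netarch`
parses that output, applies the editing rules used on real data, and
computes the architecture and kinetics descriptors:

- **Randomness index** `R = R_NN / r_rand`, where `R_NN = Σ r_NN / N` is
  the mean nearest-neighbour distance of the junction centroids and
  `r_rand = 1/(2√σ)` is the expectation for a homogeneous Poisson
  pattern at the measured junction density σ. `R ≈ 0` for aggregated
  points, `≈ 1` for a random (non-interacting) network, rising to
  ≈ 2.16 for an evenly spaced hexagonal lattice.
- **Cable intensity** `Q` (mean counts/pixel along each snake, a proxy
  for the number of bundled filaments in a diffraction-limited cable)
  and the skewness `S` of the `Q` distribution (adjusted Fisher–Pearson).
- **Curvature and persistence length**: mean unsigned tangent difference
  `K = (1/n) Σ ΔT/Δs` at sampling distance Δs, and the worm-like-chain
  maximum-likelihood persistence length from the half-normal curvature
  density `P(K) = √(2 l_p c/π) · exp(−l_p c K²/2)`, i.e.
  `l_p = 1/(c·⟨K²⟩)`.
- **Motor-driven compaction**: foci segmentation with the strict
  `> 50 µm²` area filter, integrated intensity
  `ΣQ_foci = Σ A_foci·Q_foci`, foci spacing `R`, and the linear `R(t)` /
  saturating-exponential `ΣQ_foci(t)` time-course fits.
- **Single-molecule kinetics**: dwell times with right-censoring, bound
  fraction (dwell > 6 frames ≈ 0.3 s at 20 frames/s), mono/bi-exponential
  maximum-likelihood off-rates `k_off`, mean-square-displacement curves
  and the lateral diffusion coefficient `D_lat` (MSD slope / 4), and
  kymographs along a polyline.

A first-class synthetic-data module generates every input with known
ground truth — Poisson / Thomas-clustered / hexagonal junction patterns,
worm-like-chain filaments rendered with a Gaussian PSF and Poisson shot
noise, frame-quantized exponential dwell mixtures, Brownian tracks with
localization noise, and Gaussian foci images — so every estimator is
testable end-to-end without experimental data.

## Worked example

```python
import numpy as np
from netarch import FieldSpec, randomness_index, fit_survival, fit_dlat, msd_curve
from netarch import synthetic as syn
from netarch.metrics import snake_curvature, fit_persistence_length

field = FieldSpec(width=100.0, height=100.0, seed=42)

# spatial randomness of junctions
pat = syn.gen_poisson_pattern(1.0, field)
print(f"junctions: {len(pat)},  R = {randomness_index(pat, guard=2.0):.3f}")

# filament stiffness from curvature
snake = syn.gen_wlc_snake(l_p=10.0, step=0.625, n_steps=10_000, field=field)
_, dT = snake_curvature(snake, delta_s=0.625)
l_p, _ = fit_persistence_length(dT / 0.625, c=0.625)
print(f"persistence length: {l_p:.2f} um (true 10.0)")

# single-molecule off-rate and mobility
dwells = syn.gen_dwell_times([(1.0, 2.55)], n=1200, field=field, window=20.0)
fit = fit_survival(dwells, "mono")
print(f"k_off = {fit.rates[0]:.3f} /s (true 2.55)")

tracks = syn.gen_tracks(D=0.37, n_tracks=200, n_frames=100, field=field)
curve = fit_dlat(msd_curve(tracks, max_lag=10))
print(f"D_lat = {curve.D_lat:.3f} um^2/s (true 0.37)")
```

Output:

```
junctions: 10168,  R = 1.009
persistence length: 10.12 um (true 10.0)
k_off = 2.488 /s (true 2.55)
D_lat = 0.370 um^2/s (true 0.37)
```

A Poisson junction pattern measures `R ≈ 1` (random, non-interacting);
the three recovery lines show each fitted parameter landing on the value
the generator was given.

The same analyses are available from the shell:

```sh
netarch simulate pattern --config cfg.yaml --seed 1 --out sim/
netarch import-soax result.txt --pixel-size 0.078 --fuse --out net.json
netarch analyze-network net.json --delta-s 0.625 --out summary.json
netarch analyze-tracks tracks.csv --model bi --out kin/
netarch run pipeline.yaml --out run/
```

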