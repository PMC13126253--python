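# nucleotrack

Single-molecule tracking and nucleoid analysis for rod-shaped bacteria.

`nucleotrack` implements the full analysis chain used in live-cell
photoactivated single-molecule tracking of nucleoid-associated proteins
(for example HUα-PAmCherry in *E. coli*): frame-by-frame spot detection
and 2D Gaussian localization, Hungarian frame-to-frame linking,
per-trajectory mean-squared-displacement (MSD) analysis, Bayesian
inference of diffusive mobility states from pooled single steps by
Gibbs sampling, PALM super-resolution reconstruction with a
nucleoid-occupancy statistic, and localization density heatmaps in a
rod-cell coordinate system. A synthetic-data module generates every
input the pipeline consumes — with known ground truth — so each stage
can be validated by parameter recovery.

## The models

**Per-trajectory diffusion.** Each trajectory's apparent diffusion
coefficient comes from the 2D MSD law

    MSD(τ) = 2 n D_app τ,   n = 2,

fit by weighted least squares through the origin over lags τ =
40–160 ms; fits with weighted R² < 0.70 are discarded. The pooled
D_app distribution can be decomposed with a Gaussian mixture model.

**Multi-state mobility.** A molecule switching among K diffusive
states emits frame-to-frame displacements (dx, dy) with independent
Gaussian components of per-axis variance 2 D_k τ, while its hidden
state follows a Markov chain with row-stochastic transition matrix T
(per 40 ms frame). A blocked Gibbs sampler on pooled steps —
forward-filtering backward-sampling for labels, conjugate
inverse-gamma updates for each D_k, Dirichlet updates for T — infers
the number of states K, the per-state diffusion coefficients D_k, the
weight fractions π_k, and the transition probabilities T_ij. The
sampler starts overfitted (5 states) and removes states by occupancy
pruning and a resolvability floor on adjacent D ratios.

**Nucleoid occupancy.** Pixel intensities inside a cell mask
(percentile-trimmed) are fit with a two-component Gaussian mixture;
pixels above 50% of the brighter component's mean form the nucleoid
region, and occupancy = nucleoid pixels / cell pixels. The same
statistic serves PALM reconstructions and stained-cell images.

**Cell coordinates.** Localizations are re-parameterized into
(r, l, Φ): signed radial distance from the skeleton-derived midline,
longitudinal arc-length position, and pole-cap angle. Normalized
coordinates are binned with per-cell rasterized bin areas, summed
across cells, symmetrized fourfold, and ratioed into densities
relative to the cell average.

## Worked example

Simulate 50,000 steps from the three-state stationary-phase wild-type
parameter set (slow 0.030 µm²/s at 31%, intermediate 0.080 µm²/s at
56%, fast 0.50 µm²/s at 13%) and recover the states:

```python
from nucleotrack.recovery import recover_condition

res = recover_condition("wt-stationary", seed=101)
s = res.summary
print("K =", s.K)
for i in range(s.K):
    print(f"state {i}: D = {s.D_mean[i]:.4f} ± {s.D_sd[i]:.4f} µm²/s"
          f"   weight = {100*s.pi_mean[i]:.1f} ± {100*s.pi_sd[i]:.1f} %")
```

prints

```
K = 3
state 0: D = 0.0303 ± 0.0005 µm²/s   weight = 30.5 ± 0.9 %
state 1: D = 0.0786 ± 0.0011 µm²/s   weight = 55.9 ± 0.9 %
state 2: D = 0.4851 ± 0.0082 µm²/s   weight = 13.6 ± 0.3 %
```

i.e., the sampler identifies the correct number of states and recovers
the generating diffusion coefficients and weight fractions within the
posterior uncertainty (the ± values are posterior standard deviations
over post-burn-in sweeps).

The same machinery is available from the shell:

```sh
nucleotrack simulate --preset wt-stationary --n-steps 50000 --seed 1 --out steps.csv
nucleotrack states steps.csv --iters 2000 --seed 2 --out states.json
nucleotrack run --preset wt-stationary --seed 7 --out runs/demo   # full pipeline
nucleotrack report runs/demo
```

`nucleotrack run` executes the imaging-level pipeline: it renders
camera frames of photoactivated molecules diffusing inside a
spherocylindrical cell, then detects, localizes, links, and analyzes
them, writing per-stage CSV tables, JSON summaries, a manifest of
parameters, and a log.

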