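# Methods

This note documents the models, numerical choices, and validation
strategy behind `nucleotrack`, and what the synthetic-data tests do and
do not establish about real microscopy data.

## Units, grid, and timing conventions

Positions are nanometers from the image corner; pixel centers sit at
half-integer multiples of the pixel size; pixels and frames are
0-based. The camera pixel size is fixed at 49 nm/px (consistent with
the acquisition gates "15 pixels = 735 nm" and "8 pixels = 392 nm")
and the frame interval at τ = 40 ms. Displacements and diffusion
coefficients are in µm and µm²/s.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
not a mechanistic cell model.

**Geometry.** Cells are spherocylinders (rectangle capped by
half-disks) rasterized on the 49-nm grid. The grid height is kept even
so the long axis falls on a pixel edge; the rasterization errors of the
two flat walls then cancel and the mask area tracks the analytic area
to well under 2%. Default lengths follow the measured growth-phase
means (3.76 µm wild-type exponential, 2.07 µm stationary, 3.99/2.71 µm
for the *hns* deletion); widths default to 1.0 µm (exponential) and
0.9 µm (stationary), nominal values for *E. coli* rods.

**Step-level simulation** (`simulate_steps`) draws hidden state
sequences from the Markov chain started at the stationary weights and
emits displacements with per-axis variance exactly 2 D_k τ — the same
emission law the sampler assumes — in trajectories of 10 steps by
default (within the pooled-step regime of the analysis, and above the
6-step minimum track length). Free diffusion, no confinement: recovery
tests must not be biased by boundary reflections. An optional additive
static localization-noise variance exists and defaults to zero, since
the MSD law fit by the analysis contains no noise term.

**Condition presets.** The five presets encode the multi-state
parameters measured for HUα in each strain/phase. Printed values used
verbatim: wild-type stationary D = 0.030 (slow, 31%) and 0.080 µm²/s
(intermediate), fast weight 13%, T(fast→slow) = 0.14,
T(int→fast) = 0.10; Δdps stationary intermediate D = 0.12 µm²/s, fast
weight 23%, T(int→fast) = 0.18, T(int→slow) = 0.01; Δhns slow weight
20% (exponential) and 42% (stationary), T(slow→int) = 0.16
(exponential); wild-type exponential fast weight 40%. Unreported
entries are package defaults chosen once: a 0.50 µm²/s fast state
(0.60 for Δhns, where fast diffusion is faster than wild type),
wild-type exponential D = {0.10, 0.50} µm²/s, Δdps slow state at
0.040 µm²/s and 20% (slightly faster and lighter than wild type, as
reported qualitatively), and small residual off-diagonal transition
probabilities (0.01–0.15) consistent with the reported "very low"
escape rates from the slow state. Each transition matrix is completed
by detailed balance around the stationary weights, pi_i T_ij = pi_j
T_ji, so the weights are exactly the stationary distribution of T and
weights and transitions are simultaneously recoverable.

**Confined simulation** (`simulate_confined_trajectories`) adds a
reflecting spherocylinder wall (normal reflection at the nearest wall
point) and exponential photoactivation/bleaching clocks so only a few
molecules are visible at once. Reflection biases apparent D near the
wall; that is why recovery tests use the free-diffusion generator and
the confined one serves geometry-dependent modules. The stationary law
of reflected Brownian motion is uniform over the cell, which the tests
verify with a chi-square on decorrelated samples.

**Rendering** integrates a 2D Gaussian PSF (σ = 150 nm default) over
pixels via error functions, adds constant background, applies Poisson
shot noise, and quantizes to 16 bit. The default brightness
(15,000 counts/spot over background 5) represents an EM-amplified
camera; it is chosen so the default quality filters (below) retain
well-formed fits. PSF width, brightness, and photophysics rates are
free parameters of the generator — no measured values exist for them.

**Nucleoid images** place a centered axial sub-region covering a
prescribed fraction of the mask at intensity N(µ2, σ2) against
N(µ1, σ1) elsewhere, returning the true region for scoring.

## Detection and localization

Candidates are regional maxima strictly above the frame's 95th
intensity percentile; plateaus contribute their lexicographically
smallest pixel, a constant frame has no candidates, and any two
candidates whose 9×9 px fit windows overlap are both discarded.
Each candidate window is fit by least squares with a pixel-integrated
symmetric 2D Gaussian plus constant background (trust-region reflective
with bounds; non-convergence flags the record invalid). The 95%
position confidence half-width is 1.96 × the position standard error
from the Gauss–Newton covariance. Filters: fitted width ≤ 392 nm,
`fit_error` = RMS residual / fitted amplitude ≤ 0.06, and position SE ≤
2 pixels (`stdtol`). The `fit_error` and `stdtol` semantics are this
package's declared definitions (the upstream tool's parameters of the
same name are not publicly specified); both are configurable. Rejected
records are retained with reason codes, so retained + rejected always
conserves the input.

## Linking

Localizations in consecutive frames are matched by minimum total
squared displacement (Hungarian algorithm on an augmented cost matrix
with per-particle birth/death slots priced at the 735-nm gate squared;
pairs beyond the gate are infeasible). There is no gap closing — a
missed frame terminates a track — and no motion model. Tracks shorter
than 4 steps are flagged rather than deleted; step pooling for state
inference additionally requires 6 steps. Within-frame input order does
not affect the result (inputs are sorted before assignment). The
assignment is tested against exhaustive enumeration over all gated
partial matchings for up to 4 molecules per frame.

## MSD analysis

Time-averaged MSD uses all overlapping pairs per lag; the D_app fit is
weighted least squares of MSD = 4 D τ through the origin over the
first four lags, weights = pair counts, with weighted R² and a 0.70
retention threshold. Negative slopes clip to zero and are flagged.
Because the model has no intercept, any static localization error
inflates D_app at small D; this matches the stated analysis model and
is left uncorrected. On 8-step tracks the per-track D_app distribution
is strongly right-skewed: the ensemble mean is unbiased while the
median sits ~15% below the generating D, so validation asserts the
mean. The mixture decomposition of pooled D_app values uses a
Gaussian mixture with BIC selection over 1–4 components unless K is
fixed.

## Mobility-state inference

The sampler is a blocked Gibbs scheme on an overfitted finite hidden
Markov mixture — a weak-limit stand-in for a nonparametric sampler.
Per sweep: (1) per-trajectory hidden labels by forward-filtering
backward-sampling, vectorized across trajectories of equal length;
(2) per-state emission variances σ²_k = 2 D_k τ from conjugate
inverse-gamma updates, prior shape 2 with scale set from the global
mean squared displacement (prior mean = the one-state fit);
(3) transition rows and the initial-state distribution from Dirichlet
posteriors with sparse concentration 1/K_init per entry — the sparse
prior is what lets redundant states empty, as the weak-limit
construction requires; (4) state death. Defaults: 10,000 sweeps
(2,000 for validation runs), K_init = 5, burn-in fraction 0.5,
summaries thinned to at most 500 post-burn-in samples at the modal K.
Samples are canonicalized by ascending D, so summaries are free of
label switching. Reported weights are step-occupancy fractions.

**State death.** Two mechanisms, both with a 50-sweep patience:

* *occupancy pruning* removes states holding < 2% of steps — below
  that occupancy a mobility state is not meaningfully resolved at the
  recommended ≥ 45,000 steps, and lingering "ghost" states that live
  off the cross-over region between two well-separated real states
  (~1% occupancy) otherwise corrupt the state count;
* *a resolvability floor* merges adjacent states whose diffusion
  coefficients stay within a factor 1.6 of each other (or within 3
  combined conditional posterior SDs). Overfitted mixtures sustain
  satellite states that carve off the tail of a real state at a
  slightly offset D; physically distinct mobility states in this
  regime differ by well over 2× in D, so the floor cannot collapse
  real structure.

Validation: on a single-state dataset the posterior mean D matches the
closed-form MLE Σ(dx²+dy²)/(4Nτ) within Monte Carlo error; on 50,000
steps from each condition preset the sampler recovers the modal state
count and the generating D_k, π_k, and probed T entries within a few
posterior SDs (posterior SDs understate sampling scatter slightly, so
an occasional marginal ~3.5 SD offset across many seeds is expected).
The emission model ignores localization error and motion blur, and
steps are treated as independent increments given the labels; the
recovery tests therefore validate the inference machinery, not those
modeling approximations on real camera data.

## PALM rendering and occupancy

Localizations with a 95% position CI below 80 nm each deposit a
unit-mass Gaussian kernel of width equal to their own CI (floored at a
quarter pixel, truncated at 4σ and renormalized so the image integral
equals the localization count). Occupancy trims within-mask
intensities at the 5th/99.95th percentiles (per cell), fits a
2-component Gaussian mixture (k-means++ init, fixed seed), and
thresholds at exactly 0.5 µ2. The mixture is flagged degenerate — and
occupancy withheld — when the histogram is not genuinely bimodal:
1-component fit preferred by BIC, Ashman separation < 2, or bimodality
coefficient (skew² + 1)/kurtosis < 0.45. The extra criteria are needed
because a 2-component fit to unimodal data yields deceptively
separated means (~1.6 SD); all three are affine-invariant, so
occupancy is invariant to intensity rescaling. Cell metrics come from
the convex hull of the mask pixel corners: length = maximum Feret
diameter, width = minimum Feret (rotating calipers) — the width metric
is this package's choice, used only for coordinate normalization.

## Cell coordinates and density maps

The midline is the longest path through the morphological skeleton
graph, trimmed at each end by the local half-width (skeleton branches
inside the pole caps are unreliable), lightly smoothed, extended to
the mask boundary along least-squares end tangents, and oriented by
increasing x. Masks whose skeleton path is shorter than the cell
width collapse to a single-point midline (round cell, no long axis).
Each point maps to l (arc-length of its midline projection, scaled to
the nominal cell length), signed r, and — inside the caps, within
width/2 of either end — the angle Φ to the outward axis. r is
normalized by the per-cell width, l by the length.

Binning uses 5 radial × 20 longitudinal body bins plus 3 |Φ| pole bins
per pole (configurable; the bin counts are a package choice). Bin
areas are rasterized per cell by stratified-jittered 4×4 subpixel
sampling — the jitter is seeded and deterministic, and prevents
coherent aliasing when a bin boundary runs parallel to the pixel grid
(with regular subsampling, a whole pixel row can be mis-assigned and
bias outer-bin areas by several percent). Counts and areas are summed
across cells; fourfold symmetrization (r → −r, l → 1 − l; poles pair
across ends) replaces each equivalence class by its mean, which leaves
densities and totals unchanged and makes the operation idempotent.
Relative density = (counts/area) / (total counts / total area). The
slow/fast split takes trajectories with D_app < 0.15 µm²/s and
> 0.30 µm²/s; the intermediate band belongs to neither set.

## Pipeline and reproducibility

`run_pipeline` chains the stages with a single seed fanned out into
independent per-stage substreams (`SeedSequence.spawn`), writes
per-stage CSV tables, JSON summaries, a manifest with all parameters
and file hashes, and a timing log; identical seeds give byte-identical
outputs. Validation and acceptance runs use 50,000 steps and 2,000
sweeps — sizes chosen so a full recovery of all five condition presets
completes in a few minutes on one CPU while keeping posterior SDs a
few percent of the parameter values.

## Known limitations

* No gap closing, drift correction, or motion-blur/localization-error
  terms in the state-inference emission model.
* The generator's photophysics (exponential activation/bleaching) and
  brightness are stylized; passing tests demonstrate correct inversion
  of the assumed statistical model, not robustness to every camera
  artifact of real data.
* The resolvability floor means two genuine states with D ratio below
  1.6 would be reported as one; at the data scales targeted here such
  states are not separable anyway.
* Cell coordinates assume a rod; strongly bent or branched cells only
  get what midline projection provides.
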