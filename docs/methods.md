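# Methods

## The circuit model

Each cell carries N copies of a plasmid encoding one bicistronic mRNA:
repressor plus reporter, translated together at a fixed translation ratio
`r_ratio`. The deterministic (mean-field) reporter level per cell is

- active-repressor fraction: `ρ(I) = 1 / (1 + (I/Kd_I)^hill_I)` — the
  fraction of repressor not inactivated by inducer at concentration I;
- promoter activity: `a(Rf) = basal + (1 − basal) / (1 + (Rf/K_R)^hill_R)`;
- constitutive-repressor mode: `G_det = N·α·a(R0·ρ(I))`;
- autoregulated mode: `G_det` solves `G = N·α·a(r_ratio·G·ρ(I))`.

The right-hand side of the autoregulatory equation is positive and
non-increasing in G, so the fixed point is unique; it is solved per distinct
copy number with Brent's method on the bracket [0, N·α] (`xtol`
1e-12 relative to the bracket, 200 iterations max; non-convergence raises
with iteration diagnostics). In the strong-repression limit (basal 0,
`hill_R` 1) the fixed point behaves as `G_det ≈ sqrt(N·α·K_R/(r·ρ))`, so the
copy-number elasticity `d log G / d log N` is 1/2 — the dosage-compensation
mechanism by which negative feedback halves the logarithmic sensitivity of
expression to plasmid dosage, while a constitutively repressed promoter has
elasticity exactly 1.

Stochastic layers, in fixed draw order from a single seeded generator per
call:

1. **Copy number**: `N = 1 + M` with M negative binomial targeting mean
   `N_mean` and variance `N_disp·N_mean` (Poisson when the target variance
   does not exceed the mean; constant `round(N_mean)` when `N_disp = 0`).
   A transformed cell carries at least one plasmid.
2. **Intrinsic noise**: `G ~ Gamma(shape = G_det/burst, scale = burst)` —
   the burst-size approximation that yields the gamma-like marginals this
   analysis assumes. `burst = 0` selects the deterministic limit exactly.
3. **Extrinsic noise**: G is multiplied by a lognormal cell-size factor with
   mean 1 and CV² `size_cv2`. In two-channel simulations the two reporters
   have independent copy-number and intrinsic draws but share the size
   factor — cell size is the extrinsic covariate coupling the channels.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| α (output per copy) | 1500 AU | puts the 10-copy circuit's range at ~300–15,000 AU, comfortably above a ~100 AU autofluorescence background at all but the lowest doses |
| K_R, r_ratio, basal | 6, 1, 0 | sets the repressed fixed point near `sqrt(N·α·K_R) ≈ 300` AU, i.e. ~2% of saturation |
| Kd_I, hill_I (LacI-like) | 40 μM, 3 | the 0–1250 μM IPTG ladder then spans ≈47-fold in mean |
| Kd_I, hill_I (TetR-like) | 10 nM, 2 | 4000× stronger inducer binding than the IPTG-like default in absolute concentration (>3 orders of magnitude), so even 1 nM ATc induces |
| N_mean | 10 (p15A-like), 4 (pSC101-like) | conventional copy numbers for these replicons; no measured values exist for these constructs |
| N_disp | 1.0 | near-Poisson plasmid copy control; looser dispersion lets copy noise dominate CV² at full induction, where feedback is released, and pushes the noise-vs-mean band past the factor-2 envelope the defaults are meant to exhibit |
| burst | 5 proteins | small intrinsic contribution (CV² = burst/G ≤ 0.02 over the range) |
| size_cv2 | 0.1 | the empirical extrinsic noise floor for chromosomal bacterial genes |

Measurement defaults: 30,000 events per sample; autofluorescence 100 AU per
unit cell size; 2% multiplicative instrument noise; maturation fractions
`1 − exp(−60/τ)` after a 60-minute translation-inhibited chase with τ = 5.6
min (GFP-like) and 25.7 min (RFP-like), i.e. ≈1.000 and 0.903; scatter
channels report cell size with 15% (FSC) and 25% (SSC) noise — scatter is
only weakly informative about any single cell, which is why only a density
*gate*, not a per-cell normalization, is applied; 2% of events are debris
(small particles, exponential fluorescence with 50 AU scale, 0.25× size).

## The analysis pipeline

**Density gate.** Events are binned on (log10 FSC-area, log10 SSC-height)
into a 64×64 grid spanning the central 99.9% quantile range of each axis
(out-of-range positive events are clipped into edge bins; non-positive
scatter goes to an underflow class and is never retained). The histogram is
Gaussian-smoothed (σ = 1 bin) to stabilize the mode, bins are ranked by
smoothed density (ties broken by bin index), and whole bins are retained in
decreasing order until the next would overshoot `round(f·n)`; inside that
single boundary bin events are admitted in ascending row order until the
count is exact. A sample collapsed into one bin retains the first
`round(f·n)` events and is flagged degenerate. Log axes were chosen because
scatter distributions are right-skewed; the original instrument convention
is not recoverable from the protocol.

**Log-binned density.** Values ≤ 0 (possible after background subtraction
or baseline noise) are dropped and counted; at least 100 positive values are
required. Edges are 48 geometric steps from the minimum to the maximum used
value; densities are counts per used event per linear bin width, so the
estimate integrates to 1. Bin centers are geometric midpoints. An all-equal
sample is an error, not a point-mass fit.

**Gamma fit.** `Gamma(k, θ)` is fitted by bounded least squares
(k, θ ∈ (1e-6, 1e9)), initialized from method-of-moments on the binned
density, minimizing `Σ_bins width·(density − gamma_pdf(center))²` — the L2
distance between the estimated and model densities. The width weighting is
a deliberate numerical choice: with data-range log bins, the lowest bins
are extremely narrow in linear units and typically hold zero or one event,
so their density estimates are high-variance spikes; an unweighted
objective lets a degenerate k < 1, θ → bound solution beat the true curve
for exponential-like samples, while the L2 objective recovers k ∈ [1, 50]
to within a few percent of the moment estimators. Optimizer failure returns
the moment initializer flagged `converged=False`; the caller decides.

**Summaries.** `mean_raw` and `variance` are the fitted kθ and kθ²;
`mean_bgsub = mean_raw − control_mean` where the control mean is obtained by
running the identical gate-and-fit procedure on an autofluorescence-only
control sample; `cv2 = variance / mean_bgsub²`, flagged undefined when the
subtracted mean is non-positive. Dividing by the subtracted rather than raw
mean is a convention choice, recorded in the output flag. The dynamic range
of a dose response is taken over nonzero-inducer conditions only (the
zero-inducer point is reported separately). Backbone comparison reports
`100·(1 − mean_low/mean_high)` averaged over matched conditions with SEM.
Crosstalk, per channel and per level of its own inducer, is the span
(max − min) of the mean across the other inducer's levels normalized by the
mean at the lowest other-inducer level (the channel's baseline), so a
doubling scores exactly 1; the worst span is the channel metric, and
channels are declared independent below a tolerance of 0.05 — a numeric
stand-in for a claim the source data support only graphically.

## Microscopy model

Cells are capsules (rods) of radius 4 px whose length scales with the cell
size factor, placed uniformly at random without overlap (up to 200 retries
per cell), filled with the cell's concentration (reporter/size, AU per
pixel) plus any diffuse unbound-protein background. Spots are 2D Gaussians
at the PSF width (σ = 1.3 px at 100 nm/px) integrating to
`fluors·photon_scale`, rendered over a ±6σ window (truncation < 2e-8);
full occupancy of 24 tandem PP7 sites with dimeric coat-protein binding is
48 fluorophores. Pixels then receive Poisson photon shot noise (4 AU per
photon), the camera offset, and Gaussian read noise. Shot noise is included
even though it complicates the noise model because it is the mechanism by
which a bright unbound-protein background degrades spot detectability; with
additive read noise alone, background level would cancel out of the SNR
entirely.

Quantification is exactly the mask-based protocol: per-label mean pixel
intensity minus the mean of the largest connected cell-free region (when it
spans ≥ 1000 px; otherwise all unmasked pixels — the geometric rule for "a
large region containing no cells" is a choice). The integrated
(total-fluorescence) proxy `bgsub_total = bgsub_mean × area` is also
reported; with cell-size variation on, the concentration proxy is less
noisy than the total proxy because division by area removes the shared size
factor. Spot SNR uses the bilinear image value at the spot center (unbiased:
a query at a spot-free point scores ~0 on average, where a max-over-disk
peak would inflate pure noise) against the mean and SD of in-cell pixels in
a 4–8 px annulus; an annulus with fewer than 10 in-cell pixels falls back
to all in-cell pixels beyond the inner radius and flags the score.

## Orchestration and determinism

A run configuration (YAML) fixes circuit, measurement and analysis
parameters, the inducer ladder (defaults: IPTG 0, 2, 4.5, 10, 22.4, 50,
111.8, 250, 559, 1250 μM; ATc 1, 5, 25, 125 nM), replicates (3), and one
integer seed. All per-sample randomness derives from that seed by
`SeedSequence` spawning in a fixed order (controls first, then
conditions × replicates, two sub-streams per sample for population and
measurement), so identical configs reproduce byte-identical outputs. The
run log records the config, its SHA-256 hash, control means, and library
versions. A full default run (33 samples × 30,000 events) takes a few
seconds on one CPU.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis is built for:
gamma-like single-cell fluorescence with multiplicative size variation,
autofluorescence background, weakly size-correlated scatter, a debris
subpopulation, and per-sample event counts of 30,000. It does **not**
simulate kinetics (no Gillespie scheme, no cell-cycle or plasmid
partitioning dynamics, no growth-rate coupling), spectral spillover,
instrument saturation, or maturation kinetics during growth (maturation is
a scalar fraction). Passing tests therefore demonstrate that the pipeline
recovers known ground truth under the distributional assumptions the field
makes — not that those assumptions hold for any particular instrument or
strain. Circuit parameter defaults are conventional values chosen to
reproduce the qualitative behavior of the real systems (dose-response
shape, affinity gap, dosage compensation); no kinetic constants or copy
numbers were measured for these constructs.

## Known limitations

- The gamma fit's mean can be biased by a few percent when the expression
  distribution overlaps the autofluorescence background (fluorescence below
  a few hundred AU here); noise at very low expression is correspondingly
  overestimated, as with the real assay.
- The density gate's retained *set* is deterministic but permuting event
  order can exchange members of the boundary-bin tie class.
- Sub-Poisson copy-number control cannot be expressed by the shifted
  negative-binomial law; `N_disp` below 1 degrades to Poisson.
- FCS files are not read directly; event tables are CSV (the documented
  column contract in `duotune.io`).
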