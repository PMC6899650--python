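# Methods

This note documents the statistical machinery in `sppa`, the conventions
it fixes where several defensible choices exist, and what the synthetic
validation does and does not demonstrate.

## Summary functions

All estimators work on continuous planar coordinates in metres inside an
observation-window polygon; nothing is gridded at the data stage.

**Pair correlation function.**  Distances are binned with a box kernel of
full width equal to the bandwidth h (default 0.10 m; use 0.01 m for
sub-metre quadrats), on the grid r_k = h/2 + k·h up to r_max (default
2.5 m, the longest distance the largest mapped surfaces support).  Each
ordered pair (i, j) contributes 1/|W ∩ W_{x_i−x_j}| — the translation edge
correction, evaluated in closed form for rectangular windows and by
polygon intersection otherwise — and the estimate is normalised by
λ̂² = n(n−1)/|W|², which makes the fixed-n CSR expectation exactly 1.
The binned curve is then smoothed with a centred moving average over
`smoothing_span` grid steps (default 3, i.e. three bandwidths; 5 for very
small dense quadrats); span 1 disables smoothing.  g is undefined below
r = h/2 and is reported as such, never as 0.

**K/L, O-ring, nearest neighbour.**  K uses the same translation-weighted
pair sums accumulated cumulatively, L = √(K/π); being cumulative, L is
not additionally smoothed.  O(r) = λ̂·g(r) with λ̂ = n/|W|.  The
nearest-neighbour CDF D(r) uses the border (reduced-sample) correction,
D(r) = #{i : d_i ≤ r ≤ b_i}/#{i : b_i ≥ r}, carried forward where the
denominator empties and monotonised with a running maximum.  Every
estimator is checked against an independent double-loop implementation to
1e-10 on small fixtures, and against its CSR closed form (g = 1, L = r,
O = λ, D = 1 − exp(−λπr²)) by simulation.

## Null models, envelopes and goodness of fit

Null simulations condition on the observed abundance (fixed-n): envelopes
compare pattern geometry, not specimen counts.  Pointwise envelopes take
the rank-k smallest/largest of the simulated curves at each r; the
production convention is 999 simulations with rank 50 (the 5% extremes),
and calibration studies use the reduced 199/rank-10 mode.  Because
smoothing couples neighbouring grid points, chance excursions arrive in
runs; an excursion is therefore only treated as evidence against a model
when it outlasts the smoothing span (`max_excursion_steps`, default 3
grid steps).

Diggle's goodness of fit uses the squared deviation from the
leave-one-out mean curve, u_i = Σ_r (c_i(r) − mean_{j≠i} c_j(r))², over
the pool {observed} ∪ {simulations}, with
p_d = (#{u_sim ≥ u_obs} + 1)/(n_sims + 1): p_d near 1 is a good fit and
the attainable floor is 1/(n_sims + 1).  For cluster models the sum runs
over the model's fitted distance range (the contiguous region where the
observed g exceeds 1); for the CSR and heterogeneous-Poisson rungs it
runs over the whole grid above the 2 cm exclusion.  A rung is rejected
when either the PCF-based or the NN-based p_d falls to the conventional
5% level, or a sustained envelope excursion remains.

The heterogeneous Poisson background estimates λ(x, y) as the number of
specimens of the focal taxon within a circle of radius R divided by the
circle's area clipped to the window — the clipping is an exact
piecewise-analytic circle–rectangle intersection, so edge sites are not
biased low.  R is grid-searched over {0.2, 0.35, 0.5, 0.7, 0.9} m,
maximising p_d on the PCF; 0.5 m can be pinned via `hp_fixed_R`.  The
lower limit is deliberately strict (R must exceed the dispersal-cluster
scale): a moving-window background at the cluster scale can reproduce the
clustering it is supposed to serve as a null for, collapsing the
HP-vs-Thomas distinction.

## Cluster models and the fitting ladder

The Thomas process (parents Poisson(ρ), Poisson(μ) offspring per parent
with isotropic Gaussian spread σ per axis) has
g(r) = 1 + exp(−r²/4σ²)/(4πσ²ρ) and K(r) = πr² + (1 − exp(−r²/4σ²))/ρ;
the nested (double) process adds a second Gaussian scale, and the
inhomogeneous variant thins a realisation by an intensity surface.
Simulation buffers the parent window by 4σ so edge clusters are not lost.
Total intensity λ is always held at the observed n/|W|, so the mean
cluster size is reported as λ/ρ.

Minimal-contrast fitting minimises the summed squared discrepancy between
observed and model curves over the contiguous aggregated region
(observed g > 1) beyond the 2 cm exclusion — fluctuations around g = 1
and sub-specimen-size segregation are never fitted.  The contrast uses g
directly and K through the variance-stabilising fourth-root transform,
with equal weight when both are fitted; optimisation is Nelder–Mead on
log-parameters from several starts.  Two details matter in practice:
the model curve is passed through the same moving average as the observed
estimate before comparison (otherwise smoothing's peak-flattening biases
σ̂ up), and the ITC's cluster component is fitted to the observed g
divided by the background's mean simulated g — independent thinning
factorises the product density, so this isolates the dispersal component
from the habitat component.

The ladder runs CSR → HP → TC → ITC → DTC, accepting the first rung that
leaves no sustained envelope excursion and survives both p_d tests; a
pattern below the CSR envelope with no aggregation anywhere is
SEGREGATED.  The TC fit basis falls back from PCF+L to PCF-only to L-only
when the joint fit scores poorly (thresholds in `AnalysisConfig`), and
DTC is only attempted when a single Thomas model underperforms and the
residual shows a second sustained positive excursion.  If no rung is
acceptable the candidate with the largest worst-case p_d is reported,
with all candidate scores retained for the report table.  CSR, TC and DTC
map to neutral assembly; HP, ITC and SEGREGATED to niche; the mapping is
total over everything the ladder can emit.

## Bivariate independence

The toroidal-shift test requires a rectangular window (patterns are
clipped to the largest inscribed axis-aligned rectangle, found by grid
search at 0.1 m resolution).  Pattern A stays fixed; pattern B is
translated by a uniform random vector with wrap-around, which preserves
B's univariate structure exactly (asserted on the torus metric) while
destroying cross-correlation.  Non-independence is declared on any
envelope excursion of the cross-PCF.  The effect size reported is
100·(g_extreme − 1) % over the significant range — positive for
aggregation, negative for segregation, the larger magnitude when both
occur.  An annulus-averaged variant is provided as a secondary statistic;
the extreme-value reading is the primary one.

## Erosion screening and retrodeformation

Differential erosion is modelled as an inhomogeneous Poisson intensity
λ = exp(a + b·z) with z ∈ {1, x, y, distance-to-anchor}; the log link
guarantees positivity and nests the homogeneous model at b = 0.  The
intercept is profiled out analytically (so the fitted surface integrates
exactly to n), leaving a bounded 1-D optimisation in b; the exponential
integral is evaluated in closed form along an axis of a rectangular
window and by a 128² tensor Gauss–Legendre rule (masked by the polygon)
otherwise — the integrand is smooth, so quadrature error is negligible
relative to the optimiser tolerance.  Models are ranked by
AIC = 2k − 2ℓ, and a heterogeneous model is only adopted with more than
2 AIC units of support over homogeneity.  The adopted surface can be
passed to the null models as the background intensity.

Tectonic strain is estimated from deformed (originally circular) holdfast
discs: the ratio is the median long/short axis ratio, the orientation an
axial circular mean.  Retrodeformation applies the inverse pure shear to
coordinates, window and disc axes; the default is area-preserving (axes
scaled by √ratio and 1/√ratio), the structural-geology convention that
keeps densities meaningful, with a uniaxial variant behind a flag.

## Synthetic communities: what they do and do not show

`sppa.synthetic` generates ground-truthed surfaces: per-taxon patterns
from the five processes, lognormal body sizes, then strain and erosion in
that order, with every generator parameter and each specimen's erosion
survival recorded.  The scenario bank spans the study-surface ranges
(windows 0.81–115 m², densities ~3–100 /m², abundances ~17–1137).
Fixed-n generators hit their target abundances exactly; the cluster
processes land within Poisson error.

Validation on these communities shows that the estimators are unbiased
under their own conventions, that parameters of the generating cluster
process are recovered (median |σ̂ − σ|/σ ≤ 25% at n ≈ 1000), that the
GOF test holds its nominal size, and that the niche/neutral verdict is
recovered for ≥ 80% of taxa across the four generator classes.  It does
not show that real fossil surfaces satisfy the models' assumptions:
synthetic gradients are smooth log-linear surfaces, real habitat
heterogeneity need not be; synthetic taxa are generated independently,
so bivariate structure only exists when constructed; and specimen body
size is decorative (the analyses are point-based), so finite-size effects
below 2 cm are represented only through the fitting exclusion, not
mechanistically.  ITC-vs-DTC attribution is intrinsically weak — a
location-free summary cannot fully separate "clusters of clusters" from
"clusters on a gradient" — which is why the classification collapses both
sides onto the niche/neutral axis before any ecological claim is made.

## Problem sizes and determinism

Calibration and validation runs use the reduced 199-simulation envelopes,
windows of 10×10 m (20×20 m for closed-form comparisons), per-taxon
abundances of 300–1000, and distances fitted to 1.5 m; the production
defaults (999 simulations, 2.5 m) are a configuration change, not a code
path change.  Every stochastic operation takes a seed or Generator and is
bit-reproducible; the pipeline derives independent per-surface and
per-taxon streams from one root seed, and report CSVs are byte-identical
across reruns with the same seed and configuration.
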