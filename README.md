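# sppa — spatial point process analysis of bedding-plane paleocommunities

`sppa` asks a simple ecological question of a mapped fossil surface: were
the organisms arranged by **niche** processes (habitat association,
competition, facilitation) or by **neutral** processes (randomness and
dispersal limitation)?  It is built for census paleocommunities — bedding
planes that preserve a whole sessile community in life position, such as
the Ediacaran surfaces of Newfoundland and Charnwood Forest — but works on
any marked planar point pattern with an observation window.

## The method

For each sufficiently abundant taxon the package estimates the **pair
correlation function** g(r): the density of neighbouring specimens at
distance r, normalised by the overall density.  g = 1 means complete
spatial randomness (CSR), g > 1 aggregation, g < 1 segregation.  The
observed curve is confronted with a ladder of point-process models, each
scored by 999 Monte-Carlo simulations (pointwise 5% envelopes) and
Diggle's goodness-of-fit p_d on both the PCF and the nearest-neighbour
function D(r):

1. **CSR** — homogeneous Poisson;
2. **HP** — heterogeneous Poisson whose intensity is the taxon's own
   moving-window density (circle radius 0.1 m < R < 1 m): habitat
   association;
3. **TC** — Thomas cluster process (Poisson parents of density ρ, Gaussian
   offspring of spread σ), with the closed form
   g(r) = 1 + exp(−r²/4σ²)/(4πσ²ρ), fitted by minimal contrast to the PCF
   and the L-function L(r) = √(K(r)/π): dispersal limitation;
4. **ITC** — a Thomas process thinned by the heterogeneous background:
   dispersal limitation plus habitat filtering;
5. **DTC** — nested (double) Thomas clustering at two scales;
6. **SEGREGATED** — observed curve below the CSR envelope.

CSR, TC and DTC are read as neutral assembly; HP, ITC and segregation as
niche assembly.  Pairs of taxa are tested for spatial independence with a
**toroidal shift** null on a rectangular sub-window (independent ⇒
neutral; any non-independence ⇒ niche), and the strength of a significant
association is reported as a density change, 100·(g_extreme − 1) %.
Before any of this, differential modern erosion is screened by fitting
log-linear inhomogeneous Poisson intensities in x, y and
distance-to-anchor and comparing them by AIC, and tectonically distorted
surfaces are retrodeformed by restoring elongated holdfast discs to
circles.

A ground-truthed synthetic-community generator (`sppa.synthetic`) emulates
the study conditions — windows from 0.8 to 115 m², densities from ~3 to
~100 specimens/m², taxa of 18–3900 specimens under any of the five
processes, with optional tectonic strain and erosion thinning — so the
whole chain is testable without any field data.

## Worked example

```python
import numpy as np
from sppa import (AnalysisConfig, ObservationWindow, ThomasParams,
                  simulate_thomas, fit_protocol, mean_cluster_size)
from sppa.pipeline import UNIVARIATE_PROCESS

window = ObservationWindow.rectangle(0, 0, 10, 10)
truth = ThomasParams(sigma=0.1, rho=1.0, lambda_total=10.0)   # mu = 10
pattern = simulate_thomas(truth, window, seed=1)

cfg = AnalysisConfig(n_sims=199, r_max=1.5)   # reduced-replicate mode
fit = fit_protocol(pattern, window, cfg, seed=2)
print(f"best model: {fit.kind} ({UNIVARIATE_PROCESS[fit.kind]})")
print(f"sigma = {fit.params.sigma:.3f} m, rho = {fit.params.rho:.2f} /m^2, "
      f"mean cluster size = {mean_cluster_size(fit.params):.1f}")
print(f"p_d(PCF) = {fit.p_d_pcf:.2f}, p_d(NN) = {fit.p_d_nn:.2f}")
```

prints

```
best model: TC (neutral)
sigma = 0.109 m, rho = 0.95 /m^2, mean cluster size = 10.1
p_d(PCF) = 0.88, p_d(NN) = 0.40
```

i.e. the ladder rejects CSR and the heterogeneous Poisson background,
accepts a Thomas cluster model whose recovered cluster spread (0.109 m vs
the true 0.1 m) and mean cluster size (10.1 vs 10) are close to the
generator's, and labels the taxon's distribution neutral (dispersal
limitation).  A batch of surfaces goes through the same ladder plus the
bivariate tests with

```
sppa run --maps surface1.csv surface2.csv --out reports/ --seed 1
```

which writes `fit_table.csv` (the per-taxon model table), `bias_report.csv`,
`bivariate_table.csv`, `surface_summary.csv` and the PCF/envelope figures.
`sppa simulate --scenario e_surface_like --seed 3 --out e.csv` generates a
synthetic surface from the built-in scenario bank.

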