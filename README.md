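# coexist-eca

Trait-based modelling of plant competition under elevated atmospheric CO₂.

Rising CO₂ (Cₐ) affects plant species unequally, so it can reorder
competitive hierarchies and reshape grassland communities. This package
implements a deterministic plant carbon–nitrogen production model in which a
species is a vector of twelve ecophysiological traits, and couples it to two
classical — and philosophically opposed — theories of competition:

* **Resource-use theory** (Tilman): the species that, in monoculture,
  depletes a limiting resource furthest wins in mixture. Each species'
  monoculture equilibrium yields a residual soil-nitrogen supply
  `R* = N_min exp(−k_r (1−a_f)/S_r · NPP*)` and a residual light level
  `I* = IPAR exp(−k_s · 0.4·SLA·a_f/[C]_f · NPP*)`. Species A excludes B
  when `R*_A < R*_B` **and** `I*_A < I*_B`; a trade-off across the two
  resources means coexistence.
* **Resource-capture theory** (Grime/Herbert): both species grow together,
  partitioning absorbed PAR and nitrogen uptake continuously according to
  their capture potentials (`k_s·LAI` for light, `k_r·B_r` for nitrogen),
  with the weaker competitor receiving slightly more than its proportional
  share. The outcome is the winner's equilibrium share of total biomass
  (the dominance ratio, 0.5–1).

Photosynthesis follows the Farquhar C₃ biochemical model with a two-leaf
(sunlit/shaded) canopy and the Medlyn optimal-stomata intercellular CO₂,
`C_i = C_a · g₁/(g₁ + √D)`. Whole-plant respiration is folded into a carbon
use efficiency `Y` (NPP = Y·GPP). Nitrogen uptake saturates with root
biomass, `N_up = N_min (1 − e^{−k_r B_r})`, with `N_min` = 3 g N m⁻² yr⁻¹
held constant. Daily weather (PAR, temperature, VPD) comes from a built-in
deterministic seasonal generator and is recycled each simulation year.

The package supports monoculture equilibria (by 23-year daily simulation and
by an independent analytic fixed point, cross-checked to 1%), pairwise and
all-pairs tournaments, two-species mixture runs, and the full study designs:
18 single-trait variants (each trait ±50% of baseline) and uniform random
trait sampling, everything at ambient (360 ppm) and elevated (550 ppm) CO₂.

## Worked example

```python
from coexist_eca import (
    base_traits, default_forcing, solve_equilibrium,
    pair_outcome, simulate_mixture,
)

forcing = default_forcing()           # 2500 MJ m-2 yr-1 PAR, temperate cycle
base = base_traits()                  # Table of baseline grassland traits

eq_a = solve_equilibrium(base, forcing, 360.0)
eq_e = solve_equilibrium(base, forcing, 550.0)
print(eq_a.npp_star, eq_e.npp_star)   # 295.8  345.4  (g C m-2 yr-1)
print(eq_a.r_star, eq_a.i_star)       # 0.0105 g N m-2 yr-1, 1012.8 MJ m-2 yr-1

fast = base.replace(Y=0.75, species_id="fast")   # higher carbon use efficiency
print(pair_outcome(solve_equilibrium(fast, forcing, 360.0), eq_a).outcome)
# Outcome.A_WINS — the efficient species depletes both N and light further

mix = simulate_mixture(fast, base, forcing, 360.0, years=120)
print(mix.npp_i, mix.npp_j, mix.dominance_ratio)
# 246.6  103.9  0.70 — under capture partitioning the winner dominates
# without full exclusion
```

The baseline monoculture equilibrates at NPP* ≈ 296 g C m⁻² yr⁻¹ (LAI 1.5,
leaf N:C 0.018) and gains 17% production at 550 ppm (E/A = 1.168). Across
random trait space the enhancement ratio is strongly negatively
rank-correlated with ambient productivity — slow growers benefit most —
which is what drives the model's headline behaviour: elevated CO₂ narrows
productivity differences, increases the number of coexisting pairs under
resource-use theory and lowers dominance ratios under resource-capture
theory, while rarely changing who wins.

## Command line

```sh
coexist-eca single-trait   --out out/single/
coexist-eca random-use     --config cfg.yaml --out out/use/
coexist-eca random-capture --config cfg.yaml --out out/capture/
```

The YAML config can set forcing parameters (or a forcing CSV), the two CO₂
levels, sample sizes, seeds and mixture run length. All outputs are CSV
tables (rankings, equilibria, pair shares, binned histograms) plus a JSON
run manifest.

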