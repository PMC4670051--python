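# Methods

## Model overview

The core model tracks three pools per species — foliage carbon `B_f`, root
carbon `B_r` (both g C m⁻²) and a whole-plant nitrogen pool — with a daily
time step and a one-year weather cycle recycled every simulation year. Daily
updates:

```
GPP   = canopy photosynthesis(LAI, n_f, weather, Ca)        g C m⁻² d⁻¹
NPP   = Y · GPP
dB_f  = a_f · NPP − (S_f/365) · B_f
dB_r  = (1−a_f) · NPP − (S_r/365) · B_r
N_up  = (N_min/365) · (1 − exp(−k_r B_r))
dN    = N_up − (1−λ) · n_f · (S_f/365) · B_f − ρ · n_f · (S_r/365) · B_r
```

Leaf N:C `n_f` is diagnosed from the pool, `n_f = N / (B_f + ρ B_r)`,
clamped to [0.005, 0.10] g N g⁻¹ C; leaf area index is
`LAI = 0.4 · SLA · B_f / [C]_f` with SLA converted to m² g⁻¹ DM, 0.4 the
leaf-to-canopy SLA scaling, and `[C]_f` = 0.44 g C g⁻¹ DM. Foliage turnover
is fixed at `S_f` = 1 yr⁻¹, which makes the LAI–NPP equilibrium relation
dimensionally closed. Net mineralization `N_min` = 3 g N m⁻² yr⁻¹ is
constant: nitrogen is always limiting, and there is no mineralization
feedback, water limitation, or population demography.

A species is the 12-vector of traits (`V_cmax/N`,
`J_max/V_cmax`, `g₁`, `Y`, `k_s`, SLA, `a_f`, `S_r`, `k_r`, `ρ`, `λ`, plus
a label); root allocation is always `1 − a_f`. `J_max/V_cmax` (1.86) and
`k_s` (0.6) are held at baseline in all generated species sets. Sampling is
independent-uniform on ±50% of baseline per trait; a hook for joint
samplers exists but is unused by the shipped designs.

## Canopy photosynthesis

Leaf biochemistry is the Farquhar C₃ model: gross assimilation is the
minimum of the Rubisco-limited and RuBP-regeneration-limited rates, with
Arrhenius temperature responses (25 °C references: Γ* = 42.75 μmol mol⁻¹,
K_c = 404.9 μmol mol⁻¹, K_o = 278.4 mmol mol⁻¹; activation energies 37.83,
79.43, 36.38 kJ mol⁻¹; V_cmax and J_max at 65.33 and 43.54 kJ mol⁻¹).
Electron transport follows a non-rectangular hyperbola (θ = 0.7, quantum
yield α = 0.26 mol e⁻ per mol absorbed photon). No leaf day-respiration is
subtracted — whole-plant respiration enters exactly once, through Y.

Leaf photosynthetic capacity scales with leaf nitrogen per area,
`N_area = n_f · 1000·[C]_f / SLA` and `V_cmax,area = (V_cmax/N) · N_area`.
The canopy is a two-class (sunlit/shaded) big leaf: incident PAR is split
into a fixed diffuse fraction (0.3) and a beam; both attenuate with the
species' `k_s`; beam is absorbed only by sunlit leaves; leaf absorptance is
0.85. The diurnal course is a half-sine over daylength, integrated with
3-point Gaussian quadrature; 1 MJ PAR = 4.6 mol photons.

An annual *activity factor* of 0.55 multiplies canopy assimilation. It
stands in for phenology the model does not resolve (winter dormancy, spring
regrowth from reserves, late-season senescence) and was fixed once so that
the baseline monoculture equilibrium lands in the production range typical
of nitrogen-limited temperate grassland (NPP* ≈ 300 g C m⁻² yr⁻¹, leaf N:C
≈ 0.018, LAI ≈ 1.5, nitrogen-use efficiency ≈ 100 g C g⁻¹ N). Without it
the equilibrium drifts to leaf C:N ≈ 105 — outside observed grass
stoichiometry — because nothing else in the model penalises extreme
nitrogen dilution.

## Synthetic forcing

Site weather is generated, not observed: sinusoidal annual cycles peaking
at midsummer (day 172) for daily PAR (relative amplitude 0.6, normalised so
the annual total is exactly the IPAR target, default 2500 MJ m⁻² yr⁻¹),
daytime temperature (12 ± 14 °C), VPD (1.0 ± 0.5 kPa) and daylength
(12 ± 4 h); 365-day years, no leap days, no stochastic weather. Determinism
is deliberate: the model is deterministic and equilibrium detection
compares successive recycled years. What the generator does **not**
emulate: day-to-day weather variability, beam/diffuse geometry by solar
angle, frost/drought events, and any site-specific correlation between
temperature, VPD and radiation. Passing tests therefore demonstrate the
model's comparative logic across trait space, not a fit of any particular
site's fluxes; a robustness suite checks that all directional conclusions
survive ±20% changes in the forcing defaults.

## Equilibria: two independent routes

1. **Simulation**: 23 years daily (monocultures), reporting final-year NPP
   and final-year annual means of state; `converged` requires the last two
   annual NPP totals to agree within 0.1%.
2. **Analytic fixed point**: the annual balances `B_f = a_f NPP/S_f`,
   `B_r = (1−a_f) NPP/S_r`, nitrogen closure
   `N_min(1−e^{−k_r B_r}) = n_f·NPP·((1−λ)a_f + ρ(1−a_f))`, and
   `NPP = Y · GPP_annual(LAI, n_f)`. Because `n_f` is an explicit function
   of NPP the system is one-dimensional; it is iterated with damping 0.5,
   Aitken Δ² acceleration and an active set, to 10⁻⁶ relative. Trajectories
   declining below 0.05 g C m⁻² yr⁻¹ are assigned the collapsed
   zero-production equilibrium: a few percent of random trait vectors
   (low `a_f·Y·SLA`) cannot sustain a canopy and are treated as nonviable
   monocultures (R* = N_min, I* = IPAR).

The two routes agree within 1% in NPP* for viable, converged species at
both CO₂ levels. Leaf N:C and LAI are compared at 1.5%: the simulation
reports annual means of a seasonally cycling state, while the fixed point
solves a constant-state balance, and the convexity of photosynthesis in
(LAI, n_f) leaves a ~1% Jensen gap that does not close with longer runs.

Initial pools are `B_f = B_r = 50 g C m⁻²` at leaf N:C 0.03; the
equilibrium is insensitive to initialization (tested against a 10× larger
start). Quantities like R* and I* use exact closed forms in the traits and
NPP*.

## Competition

*Resource use.* Pair outcomes compare (R*, I*) with strict inequalities;
relative differences below 10⁻⁹ are ties, and any tie yields coexistence
(this preserves antisymmetry and makes self-competition coexist).
Tournaments are computed from the vector of monoculture (R*, I*) values
only — one equilibrium per species per CO₂ level, never per pair — so
all-pairs designs scale to arbitrary n. The equivalent NPP-ratio
coexistence bounds (light bound from products `a_f·SLA·k_s`, nutrient bound
from `(1−a_f)·k_r/S_r`) are derived by taking logs of the R*/I*
expressions, making the equivalence with the direct rule exact by
construction; it is verified exhaustively on random samples.

*Resource capture.* Two species share one canopy and one soil volume with
equal dominance (no overtopping). Joint absorption follows the combined
Beer law; each species' share follows the Herbert weights
`w_i = (1−e^{−k_i x_i})(1+e^{−k_j x_j})`, which sum-preserve exactly and
give the weaker competitor slightly more than its proportional share. Each
species converts its absorbed PAR with a light-use efficiency computed
daily as its *monoculture* canopy assimilation per unit monoculture
absorbed PAR at its current LAI and leaf N — one photosynthesis code path,
and the mixture reduces exactly to the monoculture model when the
competitor's LAI is zero. A species is declared extinct when its total
biomass falls below 10⁻⁶ of the pair total (outcomes are insensitive over
10⁻⁴–10⁻⁸); the dominance ratio is then exactly 1. Both species start from
identical pools so outcomes reflect traits, not head starts.

The dominance ratio uses total (foliage + root) biomass; the winner's share
of total production is reported alongside, and the two differ negligibly
except in root-heavy pairs (e.g. the root-turnover contrast, where the
biomass share exceeds the production share).

Mixture runs use 120 years in the study pipelines: near-exclusion
transients decline slowly under this forcing, and 120 years leaves winner
shares stable to ~0.01 against runs twice as long; the per-species
convergence flag (0.1% annual NPP change, or extinction) still reports
strict equilibration honestly.

## Study designs and statistics

Single-trait design: 18 variants (each of 9 varying traits at 0.5× and
1.5× baseline), scored by resource-use ability (1 per win, 0.5 per
coexistence over the 17 pairings) and by mean biomass share over the 153
capture pairings (an extinct opponent contributes a share of 1 to the
survivor and 0 to itself). Random designs default to 2000 species
(resource use) and 500 pairs (resource capture), sized so the full
pipeline runs in minutes; both scale up by argument. Trait importance is
`(mean winner − mean loser)/overall mean` over decisive pairs (resource
use excludes coexisting pairs; under capture the winner is the species
with biomass share > 0.5). Rank correlations are Spearman with
average-rank ties (scipy), cross-checked against a brute-force rank
oracle. Species whose ambient monoculture NPP* exceeds 1 g C m⁻² yr⁻¹
count as viable for "every species" properties (CO₂ fertilization,
enhancement-ratio correlations); nonviable species still enter
tournaments.

## Known limitations and structural notes

* In the single-trait resource-use tournament the high-`a_f` and high-`Y`
  variants necessarily coexist rather than one excluding the other, and
  likewise `−a_f` and `−Y`. This is structural, not parametric: `+a_f`
  would need NPP*(+a_f) > 1.5·NPP*(+Y) to win the nutrient comparison
  (their R* exponents are 0.0127 vs 0.0191 per unit NPP), but `a_f` and
  `Y` enter the light-capture equilibrium almost symmetrically, so their
  NPP* ratio stays near 1 in every regime from open-canopy N-limited to
  light-saturated. Under capture partitioning, by contrast, both extreme
  pairs end in complete exclusion, as the acceptance script shows.
* Two-species mixtures only; extending capture partitioning to k species
  is straightforward but unimplemented. Resource-use theory is inherently
  limited to as many coexisting species as resources (two).
* No water limitation, no phenology beyond the annual activity factor, no
  demography, no trait correlations in the shipped samplers.
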