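# Methods

This note documents the models implemented in `gutflux`, their assumptions,
the parameters that matter, and the numerical and design choices made where
the problem left room. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Metabolic model and FBAwMC

A metabacterium is a metapopulation of gut bacteria represented by one
stoichiometric network. Fluxes `f` (mmol·gDW⁻¹·h⁻¹) over the irreversible
reaction set satisfy steady state `S·f = 0`; the objective is the flux of an
ATP-hydrolysis pseudo-reaction (ATP → ADP), so "growth" is ATP production
rate, converted as `μ = f_ATP/27.2` h⁻¹. On top of the flux bounds, the
molecular-crowding constraint `Σᵢ aᵢfᵢ ≤ V_prot` limits the total enzyme
volume: `aᵢ` is the volume fraction of cell needed to drive unit flux
through reaction `i`, `V_prot = 0.2` (default) the fraction of the cell
available for metabolic enzymes. Removing the budget (`V_prot=None`)
recovers standard FBA exactly — this identity is an acceptance check.

Choices and caveats:

* **Reversible splitting.** Every reversible reaction becomes a
  forward/backward irreversible pair with negated stoichiometry; the
  crowding coefficient is duplicated (the same enzyme catalyses both
  directions). Deleted reactions have upper bound 0; reintroduced ones get
  the "practically infinite" bound 999999.
* **Crowding coefficients** are not known per reaction; they are sampled.
  The sampler supports an empirical table (resampling with replacement) and
  a lognormal fallback, defaults `ln a ~ N(ln 0.02, 1)`. Rationale for the
  defaults: at full budget a median-cost reaction then carries
  `V_prot/a ≈ 10 mmol·gDW⁻¹·h⁻¹`, the scale of measured glucose uptake, and
  measured coefficient distributions span about a decade and are roughly
  lognormal. Exchange pseudo-reactions model transport availability, not
  cytosolic enzyme volume, and are excluded from the crowding sum
  (configurable).
* **Degenerate optima.** Exchange fluxes feed the community dynamics, so
  they must be deterministic. The default solve is lexicographic: maximize
  ATP, then among optima minimize total flux (a second LP with the
  objective column's lower bound fixed at the optimum). The spatial loop
  uses a single-phase approximation instead — maximize `f_ATP − ε·Σf`,
  `ε = 10⁻⁶` — which halves LP count at an O(ε) objective perturbation;
  both modes are deterministic and configurable.
* **Rate-yield trade-off.** Evolution can push all `aᵢ → 0`; growth is
  therefore capped by an empirical maximum-yield curve. With carbon uptake
  expressed in glucose equivalents `G_up` (total uptaken carbon / 6), the
  cap is `μ_max = G_up/(α·G_up + β)`, α = 3.9, β = 2.8 (asymptote
  `1/α ≈ 0.256 h⁻¹`; zero carbon → zero growth). An alternative published
  form `μ_max = 1/(α·G_up)` is available via `tradeoff_form="intext"`, but
  it is not used by default: it *decreases* with uptake and diverges at
  zero uptake, whereas the default form is the yield curve that the
  trade-off data bound from above. The cap applies to μ only; fluxes stay
  at the LP optimum (an accepted energy-bookkeeping simplification). The
  well-mixed model runs with the cap off — the trade-off exists to
  discipline the *evolving* spatial model.
* **Freely available inorganics** (hydrogen gas, water, sodium, ammonium,
  phosphate, sulfate, protons) have unlimited influx in every environment.
  In the dynamic models their concentrations are externally buffered:
  pinned, excluded from negativity checks and from excreted-species counts.
  None of them carries carbon, so cross-feeding ledgers are unaffected
  (CO₂ is *not* in this set and is tracked).

## 2. Toy fermentation network

The built-in network covers the main colonic carbohydrate fermentation
routes with 15 metabolites and ~40 irreversible reactions after splitting:
glycolysis (glc → 2 pyr + 2 ATP + 2 NADH), lactate fermentation, propionate
fermentation (lumped succinate route, pyr + 2 NADH ↔ ppa), the acrylate
pathway (lac + NADH ↔ ppa), pyruvate dehydrogenase and formate-lyase,
butyrate fermentation (2 AcCoA + 2 NADH + ADP → but + ATP), acetate kinase
(AcCoA + ADP ↔ ac + ATP), Wood-Ljungdahl acetogenesis (2 CO₂ + 4 NADH +
ADP ↔ ac + ATP, with a formate-dehydrogenase arm), ethanol fermentation and
the butyryl-CoA:acetate-CoA transferase (AcCoA + ac + 2 NADH → but).
A reversible hydrogenase (NADH ↔ NAD + H₂) closes redox balance; CoA,
water and phosphate are implicit so that every internal reaction is exactly
carbon-balanced over the tracked species (acetyl-CoA counts its acetyl
carbons only). Each of the eleven pathways can be toggled to build
knockouts; a selection without a glucose→ATP route warns but is legal (it
models a non-grower).

Consequences used by the tests: with balanced internal reactions and a
carbon-free objective, `S·f = 0` forces every cell's *net exchange carbon
flux to zero*, so total medium carbon is exactly invariant under metabolism
— conservation audits are sharp, not approximate. Under standard FBA the
highest-ATP route on glucose is homoacetogenic (5 ATP/glucose via
glycolysis + PDH + acetate kinase + Wood-Ljungdahl), so an uncrowded
community collapses onto acetate; under FBAwMC the sampled enzyme costs
make different members prefer different routes, producing the full
fermentation spectrum.

## 3. Well-mixed community model

`init_community` divides total biomass (default 0.01 gDW/l) equally over N
members (default 1000 in the full-scale setting; smaller in desk-scale
runs), each with independently sampled crowding coefficients, in a medium
containing only glucose (default 1 mM). Each step (Δt = 0.1 h):
caps `c_j/(Δt·ΣB)` are computed once from start-of-step concentrations for
all members (simultaneous update), members are solved, concentrations and
biomasses advance by forward Euler, and per-member cumulative uptake /
excretion ledgers accumulate as left-Riemann sums. Total demand can
transiently exceed supply only within Euler error; concentrations are
clipped at zero inside a small tolerance and any larger negativity raises
(it would mean the caps are wrong). The run stops when total growth flux
`Σμᵢ Bᵢ < 10⁻⁶ h⁻¹·gDW/l` or at 48 h (both configurable).

## 4. Spatial evolutionary tube model

Grid: 150 × 10 patches of 1 cm (tube cross-section), 2 cell slots per
patch, Δt = 3 min, 4000 h = 80000 steps. Per step, in this fixed order
(the order is a documented convention; any order sensitivity is a caveat):

1. **Meals** every `TIME_FOOD` (8 h): glucose ~ Normal(42 mmol, 20 % rel.
   SD), truncated at zero by redrawing, spread uniformly over the proximal
   column (concentration via `patch_volume`, default 1 l, so 42 mmol →
   +4.2 mM per entry patch).
2. **Metabolism**: per-patch shared caps `4c_i/(Δt·DENS_MAX·(V₁+V₂))`
   (these make the Euler update non-negative by construction), FBAwMC per
   cell, rate-yield cap on μ, concentration update
   `Δc_i = Δt·Σₙ F_{i,n}·Vₙ·DENS_MAX/4`, volume update `V += V·μ·Δt`,
   ledgers accumulated. `UPTAKE_HOST` (default 0) optionally removes a
   fraction of wall-adjacent SCFA per step — a no-op hook by default, as
   the walls are impermeable.
3. **Death** with rate `DEATH_BASAL + DEATH_DENS·n/n_max` (0.025 and
   2.0 h⁻¹): `n` counts occupied slots in the 8 Moore-adjacent patches plus
   the own patch's other slot, `n_max = 17` in the interior and reduced at
   edges. Probability per step is rate·Δt, clamped at 1 with a warning.
   Dead cells vanish; no lysis recycling (simplest reading, a stated
   modelling caveat).
4. **Division and mutation**: a cell with V ≥ 2 and a free slot splits
   volume and ledgers equally; *each daughter* genome is then mutated
   independently, per reaction: deletion (ub → 0) w.p. 0.002,
   reintroduction (ub → 999999) w.p. 0.0002, crowding drift
   `a → a·10^step`, step ~ N(0, 0.2), w.p. 0.002. Probabilities are per
   reaction per division event — the 10:1 deletion:reintroduction ratio
   only makes sense per reaction. Exchange reactions and the objective
   never mutate (deleting glucose import would conflate transport loss with
   pathway loss; configurable). With V ≥ 2 and no free slot the volume
   clamps at 2 (local carrying capacity).
5. **Movement**: slots are visited in random order; each slot (occupied or
   not) swaps with a uniformly chosen slot of a uniformly chosen Moore
   neighbour patch w.p. 0.05, at most one move per slot per turn.
6. **Advection** every `TIME_DRIFT` (15 min): all metabolite columns shift
   one patch distally — 150 shifts give the 37.5 h transit time. The distal
   column's contents leave through the open boundary (logged for the mole
   audit); the proximal column refills with zeros (the boundary choice the
   model leaves open — only distal outflow is specified). With probability
   `P_CELL_FLOW` the cells shift too, re-entering proximally (periodic),
   which models transit so fast that adherence fails ("diarrhea").
7. **Diffusion**: explicit 4-neighbour scheme, `D = 14×10³ μm²/s`,
   `D·Δt/L² = 0.0252` (a startup check refuses configurations ≥ 0.25);
   no-flux at the walls *and* both ends — longitudinal transport is
   advection's job — so the scheme conserves moles to machine precision on
   a closed grid.

Randomness: one `numpy` Generator per run, seeded from the config; the
draw order (init → per step: meals, death, mutation, movement, advection)
is part of the reproducibility contract. Runs are bit-reproducible from
(config, seed).

### Desk-scale variant

`SpatialConfig.scaled_down()` (20 × 4 patches, 200 h) exists for tests and
exploration. Shrinking only the grid starves the system: the 20-column
tube has a 5 h transit against the 8 h meal period, so at most one meal
pulse is ever resident (the full tube holds ~4.7) while the death term is
unchanged — the population verifiably goes extinct. The scale-down
therefore preserves the governing dimensionless ratio, meal period /
transit time (≈ 0.21): meals arrive hourly, sized 4.2 mmol so the entry
column stays at the ~1 mM scale of the well-mixed model. This follows the
model's own stated calibration rule for the meal size — nutrients mostly
consumed during passage, population sustained — and in the scaled world
>90 % of the glucose is consumed with a persistent population of order ten
cells. All rates, probabilities, the mutation model and the trade-off keep
their full-scale values. What a green scaled-down test establishes is the
*direction* of the evolutionary effects (genome-size decline, distal
enrichment of cross-feeding, its collapse under cell flow) — not the
full-scale magnitudes, which require the genome-scale network and an
empirical crowding table that are not shipped here.

## 5. Cross-feeding and the other analyses

* **Cross-feeding.** From cumulative mole ledgers per species and
  metabolite, `C(i) = Σⱼ c_C(j)·max(F_up,tot − F_ex,tot, 0) −
  6·F_up,tot(i, glc)` and `C_rel = ΣᵢC(i)/ΣᵢΣⱼc_C(j)F_up,tot(i,j)`.
  The raw `C(i)` can be negative only for a species that both takes up and
  excretes glucose; it is floored at 0 before the community sum (a species
  cannot cross-feed a negative amount) and the unfloored value is reported
  for transparency. Metabolites with unknown carbon count contribute zero
  and log a warning. `C_rel` is invariant under species relabelling and
  under splitting a ledger into identical halves (property-tested).
* **Positional profiles** average the per-cell factor
  `C(i)/Σⱼc_C(j)F_up,tot(i,j)` over rows and a snapshot time window per
  tube column; empty columns are missing values, not zeros.
* **Niche assays** solve each cell in six homogeneous environments
  (glucose, acetate, formate, lactate, propionate, CO₂+H₂), one carbon
  source at a saturating cap of 1000 mmol·gDW⁻¹·h⁻¹ (matching the
  well-mixed cap scale) plus the unlimited inorganics, reporting the
  rate-yield-capped growth rate.
* **Phenotype clustering** is agglomerative with average linkage and
  Euclidean distance on the growth-rate vectors (scipy). The reported flat
  cut is the largest relative gap between consecutive merge heights (no
  cut rule is prescribed by the problem; the full dendrogram is always
  emitted, with Newick export).
* **Stratification profiles** are per-metabolite, per-column means over
  rows and a time window.

## 6. Numerics and implementation notes

* LP engine: GLPK via `swiglpk`, one persistent problem per network
  *structure*; per-solve work is O(#reactions) bound/row/objective
  rewrites. Each solve starts from the standard basis so identical inputs
  give bit-identical solutions regardless of history (~50 μs per solve on
  the toy network). scipy's HiGHS `linprog` and an exhaustive
  vertex-enumeration routine serve as independent oracles in the tests,
  never as the implementation.
* Tolerances: LP tolerance 10⁻⁹; concentrations are clipped at zero within
  ~10⁻⁶ relative (Euler slack under simultaneous caps); "zero growth"
  status below 10⁻⁸ ATP flux.
* Known limitations: no lipid/amino-acid metabolism, mucus, oxygen or pH
  feedback; no host uptake by default; no biomass recycling from dead
  cells; forward Euler throughout (step sizes chosen so caps, not
  stability, bind); the toy network lumps cofactor stoichiometry (e.g. one
  ATP for the full Wood-Ljungdahl route), so its yields are cartoon-level
  even though carbon and redox balance exactly.
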