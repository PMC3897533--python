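# Methods

## Model structure

The simulator advances eight biomass pools (g·m⁻² AFDM) in daily
discrete time over a 90-day "over-summer growth" window. There is no
reproduction, movement, spatial structure or demographic noise; the
model is a pure biomass-flow bookkeeping of a stream reach.

Pools: algae `A`, detritus `D`, vulnerable algivores `H_alg` and
detritivores `H_det`, armored algivores `G_alg` and detritivores
`G_det`, trout `T`, salamanders `S`. Derived totals `H = H_alg+H_det`,
`G = G_alg+G_det`.

Daily flows, all evaluated from the current day's state (synchronous /
Jacobi update) and applied at once:

| flow | expression |
|---|---|
| algal growth | `b_a·(1−L)·A` |
| grazing | `c_alg·(H_alg+G_alg)·A` |
| detritus input | `I` (constant, donor-controlled) |
| detritus consumption | `c_det·(H_det+G_det)·D` |
| consumer growth | `b_g ×` (that group's realized intake) |
| predation on vulnerable prey | `c_t·T·f(H)` and `c_s·S·f(H)`, `f(B)=B²/(α²+B²)` |
| predation on armored prey | `armored_cap·c_s·S·f(G)` (salamanders only; see below) |
| emergence | `e_h·(H+G)` |
| background mortality | `m_h·(H+G)`, applied per pool |
| trout terrestrial intake | `min(c_t·T, X)` |
| salamander terrestrial intake | `min(c_s·S, max(0, X−c_t·T))` |
| predator growth | `b_t`, `b_s` × summed realized intake |

Predator demand on vulnerable prey is expressed on the total pool `H`
and apportioned between `H_alg` and `H_det` by biomass share (the
functional response is a property of total prey encounter, not of
feeding guild). Predators have no loss terms: over one growing season
they only accumulate biomass. Absent predators contribute zero intake
and zero growth and are equivalent to a zero starting pool.

**Non-negativity clamp.** Discrete daily steps can overdraw a pool when
summed losses exceed the standing stock plus that day's growth. In that
case all losses of the pool are rescaled by one common factor so the
pool lands exactly at zero. The *realized* (rescaled) flows are what
predators grow on and what the flux ledger records, so prey losses,
predator gains and the ledger agree exactly and detritus obeys
`D_t = D_0 + t·I − Σ consumption` to rounding error. Consumer growth
likewise uses the realized (clamped) basal intake, so consumers cannot
grow on resources the basal pool did not supply.

**Functional response.** Both predators share a Holling type III
response with a single half-saturation biomass α: exploitation vanishes
quadratically at low prey density (a refuge for scarce, cryptic prey in
complex habitat) and saturates at high density. α is shared because the
response is treated as a property of the prey field rather than the
predator; a per-predator override is possible via `ModelParams.replace`
but is not exposed as a default.

**Armored prey.** Armored taxa are invulnerable to trout. Salamander
predation on them is limited to 6.5% (`armored_cap`) of the salamander
daily consumption rate. Two readings of that limit are implemented:

- `armored_response="scaled"` (default): intake =
  `armored_cap·c_s·S·f(G)` — the armored pool is exploited at 6.5% of
  the rate an equally abundant vulnerable pool would be.
- `armored_response="cap"`: intake = `min(armored_cap·c_s·S, c_s·S·f(G))`
  — a hard ceiling on an otherwise full-rate response.

The scaled form is the default on internal-consistency grounds: under
the hard cap, once the armored pool approaches ~1 g·m⁻² the ceiling
binds at `0.065·c_s·S ≈ 0.0195` g·m⁻²·day⁻¹ regardless of α, and
cumulative predator consumption of benthic prey then exceeds what the
reference flux budget (emergence ≈ 2.7× consumption at a mean emergence
of ~0.045 g·m⁻²·day⁻¹) can accommodate. The two readings are a config
switch, not a tuning knob; the choice is made once, here.

**Terrestrial subsidy routing.** The prey flux X is donor-controlled:
consumed-plus-leftover always equals X. Trout, as surface drift
feeders, intercept it first; salamanders, benthic ambush predators,
only profit when `X > c_t·T`. Trout aquatic and terrestrial intakes are
computed independently (the only stated cap is terrestrial ≤ X); a
joint ceiling across both prey sources is deliberately not imposed.

**Algal light input** is proportional to standing algae
(`b_a·(1−L)·A`), i.e. compound growth on the un-shaded light fraction,
which keeps `A = 0` absorbing. A constant-flux alternative was
considered and rejected because it makes an empty algal pool
self-seeding.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `b_a` | light-to-algae conversion | 0.15 | – |
| `L` | canopy cover | 0.90 | – |
| `c_alg`, `c_det` | consumer consumption rates | 0.2, 0.35 | g·g⁻¹·day⁻¹ |
| `b_alg`, `b_det` | consumer growth efficiencies | 0.195, 0.065 | g·g⁻¹ |
| `e_h` | emergence coefficient | 0.039 | day⁻¹ |
| `m_h` | background invertebrate mortality | calibrated | day⁻¹ |
| `c_t`, `c_s` | predator consumption rates | 0.075, 0.02236 | g·g⁻¹·day⁻¹ |
| `b_t`, `b_s` | predator growth efficiencies | 0.10 | g·g⁻¹ |
| `α` | type III half-saturation biomass | calibrated | g·m⁻² |
| `armored_cap` | armored share of salamander demand | 0.065 | – |
| `I` | detritus input | 1.7 | g·m⁻²·day⁻¹ |
| `X` | terrestrial prey input | 0.261 | g·m⁻²·day⁻¹ |

Reference starting pools: `A = 1.59`, `H = 0.1` and `G = 0.13` (56.5%
armored; each class split 50/50 into algivores/detritivores — the
surveys report only totals), `T = 5.12`, `S = 13.42` g·m⁻². The
starting detritus stock `D_0` defaults to the input/consumption balance
point `I/(c_det·(H_det+G_det))` ≈ 42.2 g·m⁻² and is exposed to
calibration. Scenario grids: subsidy multipliers {0, 0.5, 1, 1.5, 2}
at the reference assemblage; armored fractions {0, 0.2, 0.4, 0.565,
0.8, 1} at reference subsidies (0.565 is exactly 0.13/0.23 so the
gradient shares a cell with the reference run); each crossed with the
2×2 predator factorial. The total initial benthic biomass (0.23 g·m⁻²)
is conserved across armoring levels.

## Calibration

`α`, `m_h` and `D_0` are fitted to two hard anchors of the 90-day
reference run — day-90 vulnerable biomass 0.041 g·m⁻² and a 97%
armored share of primary-consumer biomass — plus a soft plausibility
window keeping day-90 algae within 0.5–3× its starting value. The
objective is the summed squared relative anchor error.

Numerically, day-90 `H` is extremely steep in α, so α is *profiled
out*: for each candidate `(m_h, D_0)` it is solved by log-space
bisection (40 iterations; day-90 `H` is monotone increasing in α
because a larger half-saturation biomass weakens predation at every
density). The remaining pair is searched on a 12×12 grid (linear in
`m_h` over [0, 0.1] day⁻¹, log-spaced in `D_0` over [1, 200] g·m⁻²)
and refined with coordinate-wise golden-section sweeps confined to ±
one grid cell. Everything is deterministic; no stochastic optimizer is
involved.

The two hard anchors leave a one-dimensional ridge of exact solutions
in `(m_h, D_0)` — three unknowns, two constraints. A weak log-prior
`(0.1·ln(D_0/D_balance))²` centered on the balance-point default breaks
the degeneracy in favor of the only field-motivated detritus value;
without it the selected ridge point is an artifact of grid placement.
At the defaults the fit is exact (objective ~10⁻¹⁸):
`α = 1.481 g·m⁻²`, `m_h = 0.0377 day⁻¹`, `D_0 = 42.24 g·m⁻²`.
Calibration raises a descriptive error carrying the best-found report
whenever either hard anchor misses the 5% tolerance. The α search
bounds are [10⁻⁴, 10] g·m⁻²; benthic standing stocks in these systems
span roughly 0.2–3 g·m⁻², and capping α at 1 g·m⁻² would truncate the
anchor-feasible region.

The emergence coefficient is separately re-derivable from paired
benthic-biomass/emergence samples by least squares with the intercept
fixed at zero (an empty benthos cannot emit adults); the fit reports
slope, standard error and RMSE.

## Synthetic field data

`streamweb.fielddata` generates seeded stand-ins for each measurement
the configuration rests on: benthic/emergence pairs (uniform benthic
stocks on 0.05–2 g·m⁻², multiplicative Gaussian noise, default CV 10%),
pan-trap prey fluxes (0.261 ± 0.051 g·m⁻²·day⁻¹), litter fluxes
(1.7 ± 1.5), and replicate biomass surveys (32 samples per quantity,
matching the number of surveyed pools, at the published mean ± SD).
All noise is truncated Gaussian (redrawn below zero) since only
mean ± SD is known and biomass is non-negative; the printed SDs are
treated as between-sample variation, not as model parameters. The
generators emulate sampling dispersion only — no trap geometry, taxon
composition, temporal autocorrelation or length–weight conversion — so
tests passing on these fixtures demonstrate that the *parameterization
path* is correct and noise-robust, not that the field protocols would
be.

## Numerical choices

- Pure double precision throughout; rounding only at report time
  (tabular output serialized at 12 significant digits for bit-stable
  regression comparisons).
- The clamp sets an overdrawn pool to exactly 0.0 (not the rounding
  residue of `pool + growth − losses·scale`).
- LRRs of non-positive biomasses raise a descriptive error rather than
  returning ±inf; summary tables record them as NaN.
- Flux-budget ratios with zero consumption raise rather than divide.
- Simulation aborts with the day and pool name if any value goes
  non-finite.

## Reproduction scope and known limitations

With the anchors fitted exactly, the out-of-sample contrasts computed
by `scripts/acceptance.py` split into two groups. The subsidy-gradient
responses (trout LRR and percentage gain 200% vs 0%, the salamander
percentage gain, the vulnerable-prey subsidy LRR) and the reference
emergence/consumption budget agree with the published study within a
few percent. The predator-removal contrasts and the fully vulnerable
(0% armored) scenarios do not: this implementation yields weaker
salamander effects on emergence, a shallower vulnerable-prey response
to trout removal, and far less detritus accumulation when all prey are
vulnerable.

The discrepancy is structural, not a fitting failure. The published
flux budget requires the armored-predation limit *not* to bind (hence
the scaled default), while the published salamander-removal effect
(−31% emergence) is only reachable when it binds; and the published 0%
armored outcomes imply predation strong enough at ~0.2 g·m⁻² prey to
pin the benthos (α ≈ 0.3 g·m⁻²), while the reference anchors force
α ≈ 1.5 g·m⁻². No single parameterization of the reconstructed
equations satisfies both groups; the original display equations were
not recoverable, and at least one term evidently differed from any of
the reconstructions implemented here. The acceptance suite asserts
every published contrast at its stated tolerance and leaves the
unattainable ones failing rather than loosening them; the calibration
report plus `scripts/acceptance.py` output quantify each discrepancy.

Other limitations: no predator mortality or emigration (predators can
only grow within a season), no predator–predator interactions, no
predation during the emergence transition, single-season scope, and a
shared α for both predators.
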