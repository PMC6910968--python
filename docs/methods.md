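# Methods

This note records what the models compute, the assumptions and defaults
behind them, and what passing tests do and do not demonstrate.

## Uncertainty representation and propagation

Every uncertain input is one of four distribution kinds: triangular
(minimum, mode, maximum), uniform (lower, upper), point, or labelled
discrete. Where only a single central figure is available the
conservative convention applies: a triangular distribution with that
figure as the mode and half/double bounds. Negative figures get the
bounds swapped to preserve ordering; exactly zero degenerates to a point
mass (logged), since halving and doubling cannot spread it. Stated ranges
are kept as uniforms — discount rate 10–24%/yr, transport distance
100–400 km — and physical ceilings cap a triangular's upper bound where
doubling would be unphysical (efficiencies near 1, yields near the
stoichiometric maximum).

Scenario uncertainty (feedstock/geography, waste handling, energy
source, nitrogen source) is sampled per iteration from discrete
distributions, default equiprobable.

The Monte Carlo engine defaults to 10,000 iterations. Randomness is
counter-based: a Philox generator keyed on the root seed with the counter
set from `(iteration, crc32(name))` gives every (iteration, parameter)
cell its own substream. Consequences, all tested: results are independent
of parameter ordering; a truncated run is a bit-exact prefix of a longer
one; identical seeds give byte-identical report files. Failed model
evaluations are recorded and logged with their draw, not silently
dropped; more than 1% failures aborts the run. Summary intervals are
2.5/97.5 percentiles of the samples — the 95% interval construction is a
package choice, made because percentile intervals are exact for the
stored empirical distribution and need no normality assumption.

## Process model

The yield frontier comes from a deliberately hand-sized stoichiometric
network (six reactions: glucose uptake, growth, production, and three
export reactions) solved as a linear program: biomass flux is pinned at a
fraction of its maximum and product flux maximized subject to steady
state. The network is carbon-closed by construction — glucose (6 C)
yields either 5 C-mol biomass + 1 CO₂ or one C4/C5 diamine + the balance
as CO₂ — so the maximal product yield is exactly MW_product/MW_glucose
(0.489 g/g putrescine, 0.567 g/g cadaverine) and the frontier is linear
and non-increasing. A genome-scale model would shift these numbers but
not the machinery; drawn yield parameters are clipped at the network
maximum.

The batch model is a two-phase mass balance with a constant volumetric
sugar uptake rate: growth phase `[0, switch_time]` at the biomass yield,
production phase `(switch_time, batch_time]` at the product yield. No
Monod or inhibition kinetics are modelled — at the conceptual design
stage those parameters are unknown, and the key performance indicators
(titre, productivity, overall yield) follow from totals. Productivity
includes the turnaround time in its denominator (conservative; the
alternative is a one-line change). Nitrogen demand uses fixed elemental
compositions: biomass CH₁.₈O₀.₅N₀.₂ (11.4% N by mass), putrescine C₄H₁₂N₂
(31.8% N), cadaverine C₅H₁₄N₂ (27.4% N).

The flowsheet is expressed per kg product. Centrifugation splits the
broth into a cake at the drawn initial water content (default 80%) and a
clarified liquor; extraction adds NaOH (to shift the diamine to its free
base) and make-up solvent for recycle losses; distillation duty is
(c·ΔT + ΔH_vap)/Eff_dist; evaporation dries the cake to 60% water.
Steam and electricity of the non-distillation stages are generic
per-kg-processed factors, supplied as parameters because no specific
published factors exist at this stage. Under integrated waste handling
the dry cake's combustion energy (LHV × boiler efficiency, defaults
16 MJ/kg × 0.8) offsets steam demand, floored at zero with any surplus
discarded (no export revenue); under non-integrated handling the cake
goes to municipal incineration and the credit is zero. Every stage closes
its mass balance to 1e-6 relative, enforced at construction and tested on
1,000 random draws. Plant sizing assumes 8,000 operating hours per year
and a 100 kt/yr output; the fermenter count is the demand ceiling.

## Life-cycle assessment

Attributional, cradle-to-gate. Background data are flat per-unit
elementary-flow vectors per activity — the form in which system-model
results of commercial databases are consumed — rather than a technosphere
matrix inversion; this keeps fixtures desk-scale and the assembly exactly
linear (tested). The inventory is the flow-weighted sum of background
vectors over purchased inputs, net external steam/electricity (by the
drawn energy-source scenario), the waste branch, plant construction
scaled by the fermenter-count ratio, plus direct foreground emissions
(biogenic fermentation CO₂, fugitive solvent as NMVOC).

Characterization covers 18 midpoint categories. Climate change excludes
biogenic CO₂ (by background flag; untagged CO₂ counts as fossil with a
warning) and subtracts the embodied-carbon credit n_C·44.009/M: 1.997 kg
CO₂/kg putrescine, 2.154 kg CO₂/kg cadaverine.

Nylon recipes follow condensation stoichiometry — each repeat unit
releases two waters, so the monomer input per kg polymer is
M_monomer/(M_diamine + M_diacid − 2·M_H₂O) with molar masses putrescine
88.15, cadaverine 102.18, adipic acid 146.14, sebacic acid 202.25, HMDA
116.21, water 18.02 g/mol. Stoichiometric inputs (no polymerization
losses) are assumed. Polymerization steam/electricity are shared across
all four nylons (the chemistry is similar), and monomer transport to the
polymerization site is a uniform 100–400 km freight draw. The
fossil-adipic-acid climate value alternates equiprobably per iteration
between an 80% and a 98% N₂O-abatement variant. Nylon comparisons are
per-iteration paired differences; exceedance fractions are shares of
paired iterations. Hotspot breakdowns normalize per-stage contributions
per category and group stages under 5% into "others", preserving 100%
totals.

## Techno-economics

All in 2014 US$. Capital: a $149M base biorefinery at 33 kt/yr scaled to
the target capacity with exponent 0.836 and converted across years by the
CEPCI ratio (fixture: 585.7 → 576.1); Monte Carlo differences in fermenter
count pass through the same power law. End-of-year discounting, a
two-year 50/50 construction profile, 20-year production lifespan, fixed
opex as a drawn fraction of capital; no tax, depreciation schedule,
working capital or salvage — these follow conventions the underlying
techno-economic literature does not print, are exposed as configuration,
and are documented here as package defaults rather than asserted as
anyone else's. Variable opex prices each flowsheet quantity with its
drawn price. The MSP is found by Brent root-finding on NPV(price), which
is strictly increasing in price, so the root is unique; the capital
charge is the annuity whose discounted sum repays the capital (identity
tested to 1e-9). The cost breakdown decomposes the MSP exactly into
itemized variable opex, fixed opex per kg and the capital charge per kg.

## Social hotspot index

SHI_cat = 100·Σ_T(R_avg·W_T)/Σ_T(R_max·W_T) over themes with data;
no-data themes leave numerator and denominator symmetrically, and an
all-no-data category is reported as missing, not zero. The ordinal→numeric
mapping (low 1, medium 2, high 3, very_high 4) is not published by the
underlying databases; it is configuration-overridable and the
monotonicity and bound properties tested are independent of any
increasing mapping. Weights of 1.0/1.5 ship as fixture data; the ratio
form makes scores invariant to rescaling all weights.

## Sensitivity analysis

Multi-start one-at-a-time: for each parameter, the output is evaluated
over `n_iterations` (default 1,000) draws of that parameter with all
others frozen at a start point drawn from the joint distributions;
repeated from `n_starts` (default 30; the source convention does not
state a count) random starts. The sensitivity metric is
100 × (output range over the sweep) / |baseline|, where the baseline
evaluates **every** parameter at its central value (scenario kept from
the start). A common baseline was chosen over a per-start baseline so
the metric is a pure effect of the swept parameter: for an additive model
the sensitivity is then start-independent up to sweep sampling noise, and
the closed form 100·|a_i|·range(x_i)/|baseline| is recovered (tested to
5%). No published definition of the metric exists, so this definition is
stated prominently; rankings are robust to the choice. Parameters with
mean sensitivity under 5% are grouped into "other parameters"; 2.5/97.5
percentile bounds across starts quantify start dependence.

## Synthetic fixtures — what they are and are not

The fixture generator emulates the *statistical structure* of the study
inputs: a parameter table with the distribution conventions above, a
carbon-closed toy network, a background database covering every activity
any scenario combination can request, an 18-category factor table, and a
social-risk table in which health and safety dominates each
country-sector (with labour rights recurrent), mirroring the qualitative
pattern such assessments report. Background magnitudes are hand-set
plausible values chosen once at design time so the bio-vs-fossil climate
comparison spans its interesting regime — nylons 410/510 favourable,
nylon 46 mixed — exercising exceedance fractions away from both 0 and 1.
They are **not** the values of any licensed database, and numbers
computed on them are illustrative of the method. Real data would change
results quantitatively but not any tested property: every invariant
(linearity, closure, monotonicity, determinism, normalization) is
data-agnostic. What passing tests therefore show is that the machinery is
correct; they cannot show that any particular published headline number
is reproduced, which would require the original proprietary inputs.

Generation is deterministic — the tables are fixed and the seed only
recorded — so `same seed ⇒ bit-identical files` holds trivially and
regressions are exact. A degenerate known-answer bundle (all point
distributions, one scenario) ships with expected MSP, 18 impact scores
and SHI values computed by standalone closed-form arithmetic, independent
of the Monte Carlo and root-finding paths it regression-tests.

## Numerical choices and degenerate inputs

- LP: HiGHS via `scipy.optimize.linprog`; infeasibility reported with the
  unsatisfiable balance set named.
- MSP bracket [0, 100] $/kg, widened geometrically to 1e6 before failing;
  Brent tolerance 1e-10 $/kg.
- Degenerate triangulars (min = max) sample to the mode; point
  distributions sample to exact copies.
- Clipped corners are logged, never silent: negative fermentation off-gas
  (extreme yields) folds into broth water; a steam credit exceeding
  demand is floored at zero net demand.
- Problem sizes: the default test suite runs fixture bundles at the
  "smoke" scale (500 configured iterations, with most tests using
  30–1,000 draws); `scripts/acceptance.py` uses 4,000 Monte Carlo
  iterations and a 12-start × 400-sweep sensitivity pass, sizes chosen to
  put Monte Carlo noise well below the reported precision while keeping a
  single-CPU run in minutes. Library defaults remain 10,000 iterations
  and 30 × 1,000 sensitivity.

## Known limitations

- No correlation between sampled parameters (independence is assumed, as
  is standard at this design stage); no variance-based (Sobol) indices.
- Fed-batch/continuous fermentation, rigorous column simulation,
  endpoint (damage-level) indicators, consequential LCA, tax/financing
  structures and carbon-tax scenarios are out of scope.
- The social module scores curated theme tables; it does not model
  worker-hours weighting across a supply chain.
- Monomer-level MSP and nylon-level LCA share draws but the MSP is not
  computed for polymers.
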