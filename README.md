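# bioassess

Anticipatory sustainability assessment of fermentation-derived nylon
monomers (putrescine and cadaverine), for process engineers and
sustainability analysts evaluating bio-based chemicals at the conceptual
design stage, when almost every input is uncertain.

The package couples four models behind one Monte Carlo engine, so that a
single joint parameter draw feeds every analysis (common random numbers,
making all comparisons statistically paired):

1. **Process model** — a stoichiometric yield frontier (small
   flux-balance LP), a two-phase batch fermentation mass balance
   (titre, productivity, overall yield, nitrogen demand), and a
   per-kg-product flowsheet through centrifugation, solvent extraction,
   evaporation and distillation, with *integrated* (waste cake burned for
   process steam) and *non-integrated* (cake incinerated) waste branches.
   Distillation duty follows E_heat = (c·ΔT + ΔH_vap)/Eff_dist.
2. **Life-cycle assessment** — attributional, cradle-to-gate, 1 kg
   monomer or 1 kg nylon as the functional unit. Inventories are assembled
   from the flowsheet against a background database of per-unit
   elementary-flow vectors and characterized over 18 midpoint impact
   categories. Climate change excludes biogenic CO₂ and credits the
   carbon embodied in the product (n_C·44.009/M kg CO₂ per kg). Bio-based
   nylons 46/410/510 are combined by condensation stoichiometry and
   compared per-iteration against fossil nylon 66.
3. **Techno-economics** — capital scaled by a 0.836 power law and a cost
   index, annualized as the NPV-neutral capital charge; the minimum
   selling price (MSP) is root-found as the price making project NPV zero
   over the plant lifespan.
4. **Social hotspots** — per-category social hotspot index
   SHI = 100·Σ(R_avg·W_T)/Σ(R_max·W_T) for country-specific sectors, with
   theme weights of 1.0/1.5.

Uncertainty follows the conservative convention for early-stage data:
single published figures become triangular distributions with half/double
bounds; stated ranges stay uniform (discount rate 10–24%/yr, transport
100–400 km); scenario axes (4 feedstocks × waste handling × energy source
× nitrogen source) are sampled as discrete distributions. A multi-start
one-at-a-time (OAT) sensitivity analysis ranks parameter influence on any
output.

All background tables are **synthetic fixtures** generated by
`bioassess.synthetic_data`: physically plausible, self-consistent and
deterministic, but not the values of any licensed database. Results are
therefore illustrative of the method, not of any commercial dataset.

## Worked example

```python
from bioassess import generate_fixture_bundle, run_assessment, RunConfig

bundle = generate_fixture_bundle(seed=7, scale="smoke")   # 500 iterations
report = run_assessment(RunConfig.from_bundle(bundle, seed=7))

msp = report.mc.summaries["msp/putrescine"]
print(f"MSP(putrescine): {msp['mean']:.2f} $/kg  "
      f"(95% CI {msp['p2.5']:.2f}-{msp['p97.5']:.2f})")
print(report.nylon_comparison[["mean", "exceedance_vs_ref", "mean_rel_diff_pct"]])
```

prints

```
MSP(putrescine): 3.48 $/kg  (95% CI 2.26-5.48)
           mean  exceedance_vs_ref  mean_rel_diff_pct
nylon66   6.986              0.000              0.000
nylon46   7.774              0.850             11.188
nylon410  4.224              0.004            -39.202
nylon510  4.245              0.010            -38.904
```

Reading: the minimum selling price of bio-based putrescine averages
$3.48/kg (2014 US$) across the uncertainty space. Per kg of polymer,
nylon 46 (bio-putrescine + fossil adipic acid) has a *higher* climate
impact than fossil nylon 66 in 85% of paired iterations — nylon 46 needs
more adipic acid per kg than nylon 66, which cancels the benefit of
replacing HMDA — while nylons 410 and 510 (bio diamine + castor-derived
sebacic acid) cut the climate score by roughly 39% on average and are
essentially always better. The same report object carries all 18 impact
categories per monomer and per nylon, hotspot breakdowns (stages below 5%
grouped into "others"), social hotspot tables, and the full per-iteration
samples.

The same pipeline is scriptable from the shell:

```bash
bioassess fixtures --outdir fixtures/ --scale full
bioassess validate --config fixtures/
bioassess run --config fixtures/ --seed 7 --iterations 2000 --outdir results/
bioassess sensitivity --seed 7 --starts 30 --iterations 1000 --outdir results/
```

## Layout

| module | contents |
| --- | --- |
| `bioassess.uncertainty` | distributions, half/double rule, scenario spaces, counter-based substreams, Monte Carlo engine |
| `bioassess.bioprocess` | stoichiometric LP, batch fermentation, distillation duty, plant sizing, flowsheet |
| `bioassess.lcia` | background database, characterization, biogenic-carbon rules, nylon recipes, hotspots |
| `bioassess.tea` | capital scaling, NPV, capital charge annuity, MSP root-finding |
| `bioassess.social` | social hotspot index aggregation |
| `bioassess.sensitivity` | multi-start OAT sensitivity |
| `bioassess.synthetic_data` | fixture generator and known-answer case |
| `bioassess.pipeline`, `bioassess.cli` | orchestration, validation, reports, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
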