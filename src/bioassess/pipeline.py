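"""End-to-end assessment: sample -> process model -> impacts + MSP -> reports.

Each Monte Carlo iteration draws one joint parameter/scenario sample and
feeds the *same* draw to the process model, the life-cycle assessment and
the techno-economic model (common random numbers), so per-iteration
comparisons — bio-based vs fossil nylon, integrated vs non-integrated —
are statistically paired.  Both diamines are modelled in every iteration;
nylon 46/410/510 are combined from the bio monomers and purchased fossil
monomers and compared against the nylon 66 benchmark.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioprocess, lcia, social, tea
from .sensitivity import SensitivityResult, multistart_sensitivity
from .synthetic_data import FEEDSTOCK_COUNTRY, FixtureBundle
from .uncertainty import (
    Distribution,
    MCResult,
    ParameterDraw,
    run_monte_carlo,
    substream,
)

logger = logging.getLogger(__name__)

MONOMERS = ("putrescine", "cadaverine")


@dataclass
class RunConfig:
    """Resolved run configuration over a fixture bundle."""

    bundle: FixtureBundle
    seed: int
    n_iterations: int
    monomer: str = "putrescine"
    annual_output_kt: float = 100.0
    operating_hours: float = 8000.0
    hotspot_threshold_pct: float = 5.0
    sensitivity_threshold_pct: float = 5.0

    @classmethod
    def from_bundle(cls, bundle: FixtureBundle, seed: int | None = None,
                    n_iterations: int | None = None,
                    monomer: str | None = None) -> "RunConfig":
        cfg = bundle.config
        monomer = monomer or cfg.get("monomer", "putrescine")
        if monomer not in MONOMERS:
            raise ValueError(f"unknown monomer target {monomer!r}")
        return cls(
            bundle=bundle,
            seed=int(seed if seed is not None else cfg.get("seed", 0)),
            n_iterations=int(n_iterations if n_iterations is not None
                             else cfg.get("n_iterations", 10_000)),
            monomer=monomer,
            annual_output_kt=float(cfg.get("annual_output_kt", 100.0)),
            operating_hours=float(cfg.get("operating_hours", 8000.0)),
            hotspot_threshold_pct=float(cfg.get("hotspot_threshold_pct", 5.0)),
            sensitivity_threshold_pct=float(cfg.get("sensitivity_threshold_pct", 5.0)),
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {"config": self.bundle.config, "seed": self.seed,
             "n_iterations": self.n_iterations, "monomer": self.monomer},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    mc: MCResult
    nylon_comparison: pd.DataFrame  # per-nylon climate summary vs nylon 66
    nylon_category_summary: pd.DataFrame  # mean score per nylon per category
    hotspots: lcia.HotspotBreakdown
    shi: pd.DataFrame
    shi_hotspots: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    sensitivity: SensitivityResult | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        samples = pd.DataFrame(self.mc.samples)
        samples.insert(0, "iteration", np.arange(len(samples)))
        samples.to_csv(outdir / "samples.csv", index=False)
        pd.DataFrame(self.mc.summaries).T.rename_axis("output").to_csv(
            outdir / "summary.csv")
        self.nylon_comparison.to_csv(outdir / "nylons.csv")
        self.nylon_category_summary.to_csv(outdir / "nylon_categories.csv")
        self.hotspots.table.rename_axis("stage").to_csv(outdir / "hotspots.csv")
        self.shi.to_csv(outdir / "shi.csv", index=False)
        self.shi_hotspots.to_csv(outdir / "shi_hotspots.csv", index=False)
        if self.sensitivity is not None:
            self.sensitivity.table.to_csv(outdir / "sensitivity.csv")
        with open(outdir / "run_record.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_inputs(bundle: FixtureBundle) -> list[str]:
    """Collect every configuration problem; an empty list means valid."""
    errors: list[str] = []
    try:
        dists = bundle.distributions
    except Exception as exc:  # noqa: BLE001
        return [f"parameter table unreadable: {exc}"]
    for name, dist in dists.items():
        try:
            dist.sample(np.random.default_rng(0), 1)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"distribution {name!r} malformed: {exc}")
    try:
        space = bundle.space
    except Exception as exc:  # noqa: BLE001
        errors.append(f"scenario axes malformed: {exc}")
        space = None
    if space is not None:
        for axis in ("feedstock", "waste_handling", "energy_source", "nitrogen_source"):
            if axis not in space.axes:
                errors.append(f"scenario axis {axis!r} missing")
        # mapping closure over every scenario combination
        import itertools
        axes = {k: list(v.outcomes) for k, v in space.axes.items()}
        for combo in itertools.product(*axes.values()):
            scenario = dict(zip(axes.keys(), combo))
            try:
                mapping = lcia.activity_mapping(scenario)
            except lcia.MappingError as exc:
                errors.append(str(exc))
                continue
            for flow, activity in mapping.items():
                if activity not in bundle.background_db:
                    errors.append(
                        f"background activity {activity!r} (for foreground flow "
                        f"{flow!r}) missing")
    if len(bundle.cf_table.categories) != 18:
        errors.append("characterization table must declare 18 categories")
    needed = {"sugar_uptake_rate", "product_yield", "discount_rate", "capital_base"}
    missing = needed - set(dists)
    if missing:
        errors.append(f"parameter table missing entries {sorted(missing)}")
    if bundle.social_table.empty:
        errors.append("social table is empty")
    return sorted(set(errors))


# ---------------------------------------------------------------------------
# Per-iteration model
# ---------------------------------------------------------------------------


class AssessmentModel:
    """Deterministic function of one ParameterDraw returning all outputs."""

    def __init__(self, config: RunConfig):
        self.config = config
        bundle = config.bundle
        self.bg = bundle.background_db
        self.cf = bundle.cf_table
        self.dists = bundle.distributions
        self.network = bundle.toy_network
        self.flows = self.bg.flows
        self.cf_matrix = self.cf.matrix(self.flows)
        self.categories = list(self.cf.categories)
        # per-kg/per-MJ impact vectors of purchased items, fixed across draws
        self.unit_impacts = {
            act: self.cf_matrix @ self.bg.vector(act) for act in self.bg.activities
        }
        self.unit_climate_fossil = {
            act: self._fossil_climate(self.bg.vector(act)) for act in self.bg.activities
        }
        self.max_product_yield = {
            m: bioprocess.MW[m] / bioprocess.MW["glucose"] for m in MONOMERS
        }
        self.reference_fermenters = self._reference_fermenters()

    def _fossil_climate(self, vec: np.ndarray) -> float:
        total = 0.0
        for i, flow in enumerate(self.flows):
            if self.bg.biogenic.get(flow, False):
                continue
            total += vec[i] * self.cf.factor("climate change", flow)
        return total

    def _central_values(self) -> dict[str, float]:
        return {name: d.mode() for name, d in self.dists.items()
                if d.kind != "discrete"}

    def _reference_fermenters(self) -> int:
        v = self._central_values()
        outcome = bioprocess.simulate_batch(self._ferm_params(v, "putrescine"))
        return bioprocess.size_plant(outcome, self.config.annual_output_kt,
                                     self.config.operating_hours)

    def _ferm_params(self, v: dict[str, float], monomer: str) -> bioprocess.FermentationParams:
        return bioprocess.FermentationParams(
            substrate_uptake_rate=v["sugar_uptake_rate"],
            biomass_yield_growth=v["biomass_yield_growth"],
            product_yield=min(v["product_yield"], self.max_product_yield[monomer]),
            switch_time=min(v["switch_time"], v["batch_time"]),
            batch_time=v["batch_time"],
            turnaround_time=v["turnaround_time"],
            working_volume=v["working_volume"],
            product=monomer,
        )

    # -- single-monomer assessment ------------------------------------------

    def assess_monomer(self, draw: ParameterDraw, monomer: str) -> dict:
        cfg = self.config
        v = dict(draw.values)
        outcome = bioprocess.simulate_batch(self._ferm_params(v, monomer))
        fs = bioprocess.build_flowsheet(outcome, draw, cfg.annual_output_kt,
                                        cfg.operating_hours)
        inventory = lcia.assemble_inventory(
            fs, self.bg, draw, reference_fermenters=self.reference_fermenters)
        scores = self.cf_matrix @ inventory
        climate = lcia.climate_change_score(
            pd.Series(inventory, index=self.flows), monomer, self.cf, self.bg)

        # techno-economics from the same flowsheet
        inputs = fs.external_inputs()
        price_of = {"sugar": "sugar_price", "nitrogen-source": "nitrogen_price",
                    "naoh": "naoh_price", "solvent": "solvent_price",
                    "process-water": "water_price"}
        breakdown = {flow: inputs[flow] * v[p] for flow, p in price_of.items()
                     if flow in inputs}
        breakdown["steam"] = fs.net_steam_mj * v["steam_price"]
        breakdown["electricity"] = fs.electricity_mj * v["electricity_price"]
        if fs.waste_handling == "non-integrated":
            cake = fs.stage("waste handling").inputs["dried-cake"]
            breakdown["waste disposal"] = cake * v["waste_disposal_price"]
        variable_opex = sum(breakdown.values())

        spec = tea.CapitalCostSpec(
            base_cost=v["capital_base"],
            base_capacity_kt=v["base_capacity_kt"],
            target_capacity_kt=cfg.annual_output_kt,
            scaling_exponent=v["scaling_exponent"],
            index_base=v["cepci_base"],
            index_target=v["cepci_target"],
        )
        capital = tea.scale_capital(
            spec, fermenter_ratio=fs.n_fermenters / self.reference_fermenters)
        cashflow = tea.CashflowModel(
            annual_output_kg=cfg.annual_output_kt * 1e6,
            variable_opex=variable_opex,
            fixed_opex=v["fixed_opex_frac"] * capital,
            capital=capital,
            lifespan=int(round(v["lifespan"])),
            discount_rate=v["discount_rate"],
            opex_breakdown=breakdown,
        )
        result = tea.minimum_selling_price(cashflow)
        return {
            "flowsheet": fs,
            "inventory": inventory,
            "scores": scores,
            "climate": climate,
            "tea": result,
        }

    # -- nylon combination ---------------------------------------------------

    def nylon_scores(self, draw: ParameterDraw, monomer_results: dict,
                     adipic_climate: float) -> dict[str, np.ndarray]:
        """Per-category score vectors (len 18) for the four nylons."""
        v = draw.values
        energy = draw.scenario["energy_source"]
        steam_vec = self.unit_impacts[f"steam, {energy}"]
        elec_vec = self.unit_impacts[f"electricity, {energy}"]
        transport_vec = self.unit_impacts["freight transport"]
        steam_cc = self.unit_climate_fossil[f"steam, {energy}"]
        elec_cc = self.unit_climate_fossil[f"electricity, {energy}"]
        transport_cc = self.unit_climate_fossil["freight transport"]
        km = v["transport_km"]
        recipes = lcia.standard_recipes(v["poly_steam_mj"], v["poly_elec_mj"])

        cc_idx = self.categories.index("climate change")
        monomer_vec = {m: monomer_results[m]["scores"] for m in MONOMERS}
        monomer_cc = {m: monomer_results[m]["climate"] for m in MONOMERS}
        bg_vec = {m: self.unit_impacts[m] for m in ("hmda", "adipic acid", "sebacic acid")}
        bg_cc = {
            "hmda": self.unit_climate_fossil["hmda"],
            "sebacic acid": self.unit_climate_fossil["sebacic acid"],
            "adipic acid": adipic_climate,  # N2O-abatement variant of the draw
        }

        out = {}
        for name, r in recipes.items():
            vec = np.zeros(len(self.categories))
            cc = 0.0
            for mono, mass in ((r.diamine, r.diamine_kg), (r.diacid, r.diacid_kg)):
                vec += mass * (monomer_vec.get(mono, bg_vec.get(mono)))
                cc += mass * (monomer_cc[mono] if mono in monomer_cc else bg_cc[mono])
            util = (r.polymerization_steam_mj * steam_vec
                    + r.polymerization_electricity_mj * elec_vec
                    + (r.diamine_kg + r.diacid_kg) / 1000.0 * km * transport_vec)
            vec += util
            cc += (r.polymerization_steam_mj * steam_cc
                   + r.polymerization_electricity_mj * elec_cc
                   + (r.diamine_kg + r.diacid_kg) / 1000.0 * km * transport_cc)
            vec[cc_idx] = cc  # climate column carries the biogenic/credit convention
            out[name] = vec
        return out

    # -- full iteration -------------------------------------------------------

    def __call__(self, draw: ParameterDraw) -> dict[str, float]:
        monomer_results = {m: self.assess_monomer(draw, m) for m in MONOMERS}
        rng = substream(self.config.seed, draw.iteration_index, "adipic-variant")
        adipic_cc = lcia.adipic_acid_cc_variant(
            rng, draw.values["adipic_cc_80"], draw.values["adipic_cc_98"])
        nylons = self.nylon_scores(draw, monomer_results, adipic_cc)
        out: dict[str, float] = {}
        for m in MONOMERS:
            res = monomer_results[m]
            out[f"msp/{m}"] = res["tea"].msp
            out[f"climate/{m}"] = res["climate"]
            for cat, score in zip(self.categories, res["scores"]):
                out[f"impact/{m}/{cat}"] = score
        for name, vec in nylons.items():
            for cat, score in zip(self.categories, vec):
                out[f"nylon/{name}/{cat}"] = score
        self._last_monomer_results = monomer_results
        return out

    # -- hotspot contributions ------------------------------------------------

    def stage_contributions(self, draw: ParameterDraw, monomer: str) -> pd.DataFrame:
        """Signed per-supply contributions (rows) per category (columns)."""
        res = self.assess_monomer(draw, monomer)
        fs = res["flowsheet"]
        mapping = lcia.activity_mapping(draw.scenario)
        contribs: dict[str, np.ndarray] = {}
        for flow, amount in fs.external_inputs().items():
            contribs[flow] = amount * self.unit_impacts[mapping[flow]]
        contribs["steam"] = fs.net_steam_mj * self.unit_impacts[mapping["steam"]]
        contribs["electricity"] = fs.electricity_mj * self.unit_impacts[
            mapping["electricity"]]
        waste_stage = fs.stage("waste handling")
        if "waste-cake-to-incineration" in waste_stage.outputs:
            contribs["waste handling"] = (
                waste_stage.outputs["waste-cake-to-incineration"]
                * self.unit_impacts["municipal incineration"])
        contribs["plant construction"] = (
            fs.n_fermenters / self.reference_fermenters
            * self.unit_impacts["fermentation plant construction"])
        direct = self.bg.zero()
        for flow, amount in fs.emissions().items():
            name = flow.removeprefix("emission/")
            name = {"co2-biogenic": "carbon dioxide, biogenic",
                    "solvent-loss": "nmvoc"}.get(name)
            if name in self.bg._flow_index:
                direct[self.bg._flow_index[name]] += amount
        contribs["direct emissions"] = self.cf_matrix @ direct
        return pd.DataFrame(contribs, index=self.categories).T


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_assessment(
    config: RunConfig,
    outdir: str | Path | None = None,
    with_sensitivity: bool = False,
    sensitivity_starts: int = 30,
    sensitivity_sweep: int = 1000,
) -> RunReport:
    """Run the full Monte Carlo assessment and assemble the report."""
    errors = validate_inputs(config.bundle)
    if errors:
        raise ValueError("invalid inputs:\n" + "\n".join(errors))
    model = AssessmentModel(config)
    logger.info("run %s: seed=%d n_iterations=%d monomer=%s",
                config.config_hash(), config.seed, config.n_iterations, config.monomer)
    mc = run_monte_carlo(model, model.dists, config.bundle.space,
                         n_iterations=config.n_iterations, seed=config.seed)

    cc = "climate change"
    nylon_cc = {name: mc.samples[f"nylon/{name}/{cc}"]
                for name in ("nylon66", "nylon46", "nylon410", "nylon510")}
    nylon_comparison = lcia.compare_nylons(nylon_cc, reference="nylon66")
    cat_rows = {}
    for name in nylon_cc:
        cat_rows[name] = {cat: float(np.nanmean(mc.samples[f"nylon/{name}/{cat}"]))
                          for cat in model.categories}
    nylon_categories = pd.DataFrame(cat_rows).T.rename_axis("nylon")

    # hotspots: mean stage contributions across a subsample of iterations
    n_hot = min(200, config.n_iterations)
    from .uncertainty import draw_parameters
    acc: pd.DataFrame | None = None
    for i in range(n_hot):
        draw = draw_parameters(model.dists, config.bundle.space, config.seed, i)
        c = model.stage_contributions(draw, config.monomer)
        acc = c if acc is None else acc.add(c, fill_value=0.0)
    hotspots = lcia.hotspot_analysis(acc / n_hot, config.hotspot_threshold_pct)

    # social scores for each geography: feedstock sector + biorefinery proxy
    shi_tables, hot_tables = [], []
    for country in sorted(set(FEEDSTOCK_COUNTRY.values())):
        for sector in ("agriculture", "Chemical, rubber and plastic products"):
            record = social.CSSRecord.from_frame(config.bundle.social_table,
                                                 country, sector)
            table, hot = social.aggregate_shi(record)
            shi_tables.append(table)
            hot = hot.assign(country=country, sector=sector)
            hot_tables.append(hot)
    shi = pd.concat(shi_tables, ignore_index=True)
    shi_hot = pd.concat(hot_tables, ignore_index=True)

    sens = None
    if with_sensitivity:
        sens = msp_sensitivity(config, n_starts=sensitivity_starts,
                               n_iterations=sensitivity_sweep)

    report = RunReport(
        mc=mc,
        nylon_comparison=nylon_comparison,
        nylon_category_summary=nylon_categories,
        hotspots=hotspots,
        shi=shi,
        shi_hotspots=shi_hot,
        sensitivity=sens,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "n_failed": mc.n_failed,
            "monomer": config.monomer,
            "reference_fermenters": model.reference_fermenters,
        },
    )
    if outdir is not None:
        report.write(outdir)
    return report


def msp_sensitivity(
    config: RunConfig,
    n_starts: int = 30,
    n_iterations: int = 1000,
    targets: tuple[str, ...] | None = None,
) -> SensitivityResult:
    """Multi-start OAT sensitivity of the minimum selling price."""
    model = AssessmentModel(config)
    monomer = config.monomer

    def msp_of(draw: ParameterDraw) -> float:
        return model.assess_monomer(draw, monomer)["tea"].msp

    dists = model.dists
    if targets is None:
        targets = tuple(n for n, d in dists.items()
                        if d.kind not in ("point", "discrete"))
    return multistart_sensitivity(
        msp_of, dists, config.bundle.space,
        n_starts=n_starts, n_iterations=n_iterations,
        threshold_pct=config.sensitivity_threshold_pct,
        seed=config.seed, targets=targets,
    )
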