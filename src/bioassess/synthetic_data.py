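"""Synthetic input fixtures for the whole pipeline.

None of the proprietary background sources the assessment emulates
(commercial LCI databases, social-risk databases, supplementary parameter
tables) can be shipped, so this module generates every input table the
pipeline needs with the statistical structure the analysis assumes:

* a parameter table of uncertainty distributions (triangular half/double
  rule for single published figures, stated ranges where known: discount
  rate uniform 10-24%, transport uniform 100-400 km, capital $149M at 33 kt),
* a hand-sized carbon-balanced stoichiometric network for the yield frontier,
* a background database of per-unit elementary-flow vectors for every
  activity any scenario combination can request,
* a characterization-factor table over the 18 midpoint impact categories,
* a social-risk table for the feedstock and biorefinery country-sectors.

All magnitudes are illustrative synthetic values chosen once at design time
to be physically plausible; they are not the values of any licensed
database.  Generation is deterministic: the tables are fixed and the seed
is only recorded in the manifest, so regenerating with any seed is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .bioprocess import MW, StoichiometricModel
from .lcia import BackgroundDatabase, CharacterizationTable, DEFAULT_CATEGORIES
from .uncertainty import ConfigurationError, Distribution, ScenarioSpace

FEEDSTOCKS = ("corn-stover-US", "corn-starch-US", "sugar-beet-FR", "sugarcane-BR")
FEEDSTOCK_COUNTRY = {"corn-stover-US": "US", "corn-starch-US": "US",
                     "sugar-beet-FR": "FR", "sugarcane-BR": "BR"}

GENERATOR_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------


def parameter_distributions() -> dict[str, tuple[Distribution, str, str]]:
    """name -> (distribution, group, description).

    Triangular entries follow the conservative half/double convention around
    a single central figure unless a published range is stated (discount
    rate, transport distance) or a physical bound caps the spread
    (efficiencies below 1, yields below the stoichiometric maximum).
    """
    t = lambda a, c, b, u="": Distribution("triangular", (a, c, b), units=u)  # noqa: E731
    u_ = lambda lo, hi, u="": Distribution("uniform", (lo, hi), units=u)  # noqa: E731
    p = lambda v, u="": Distribution("point", (v,), units=u)  # noqa: E731
    return {
        # fermentation
        "sugar_uptake_rate": (t(1.5, 3.0, 6.0, "g/L/h"), "process",
                              "volumetric sugar uptake rate"),
        "biomass_yield_growth": (t(0.2, 0.4, 0.5, "g/g"), "process",
                                 "biomass yield on sugar in the growth phase"),
        "product_yield": (t(0.175, 0.35, 0.45, "g/g"), "process",
                          "product yield on sugar, capped below the stoichiometric maximum"),
        "switch_time": (t(4.0, 8.0, 16.0, "h"), "process", "growth-to-production switch"),
        "batch_time": (p(48.0, "h"), "process", "batch duration"),
        "turnaround_time": (p(12.0, "h"), "process", "clean/sterilize/refill"),
        "working_volume": (p(200_000.0, "L"), "process", "fermenter working volume"),
        # downstream processing
        "cake_water_initial": (p(0.8, "kg/kg"), "process",
                               "water content of centrifuge cake"),
        "solvent_per_kg": (t(2.5, 5.0, 10.0, "kg/kg"), "process",
                           "solvent load per kg product in extraction"),
        "solvent_loss_frac": (t(0.01, 0.02, 0.04, "-"), "process",
                              "make-up fraction of the solvent recycle"),
        "naoh_per_kg": (t(0.25, 0.5, 1.0, "kg/kg"), "process",
                        "NaOH to free the diamine base"),
        "water_per_kg": (p(8.0, "kg/kg"), "process", "process water per kg product"),
        "evap_steam_per_kg_water": (t(0.9, 1.8, 3.6, "MJ/kg"), "process",
                                    "steam per kg water evaporated from the cake"),
        "steam_ferm_per_kg": (t(0.15, 0.3, 0.6, "MJ/kg"), "process",
                              "generic sterilization steam per kg broth"),
        "elec_ferm_per_kg": (t(0.1, 0.2, 0.4, "MJ/kg"), "process",
                             "agitation/aeration electricity per kg broth"),
        "elec_centrifuge_per_kg": (t(0.025, 0.05, 0.1, "MJ/kg"), "process",
                                   "centrifuge electricity per kg processed"),
        "elec_extraction_per_kg": (t(0.025, 0.05, 0.1, "MJ/kg"), "process",
                                   "extraction electricity per kg processed"),
        "dist_sensible_heat": (p(2.9, "kJ/kg/K"), "process",
                               "specific heat of the product stream"),
        "dist_delta_t": (t(65.0, 130.0, 260.0, "K"), "process",
                         "temperature rise to the boiling point"),
        "dist_dhvap": (p(560.0, "kJ/kg"), "process", "enthalpy of vaporization"),
        "dist_efficiency": (t(0.35, 0.7, 0.9, "-"), "process",
                            "distillation efficiency (upper bound physical)"),
        "cake_lhv_dry": (t(12.0, 16.0, 20.0, "MJ/kg"), "process",
                         "lower heating value of dry cake"),
        "boiler_efficiency": (p(0.8, "-"), "process", "combustor/boiler efficiency"),
        # techno-economics (2014 US$)
        "sugar_price": (t(0.15, 0.3, 0.6, "$/kg"), "tea", "fermentable sugar price"),
        "nitrogen_price": (t(0.4, 0.8, 1.6, "$/kg N"), "tea", "nitrogen source price"),
        "naoh_price": (t(0.2, 0.4, 0.8, "$/kg"), "tea", "sodium hydroxide price"),
        "solvent_price": (t(0.75, 1.5, 3.0, "$/kg"), "tea", "extraction solvent price"),
        "water_price": (p(0.0005, "$/kg"), "tea", "process water price"),
        "steam_price": (t(0.0025, 0.005, 0.01, "$/MJ"), "tea", "steam price"),
        "electricity_price": (t(0.01, 0.02, 0.04, "$/MJ"), "tea", "electricity price"),
        "waste_disposal_price": (t(0.025, 0.05, 0.1, "$/kg"), "tea",
                                 "incineration gate fee per kg cake"),
        "discount_rate": (u_(0.10, 0.24, "1/yr"), "tea",
                          "minimum acceptable rate of return"),
        "capital_base": (t(74.5e6, 149e6, 298e6, "$"), "tea",
                         "base biorefinery capital (2011 US$), half/double around "
                         "the single published figure"),
        "base_capacity_kt": (p(33.0, "kt/yr"), "tea", "capacity of the base design"),
        "scaling_exponent": (p(0.836, "-"), "tea", "capital power-law exponent"),
        "cepci_base": (p(585.7, "-"), "tea", "cost index, base year"),
        "cepci_target": (p(576.1, "-"), "tea", "cost index, target year (2014)"),
        "lifespan": (p(20.0, "yr"), "tea", "project production lifespan"),
        "fixed_opex_frac": (t(0.02, 0.04, 0.08, "1/yr"), "tea",
                            "fixed operating cost as a fraction of capital"),
        # LCA-side parameters
        "transport_km": (u_(100.0, 400.0, "km"), "lca",
                         "monomer transport to the polymerization site"),
        "adipic_cc_80": (p(6.15 + 1.05, "kg CO2e/kg"), "lca",
                         "adipic acid climate value, 80% N2O abatement variant"),
        "adipic_cc_98": (p(6.15 - 1.05, "kg CO2e/kg"), "lca",
                         "adipic acid climate value, 98% N2O abatement variant"),
        "poly_steam_mj": (t(3.0, 6.0, 12.0, "MJ/kg"), "lca",
                          "polymerization steam per kg nylon"),
        "poly_elec_mj": (t(1.0, 2.0, 4.0, "MJ/kg"), "lca",
                         "polymerization electricity per kg nylon"),
    }


def parameter_table() -> pd.DataFrame:
    rows = []
    for name, (dist, group, desc) in parameter_distributions().items():
        p1 = p2 = p3 = ""
        if dist.kind == "discrete":
            p1 = ";".join(f"{k}:{v}" for k, v in dist.outcomes.items())
        else:
            ps = list(dist.params) + [""] * (3 - len(dist.params))
            p1, p2, p3 = ps[:3]
        rows.append({"name": name, "kind": dist.kind, "p1": p1, "p2": p2, "p3": p3,
                     "units": dist.units, "group": group, "description": desc})
    return pd.DataFrame(rows)


def distributions_from_table(df: pd.DataFrame) -> dict[str, Distribution]:
    out = {}
    for row in df.itertuples():
        try:
            if row.kind == "discrete":
                outcomes = {}
                for pair in str(row.p1).split(";"):
                    label, _, prob = pair.partition(":")
                    outcomes[label.strip()] = float(prob)
                out[row.name] = Distribution("discrete", outcomes=outcomes,
                                             units=row.units)
            else:
                params = [float(p) for p in (row.p1, row.p2, row.p3)
                          if p not in ("", None) and not pd.isna(p)]
                out[row.name] = Distribution(row.kind, tuple(params), units=row.units)
        except (ConfigurationError, ValueError) as exc:
            raise ConfigurationError(f"parameter {row.name!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Scenario space
# ---------------------------------------------------------------------------


def scenario_space() -> ScenarioSpace:
    eq = lambda labels: Distribution(  # noqa: E731
        "discrete", outcomes={l: 1.0 / len(labels) for l in labels})
    return ScenarioSpace({
        "feedstock": eq(FEEDSTOCKS),
        "waste_handling": eq(("integrated", "non-integrated")),
        "energy_source": eq(("biomass", "grid")),
        "nitrogen_source": eq(("ammonia", "ammonium-sulfate")),
    })


# ---------------------------------------------------------------------------
# Toy stoichiometric network
# ---------------------------------------------------------------------------


def generate_toy_network(product: str = "putrescine") -> StoichiometricModel:
    """Six-reaction carbon-balanced network with hand-verifiable yields.

    Glucose (6 C) either grows biomass (5 C-mol biomass + 1 CO2 per glucose)
    or makes product (one C4/C5 diamine + the balance as CO2).  The maximal
    product yield is therefore MW_product / MW_glucose exactly, and the
    biomass/product frontier is linear and non-increasing.
    """
    n_c = {"putrescine": 4, "cadaverine": 5}[product]
    reactions = {
        "uptake": {"glc": 1.0},
        "growth": {"glc": -1.0, "bio": 5.0, "co2": 1.0},
        "production": {"glc": -1.0, "prod": 1.0, "co2": float(6 - n_c)},
        "biomass_export": {"bio": -1.0},
        "product_export": {"prod": -1.0},
        "co2_export": {"co2": -1.0},
    }
    bounds = {
        "uptake": (0.0, 10.0),
        "growth": (0.0, 1000.0),
        "production": (0.0, 1000.0),
        "biomass_export": (0.0, 1000.0),
        "product_export": (0.0, 1000.0),
        "co2_export": (0.0, 1000.0),
    }
    return StoichiometricModel(
        reactions=reactions,
        bounds=bounds,
        objective="product_export",
        substrate="uptake",
        biomass_reaction="biomass_export",
        molar_masses={"substrate": MW["glucose"], "product": MW[product],
                      "biomass": MW["biomass_c1"]},
    )


# ---------------------------------------------------------------------------
# Background database
# ---------------------------------------------------------------------------

_BG = {
    # per kg sugar
    "sugar, corn-stover-US": ("kg", {
        "carbon dioxide, fossil": 0.65, "dinitrogen monoxide": 0.0015,
        "land occupation": 0.6, "water consumption": 0.08,
        "phosphate": 0.0008, "nitrate": 0.006, "ammonia": 0.003,
        "toxicant to freshwater": 1.2e-4, "toxicant to soil": 8e-5,
        "oil equivalent": 0.15, "nmvoc": 8e-4, "nitrogen oxides": 0.0012}),
    "sugar, corn-starch-US": ("kg", {
        "carbon dioxide, fossil": 1.1, "methane, fossil": 0.001,
        "dinitrogen monoxide": 0.002, "land occupation": 1.8,
        "water consumption": 0.25, "phosphate": 0.0015, "nitrate": 0.01,
        "ammonia": 0.006, "toxicant to freshwater": 2e-4,
        "toxicant to soil": 1e-4, "pm2.5": 5e-4, "nitrogen oxides": 0.002,
        "oil equivalent": 0.25}),
    "sugar, sugar-beet-FR": ("kg", {
        "carbon dioxide, fossil": 1.0, "dinitrogen monoxide": 0.0018,
        "land occupation": 1.2, "water consumption": 0.12,
        "phosphate": 0.0012, "nitrate": 0.012, "ammonia": 0.005,
        "toxicant to freshwater": 1.5e-4, "oil equivalent": 0.2,
        "nitrogen oxides": 0.0015}),
    "sugar, sugarcane-BR": ("kg", {
        "carbon dioxide, fossil": 0.8, "methane, fossil": 0.0012,
        "dinitrogen monoxide": 0.0012, "land occupation": 2.6,
        "water consumption": 0.35, "phosphate": 0.001, "nitrate": 0.008,
        "ammonia": 0.004, "toxicant to freshwater": 2.5e-4,
        "toxicant to soil": 1.5e-4, "pm2.5": 0.0012,
        "nitrogen oxides": 0.0018, "oil equivalent": 0.12}),
    # per kg N supplied
    "nitrogen, ammonia": ("kg", {
        "carbon dioxide, fossil": 2.6, "methane, fossil": 0.004,
        "ammonia": 0.01, "oil equivalent": 0.8, "nitrogen oxides": 0.002}),
    "nitrogen, ammonium-sulfate": ("kg", {
        "carbon dioxide, fossil": 2.2, "ammonia": 0.02, "sulfur dioxide": 0.01,
        "oil equivalent": 0.6, "nitrogen oxides": 0.0015}),
    # per kg
    "sodium hydroxide": ("kg", {
        "carbon dioxide, fossil": 1.1, "radionuclides": 0.02,
        "metal ore": 0.001, "toxicant, carcinogenic": 1e-5,
        "oil equivalent": 0.3, "sulfur dioxide": 0.002}),
    "solvent, organic": ("kg", {
        "carbon dioxide, fossil": 1.8, "nmvoc": 0.01, "oil equivalent": 1.5,
        "cfc-11": 1e-8, "toxicant, non-carcinogenic": 5e-5}),
    "process water": ("kg", {
        "carbon dioxide, fossil": 3e-4, "water consumption": 0.0011}),
    # per MJ
    "steam, grid": ("MJ", {
        "carbon dioxide, fossil": 0.075, "methane, fossil": 2e-4,
        "nitrogen oxides": 8e-5, "oil equivalent": 0.024}),
    "steam, biomass": ("MJ", {
        "carbon dioxide, biogenic": 0.11, "carbon dioxide, fossil": 0.006,
        "pm2.5": 1e-4, "nitrogen oxides": 2e-4, "land occupation": 0.01}),
    "electricity, grid": ("MJ", {
        "carbon dioxide, fossil": 0.14, "methane, fossil": 3e-4,
        "sulfur dioxide": 3e-4, "radionuclides": 0.05, "oil equivalent": 0.03}),
    "electricity, biomass": ("MJ", {
        "carbon dioxide, biogenic": 0.25, "carbon dioxide, fossil": 0.012,
        "pm2.5": 2e-4, "nitrogen oxides": 3e-4, "land occupation": 0.02}),
    # per kg cake
    "municipal incineration": ("kg", {
        "carbon dioxide, biogenic": 0.8, "carbon dioxide, fossil": 0.08,
        "dinitrogen monoxide": 3e-4, "nitrogen oxides": 0.002,
        "toxicant to freshwater": 1e-4, "toxicant to marine": 5e-5,
        "toxicant, carcinogenic": 2e-5}),
    # per t*km
    "freight transport": ("tkm", {
        "carbon dioxide, fossil": 0.09, "nitrogen oxides": 6e-4,
        "pm2.5": 2e-5, "nmvoc": 3e-5, "oil equivalent": 0.03}),
    # amortized per kg product at the reference fermenter count
    "fermentation plant construction": ("kg", {
        "carbon dioxide, fossil": 0.05, "metal ore": 0.002,
        "toxicant to soil": 1e-5, "land occupation": 0.001}),
    # purchased monomers, per kg
    "hmda": ("kg", {
        "carbon dioxide, fossil": 4.5, "methane, fossil": 0.008,
        "oil equivalent": 1.9, "nitrogen oxides": 0.003,
        "toxicant, non-carcinogenic": 1e-4, "cfc-11": 5e-9}),
    "adipic acid": ("kg", {
        "carbon dioxide, fossil": 3.0, "dinitrogen monoxide": 0.0106,
        "oil equivalent": 1.6, "nitrogen oxides": 0.004, "ammonia": 0.001}),
    "sebacic acid": ("kg", {
        "carbon dioxide, fossil": 2.0, "land occupation": 1.5,
        "water consumption": 0.15, "phosphate": 8e-4, "nitrate": 0.004,
        "toxicant to freshwater": 2e-4}),
}


def background_table() -> pd.DataFrame:
    rows = []
    for activity, (unit, flows) in _BG.items():
        for flow, amount in flows.items():
            rows.append({
                "activity": activity,
                "unit": unit,
                "elementary_flow": flow,
                "compartment": "air" if flow in (
                    "carbon dioxide, fossil", "carbon dioxide, biogenic",
                    "methane, fossil", "dinitrogen monoxide", "nmvoc", "cfc-11",
                    "sulfur dioxide", "nitrogen oxides", "pm2.5", "ammonia",
                ) else "other",
                "biogenic_flag": flow == "carbon dioxide, biogenic",
                "amount_per_unit": amount,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Characterization factors
# ---------------------------------------------------------------------------

_CF = {
    "climate change": {"carbon dioxide, fossil": 1.0, "carbon dioxide, biogenic": 0.0,
                       "methane, fossil": 34.0, "dinitrogen monoxide": 298.0},
    "stratospheric ozone depletion": {"cfc-11": 1.0, "dinitrogen monoxide": 0.011},
    "ionizing radiation": {"radionuclides": 1.0},
    "ozone formation, human health": {"nitrogen oxides": 1.0, "nmvoc": 0.18},
    "fine particulate matter formation": {"pm2.5": 1.0, "sulfur dioxide": 0.29,
                                          "nitrogen oxides": 0.11, "ammonia": 0.24},
    "ozone formation, terrestrial ecosystems": {"nitrogen oxides": 1.0, "nmvoc": 0.29},
    "terrestrial acidification": {"sulfur dioxide": 1.0, "nitrogen oxides": 0.36,
                                  "ammonia": 1.96},
    "freshwater eutrophication": {"phosphate": 1.0},
    "marine eutrophication": {"nitrate": 0.297, "ammonia": 0.092},
    "terrestrial ecotoxicity": {"toxicant to soil": 1.0},
    "freshwater ecotoxicity": {"toxicant to freshwater": 1.0},
    "marine ecotoxicity": {"toxicant to marine": 1.0},
    "human carcinogenic toxicity": {"toxicant, carcinogenic": 1.0},
    "human non-carcinogenic toxicity": {"toxicant, non-carcinogenic": 1.0},
    "land use": {"land occupation": 1.0},
    "mineral resource scarcity": {"metal ore": 1.0},
    "fossil resource scarcity": {"oil equivalent": 1.0},
    "water consumption": {"water consumption": 1.0},
}

_CF_UNITS = {
    "climate change": "kg CO2 eq", "stratospheric ozone depletion": "kg CFC-11 eq",
    "ionizing radiation": "kBq Co-60 eq", "ozone formation, human health": "kg NOx eq",
    "fine particulate matter formation": "kg PM2.5 eq",
    "ozone formation, terrestrial ecosystems": "kg NOx eq",
    "terrestrial acidification": "kg SO2 eq", "freshwater eutrophication": "kg P eq",
    "marine eutrophication": "kg N eq", "terrestrial ecotoxicity": "kg 1,4-DCB eq",
    "freshwater ecotoxicity": "kg 1,4-DCB eq", "marine ecotoxicity": "kg 1,4-DCB eq",
    "human carcinogenic toxicity": "kg 1,4-DCB eq",
    "human non-carcinogenic toxicity": "kg 1,4-DCB eq", "land use": "m2a crop eq",
    "mineral resource scarcity": "kg Cu eq", "fossil resource scarcity": "kg oil eq",
    "water consumption": "m3",
}


def cf_table() -> pd.DataFrame:
    rows = []
    for category, flows in _CF.items():
        for flow, factor in flows.items():
            rows.append({"category": category, "elementary_flow": flow,
                         "factor": factor, "factor_units": _CF_UNITS[category]})
    assert set(_CF) == set(DEFAULT_CATEGORIES)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Social risk fixture
# ---------------------------------------------------------------------------

CATEGORIES_SOCIAL = ("Labour Rights & Decent Work", "Health & Safety", "Human Rights",
                     "Governance", "Community Infrastructure")

# (country, sector) -> {(category, theme): (risk_level, weight)}
# Health & safety is set as the dominant risk in every CSS, with labour
# rights / work conditions the recurrent secondary hotspot.
_SOCIAL = {
    ("US", "agriculture"): {
        ("Health & Safety", "risk of occupational injury"): ("high", 1.5),
        ("Health & Safety", "risk of exposure to toxics"): ("high", 1.0),
        ("Labour Rights & Decent Work", "risk of excessive working time"): ("high", 1.0),
        ("Labour Rights & Decent Work", "risk of child labour"): ("low", 1.5),
        ("Labour Rights & Decent Work", "risk of low wages"): ("medium", 1.0),
        ("Human Rights", "risk to indigenous rights"): ("medium", 1.0),
        ("Governance", "risk of corruption"): ("low", 1.5),
        ("Community Infrastructure", "risk to local access to water"): ("medium", 1.0),
    },
    ("US", "Chemical, rubber and plastic products"): {
        ("Health & Safety", "risk of occupational injury"): ("high", 1.5),
        ("Health & Safety", "risk of exposure to toxics"): ("very_high", 1.0),
        ("Labour Rights & Decent Work", "risk of excessive working time"): ("medium", 1.0),
        ("Labour Rights & Decent Work", "risk of child labour"): ("low", 1.5),
        ("Human Rights", "risk to indigenous rights"): ("low", 1.0),
        ("Governance", "risk of corruption"): ("low", 1.5),
        ("Community Infrastructure", "risk to local access to water"): ("low", 1.0),
    },
    ("FR", "agriculture"): {
        ("Health & Safety", "risk of occupational injury"): ("high", 1.5),
        ("Health & Safety", "risk of exposure to toxics"): ("medium", 1.0),
        ("Labour Rights & Decent Work", "risk of excessive working time"): ("medium", 1.0),
        ("Labour Rights & Decent Work", "risk of child labour"): ("low", 1.5),
        ("Labour Rights & Decent Work", "risk of low wages"): ("medium", 1.0),
        ("Human Rights", "risk to indigenous rights"): ("low", 1.0),
        ("Governance", "risk of corruption"): ("low", 1.5),
        ("Community Infrastructure", "risk to local access to water"): ("low", 1.0),
    },
    ("FR", "Chemical, rubber and plastic products"): {
        ("Health & Safety", "risk of occupational injury"): ("high", 1.5),
        ("Health & Safety", "risk of exposure to toxics"): ("high", 1.0),
        ("Labour Rights & Decent Work", "risk of excessive working time"): ("medium", 1.0),
        ("Labour Rights & Decent Work", "risk of child labour"): ("low", 1.5),
        ("Human Rights", "risk to indigenous rights"): ("low", 1.0),
        ("Governance", "risk of corruption"): ("low", 1.5),
        ("Community Infrastructure", "risk to local access to water"): ("low", 1.0),
    },
    ("BR", "agriculture"): {
        ("Health & Safety", "risk of occupational injury"): ("very_high", 1.5),
        ("Health & Safety", "risk of exposure to toxics"): ("very_high", 1.0),
        ("Labour Rights & Decent Work", "risk of forced labour"): ("high", 1.5),
        ("Labour Rights & Decent Work", "risk of excessive working time"): ("high", 1.0),
        ("Labour Rights & Decent Work", "risk of low wages"): ("high", 1.0),
        ("Human Rights", "risk to indigenous rights"): ("high", 1.0),
        ("Governance", "risk of corruption"): ("high", 1.5),
        ("Community Infrastructure", "risk to local access to water"): ("medium", 1.0),
    },
    ("BR", "Chemical, rubber and plastic products"): {
        ("Health & Safety", "risk of occupational injury"): ("very_high", 1.5),
        ("Health & Safety", "risk of exposure to toxics"): ("high", 1.0),
        ("Labour Rights & Decent Work", "risk of forced labour"): ("medium", 1.5),
        ("Labour Rights & Decent Work", "risk of excessive working time"): ("high", 1.0),
        ("Human Rights", "risk to indigenous rights"): ("medium", 1.0),
        ("Governance", "risk of corruption"): ("high", 1.5),
        ("Community Infrastructure", "risk to local access to water"): ("medium", 1.0),
    },
}


def social_table() -> pd.DataFrame:
    rows = []
    for (country, sector), themes in _SOCIAL.items():
        for (category, theme), (risk, weight) in themes.items():
            rows.append({"country": country, "sector": sector, "category": category,
                         "theme": theme, "risk_level": risk, "weight": weight})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """All input tables plus the run configuration and a manifest."""

    parameter_table: pd.DataFrame
    toy_network: StoichiometricModel
    background_db: BackgroundDatabase
    cf_table: CharacterizationTable
    social_table: pd.DataFrame
    config: dict
    manifest: dict = field(default_factory=dict)

    @property
    def distributions(self) -> dict[str, Distribution]:
        return distributions_from_table(self.parameter_table)

    @property
    def space(self) -> ScenarioSpace:
        axes = {}
        for axis, outcomes in self.config["scenario_axes"].items():
            axes[axis] = Distribution("discrete", outcomes=dict(outcomes))
        return ScenarioSpace(axes)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.parameter_table.to_csv(outdir / "parameters.csv", index=False)
        self.toy_network.to_frame().to_csv(outdir / "network.csv", index=False)
        self.background_db.table.to_csv(outdir / "background.csv", index=False)
        self.cf_table.table.to_csv(outdir / "characterization.csv", index=False)
        self.social_table.to_csv(outdir / "social.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, indir: str | Path) -> "FixtureBundle":
        indir = Path(indir)
        with open(indir / "config.yaml") as fh:
            config = yaml.safe_load(fh)
        with open(indir / "manifest.json") as fh:
            manifest = json.load(fh)
        network = StoichiometricModel.from_frame(
            pd.read_csv(indir / "network.csv"),
            molar_masses=manifest.get("network_molar_masses"),
        )
        return cls(
            parameter_table=pd.read_csv(indir / "parameters.csv",
                                        keep_default_na=False),
            toy_network=network,
            background_db=BackgroundDatabase(pd.read_csv(indir / "background.csv")),
            cf_table=CharacterizationTable(pd.read_csv(indir / "characterization.csv")),
            social_table=pd.read_csv(indir / "social.csv"),
            config=config,
            manifest=manifest,
        )


def generate_fixture_bundle(seed: int = 0, scale: str = "full",
                            monomer: str = "putrescine") -> FixtureBundle:
    """Complete, self-consistent input bundle (deterministic for any seed).

    ``scale="smoke"`` trims the configured Monte Carlo default to 500
    iterations for fast test runs; ``"full"`` keeps 10,000.
    """
    if scale not in ("smoke", "full"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    network = generate_toy_network(monomer)
    space = scenario_space()
    config = {
        "seed": int(seed),
        "n_iterations": 500 if scale == "smoke" else 10_000,
        "monomer": monomer,
        "annual_output_kt": 100.0,
        "operating_hours": 8000.0,
        "hotspot_threshold_pct": 5.0,
        "sensitivity_threshold_pct": 5.0,
        "interval_level": 95.0,
        "scenario_axes": {axis: dict(dist.outcomes)
                          for axis, dist in space.axes.items()},
    }
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "seed": int(seed),
        "scale": scale,
        "network_molar_masses": dict(network.molar_masses),
        # hand LP on the fixed network: all substrate to product
        "network_max_product_yield_gg": MW[monomer] / MW["glucose"],
        "network_max_biomass_yield_gg": 5.0 * MW["biomass_c1"] / MW["glucose"],
    }
    return FixtureBundle(
        parameter_table=parameter_table(),
        toy_network=network,
        background_db=BackgroundDatabase(background_table()),
        cf_table=CharacterizationTable(cf_table()),
        social_table=social_table(),
        config=config,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Known-answer case
# ---------------------------------------------------------------------------


def _point_override(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse every distribution to a point at its central value."""
    dists = distributions_from_table(table)
    out = table.copy()
    for i, row in out.iterrows():
        mode = dists[row["name"]].mode() if dists[row["name"]].kind != "discrete" else None
        if mode is not None:
            out.loc[i, ["kind", "p1", "p2", "p3"]] = ["point", mode, "", ""]
    return out


def generate_known_answer_case() -> tuple[FixtureBundle, dict]:
    """Degenerate bundle (all point distributions, one scenario) + expected outputs.

    The expected minimum selling price, all 18 impact scores and the SHI
    values are recomputed here by direct closed-form arithmetic on the
    tables — plain mass balances, a matrix dot product and the break-even
    annuity identity — independent of the Monte Carlo engine, the flowsheet
    classes and the root-finding path they exercise.
    """
    bundle = generate_fixture_bundle(seed=0, scale="smoke")
    bundle.parameter_table = _point_override(bundle.parameter_table)
    scenario = {"feedstock": "corn-starch-US", "waste_handling": "non-integrated",
                "energy_source": "grid", "nitrogen_source": "ammonia"}
    bundle.config["scenario_axes"] = {k: {v: 1.0} for k, v in scenario.items()}
    bundle.config["n_iterations"] = 3
    v = {name: d.mode() for name, d in bundle.distributions.items()}

    # --- independent recomputation (straight-line arithmetic) ---------------
    from .bioprocess import MW as _MW, N_FRACTION  # local to keep module import light

    q, vol = v["sugar_uptake_rate"], v["working_volume"]
    t_sw, t_b = v["switch_time"], v["batch_time"]
    sugar = q * vol * t_b / 1000.0
    biomass = q * vol * t_sw / 1000.0 * v["biomass_yield_growth"]
    product = q * vol * (t_b - t_sw) / 1000.0 * v["product_yield"]
    nitrogen = biomass * N_FRACTION["biomass"] + product * N_FRACTION["putrescine"]
    per = 1.0 / product
    sugar_kg, bio_kg, n_kg = sugar * per, biomass * per, nitrogen * per
    water = v["water_per_kg"]
    naoh = v["naoh_per_kg"]
    makeup = v["solvent_per_kg"] * v["solvent_loss_frac"]
    cake_w0 = bio_kg * v["cake_water_initial"] / (1 - v["cake_water_initial"])
    evap = cake_w0 - bio_kg * 0.6 / 0.4
    cake = bio_kg + bio_kg * 0.6 / 0.4
    broth_mass = sugar_kg + n_kg + water
    dist_heat = (v["dist_sensible_heat"] * v["dist_delta_t"] + v["dist_dhvap"]) \
        / v["dist_efficiency"] / 1000.0
    steam = (v["steam_ferm_per_kg"] * broth_mass + v["evap_steam_per_kg_water"] * evap
             + dist_heat)
    liquor_w = water - cake_w0
    elec = (v["elec_ferm_per_kg"] * broth_mass
            + v["elec_centrifuge_per_kg"] * (1.0 + bio_kg + water)
            + v["elec_extraction_per_kg"] * (1.0 + liquor_w + v["solvent_per_kg"]))
    offgas = sugar_kg + n_kg - 1.0 - bio_kg

    bg, cft = bundle.background_db, bundle.cf_table
    amounts = {
        "sugar, corn-starch-US": sugar_kg,
        "nitrogen, ammonia": n_kg,
        "sodium hydroxide": naoh,
        "solvent, organic": makeup,
        "process water": water,
        "steam, grid": steam,
        "electricity, grid": elec,
        "municipal incineration": cake,
    }
    inventory = bg.zero()
    for act, amt in amounts.items():
        inventory = inventory + amt * bg.vector(act)
    idx = {f: i for i, f in enumerate(bg.flows)}
    inventory[idx["carbon dioxide, biogenic"]] += offgas
    inventory[idx["nmvoc"]] += makeup

    # construction: fermenter count relative to the reference design
    cycle = t_b + v["turnaround_time"]
    batches = bundle.config["operating_hours"] / cycle
    import math as _math
    n_ferm = _math.ceil(bundle.config["annual_output_kt"] * 1e6 / (product * batches) - 1e-9)
    inventory = inventory + 1.0 * bg.vector("fermentation plant construction")

    scores = cft.matrix(bg.flows) @ inventory
    expected_impacts = dict(zip(cft.categories, scores.tolist()))
    fossil_ghg = sum(
        inventory[idx[f]] * cft.factor("climate change", f)
        for f in bg.flows if not bg.biogenic.get(f, False))
    credit = 4 * _MW["co2"] / _MW["putrescine"]
    expected_climate = fossil_ghg - credit

    # MSP by the break-even identity: p = varopex + fixed/Q + PV_cap/(Q*D)
    varopex = (sugar_kg * v["sugar_price"] + n_kg * v["nitrogen_price"]
               + naoh * v["naoh_price"] + makeup * v["solvent_price"]
               + water * v["water_price"] + steam * v["steam_price"]
               + elec * v["electricity_price"] + cake * v["waste_disposal_price"])
    capital = (v["capital_base"]
               * (bundle.config["annual_output_kt"] / v["base_capacity_kt"])
               ** v["scaling_exponent"]
               * (v["cepci_target"] / v["cepci_base"]))
    r = v["discount_rate"]
    q_out = bundle.config["annual_output_kt"] * 1e6
    fixed = v["fixed_opex_frac"] * capital
    profile = (0.5, 0.5)
    pv_cap = sum(f * (1 + r) ** -j for j, f in enumerate(profile)) * capital
    disc = sum((1 + r) ** -(len(profile) + t) for t in range(int(v["lifespan"])))
    expected_msp = varopex + fixed / q_out + pv_cap / (q_out * disc)

    # SHI, US biorefinery proxy sector, direct weighted ratio
    themes = _SOCIAL[("US", "Chemical, rubber and plastic products")]
    rmap = {"low": 1.0, "medium": 2.0, "high": 3.0, "very_high": 4.0}
    hs = [(rmap[r_], w) for (cat, _), (r_, w) in themes.items()
          if cat == "Health & Safety"]
    expected_shi_hs = 100.0 * sum(r_ * w for r_, w in hs) / sum(4.0 * w for _, w in hs)

    expected = {
        "msp": expected_msp,
        "climate_change_score": expected_climate,
        "impacts": expected_impacts,
        "shi_health_safety_US_biorefinery": expected_shi_hs,
        "n_fermenters": n_ferm,
        "scenario": scenario,
    }
    bundle.manifest["known_answer"] = expected
    return bundle, expected
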