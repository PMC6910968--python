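"""Cradle-to-gate life-cycle impact assessment.

Background data are consumed as pre-aggregated life-cycle inventories: each
activity is a flat vector of elementary flows per unit (kg or MJ), the way
system-model results from commercial databases are typically used at desk
scale.  Characterization multiplies the assembled inventory by a factor
table over the 18 midpoint impact categories of a hierarchist-style method.

Climate change follows the biogenic-carbon convention for bio-based
products: biogenic CO2 emissions are excluded and the carbon embodied in
the product earns a credit of n_C * 44.009 / M kg CO2 per kg product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bioprocess import CARBON_COUNT, MW, ProcessFlowSheet
from .uncertainty import Distribution, ParameterDraw

logger = logging.getLogger(__name__)

#: the 18 midpoint categories of the default characterization table
DEFAULT_CATEGORIES = (
    "climate change",
    "stratospheric ozone depletion",
    "ionizing radiation",
    "ozone formation, human health",
    "fine particulate matter formation",
    "ozone formation, terrestrial ecosystems",
    "terrestrial acidification",
    "freshwater eutrophication",
    "marine eutrophication",
    "terrestrial ecotoxicity",
    "freshwater ecotoxicity",
    "marine ecotoxicity",
    "human carcinogenic toxicity",
    "human non-carcinogenic toxicity",
    "land use",
    "mineral resource scarcity",
    "fossil resource scarcity",
    "water consumption",
)

#: greenhouse-gas flows whose fossil share enters the climate score
GHG_FLOWS = ("carbon dioxide, fossil", "methane, fossil", "dinitrogen monoxide")

MOLAR_MASS = {  # g/mol, condensation chemistry
    "putrescine": 88.15,
    "cadaverine": 102.18,
    "adipic acid": 146.14,
    "sebacic acid": 202.25,
    "hmda": 116.21,
    "water": 18.02,
}

CARBON_ATOMS = {"putrescine": 4, "cadaverine": 5}


class MappingError(KeyError):
    pass


class BackgroundDatabase:
    """Activity -> per-unit elementary-flow vectors, with biogenic tagging."""

    def __init__(self, table: pd.DataFrame):
        required = {"activity", "unit", "elementary_flow", "biogenic_flag", "amount_per_unit"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"background table missing columns {sorted(missing)}")
        self.table = table.copy()
        self.flows = sorted(table["elementary_flow"].unique())
        self._flow_index = {f: i for i, f in enumerate(self.flows)}
        self.biogenic = {
            row.elementary_flow: bool(row.biogenic_flag)
            for row in table.itertuples()
        }
        self._vectors: dict[str, np.ndarray] = {}
        for activity, group in table.groupby("activity"):
            vec = np.zeros(len(self.flows))
            for row in group.itertuples():
                vec[self._flow_index[row.elementary_flow]] += row.amount_per_unit
            self._vectors[activity] = vec
        self.units = dict(zip(table["activity"], table["unit"]))

    @property
    def activities(self) -> list[str]:
        return sorted(self._vectors)

    def __contains__(self, activity: str) -> bool:
        return activity in self._vectors

    def vector(self, activity: str) -> np.ndarray:
        try:
            return self._vectors[activity]
        except KeyError:
            raise MappingError(f"no background activity named {activity!r}") from None

    def zero(self) -> np.ndarray:
        return np.zeros(len(self.flows))

    def series(self, vec: np.ndarray) -> pd.Series:
        return pd.Series(vec, index=self.flows)


class CharacterizationTable:
    """Category x elementary-flow characterization factors."""

    def __init__(self, table: pd.DataFrame, categories: Sequence[str] | None = None):
        required = {"category", "elementary_flow", "factor"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"characterization table missing columns {sorted(missing)}")
        self.table = table.copy()
        self.categories = tuple(categories or DEFAULT_CATEGORIES)
        unknown = set(table["category"]) - set(self.categories)
        if unknown:
            raise ValueError(f"factors given for undeclared categories {sorted(unknown)}")
        self._factors: dict[tuple[str, str], float] = {
            (row.category, row.elementary_flow): float(row.factor)
            for row in table.itertuples()
        }
        self._warned: set[str] = set()
        self._matrix_cache: dict[tuple[str, ...], np.ndarray] = {}

    def factor(self, category: str, flow: str) -> float:
        return self._factors.get((category, flow), 0.0)

    def matrix(self, flows: Sequence[str]) -> np.ndarray:
        """(categories x flows) factor matrix; missing pairs are 0, logged once."""
        key = tuple(flows)
        if key in self._matrix_cache:
            return self._matrix_cache[key]
        known_flows = {f for _, f in self._factors}
        for f in flows:
            if f not in known_flows and f not in self._warned:
                logger.warning("no characterization factor for flow %r; treated as 0", f)
                self._warned.add(f)
        M = np.zeros((len(self.categories), len(flows)))
        for i, cat in enumerate(self.categories):
            for j, f in enumerate(flows):
                M[i, j] = self._factors.get((cat, f), 0.0)
        self._matrix_cache[key] = M
        return M


@dataclass
class ImpactVector:
    """Characterized scores across the impact categories for one functional unit."""

    scores: pd.Series  # index = categories
    functional_unit: str = "1 kg monomer"
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, category: str) -> float:
        return float(self.scores[category])

    def __add__(self, other: "ImpactVector") -> "ImpactVector":
        return ImpactVector(self.scores + other.scores, self.functional_unit)


# ---------------------------------------------------------------------------
# Inventory assembly
# ---------------------------------------------------------------------------


def activity_mapping(scenario: Mapping[str, str]) -> dict[str, str]:
    """Map foreground flow names to background activities for one scenario."""
    for axis in ("feedstock", "energy_source", "nitrogen_source"):
        if axis not in scenario:
            raise MappingError(f"scenario axis {axis!r} unresolved")
    return {
        "sugar": f"sugar, {scenario['feedstock']}",
        "nitrogen-source": f"nitrogen, {scenario['nitrogen_source']}",
        "naoh": "sodium hydroxide",
        "solvent": "solvent, organic",
        "process-water": "process water",
        "steam": f"steam, {scenario['energy_source']}",
        "electricity": f"electricity, {scenario['energy_source']}",
        "waste-cake-to-incineration": "municipal incineration",
    }


def assemble_inventory(
    flowsheet: ProcessFlowSheet,
    background: BackgroundDatabase,
    draw: ParameterDraw,
    construction_activity: str = "fermentation plant construction",
    reference_fermenters: int = 1,
) -> np.ndarray:
    """Elementary-flow vector per 1 kg monomer, cradle to gate.

    Sum of (foreground amount x background activity vector) over purchased
    inputs, net external steam and electricity, the waste branch, and the
    plant-construction activity scaled by the fermenter count, plus direct
    foreground emissions.  Linear in the foreground flows.
    """
    mapping = activity_mapping(draw.scenario)
    inv = background.zero()
    for flow, amount in flowsheet.external_inputs().items():
        activity = mapping.get(flow)
        if activity is None:
            raise MappingError(
                f"foreground flow {flow!r} has no background mapping "
                f"for scenario {dict(draw.scenario)}"
            )
        inv += amount * background.vector(activity)
    inv += flowsheet.net_steam_mj * background.vector(mapping["steam"])
    inv += flowsheet.electricity_mj * background.vector(mapping["electricity"])
    # waste branch: incineration is an external service; on-site combustion of
    # the (biogenic) cake emits biogenic CO2 directly
    waste_stage = flowsheet.stage("waste handling")
    if "waste-cake-to-incineration" in waste_stage.outputs:
        inv += (waste_stage.outputs["waste-cake-to-incineration"]
                * background.vector(mapping["waste-cake-to-incineration"]))
    for flow, amount in flowsheet.emissions().items():
        name = flow.removeprefix("emission/")
        if name == "co2-biogenic":
            name = "carbon dioxide, biogenic"
        elif name == "solvent-loss":
            name = "nmvoc"
        elif name == "water-vapour":
            continue  # evaporated water is not an impact-bearing flow
        if name in background._flow_index:
            inv[background._flow_index[name]] += amount
    # plant construction, amortized per kg and scaled by fermenter count
    if construction_activity in background:
        per_kg = flowsheet.n_fermenters / max(reference_fermenters, 1)
        inv += per_kg * background.vector(construction_activity)
    return inv


def characterize(
    inventory: np.ndarray | pd.Series,
    table: CharacterizationTable,
    flows: Sequence[str] | None = None,
    functional_unit: str = "1 kg monomer",
) -> ImpactVector:
    """score_c = sum_f factor(c, f) * inventory(f) over all categories."""
    if isinstance(inventory, pd.Series):
        flows = list(inventory.index)
        vec = inventory.to_numpy(dtype=float)
    else:
        if flows is None:
            raise ValueError("flows must be given with a bare array inventory")
        vec = np.asarray(inventory, dtype=float)
    scores = table.matrix(list(flows)) @ vec
    return ImpactVector(pd.Series(scores, index=list(table.categories)),
                        functional_unit=functional_unit)


def embodied_carbon_credit(product: str) -> float:
    """kg CO2 credited per kg product for carbon fixed in the molecule."""
    n_c = CARBON_ATOMS.get(product, 0)
    if n_c == 0:
        return 0.0
    return n_c * 44.009 / MOLAR_MASS[product]


def climate_change_score(
    inventory: np.ndarray | pd.Series,
    product: str,
    table: CharacterizationTable,
    background: BackgroundDatabase | None = None,
    flows: Sequence[str] | None = None,
) -> float:
    """Climate score excluding biogenic CO2 with an embodied-carbon credit.

    Flows are classified by the background database's biogenic flag; an
    untagged CO2 flow counts as fossil (with a warning).  The credit is
    n_C * 44.009 / M for the product molecule.
    """
    if isinstance(inventory, pd.Series):
        series = inventory
    else:
        series = pd.Series(np.asarray(inventory, dtype=float), index=list(flows))
    score = 0.0
    for flow, amount in series.items():
        if background is not None:
            biogenic = background.biogenic.get(flow)
            if biogenic is None and "carbon dioxide" in flow:
                logger.warning("CO2 flow %r untagged; treated as fossil", flow)
                biogenic = False
        else:
            biogenic = "biogenic" in flow
        if biogenic:
            continue
        score += amount * table.factor("climate change", flow)
    return score - embodied_carbon_credit(product)


def adipic_acid_cc_variant(
    rng: np.random.Generator,
    value_80_abatement: float,
    value_98_abatement: float,
) -> float:
    """Per-iteration equiprobable pick between the two N2O-abatement variants."""
    if value_80_abatement is None or value_98_abatement is None:
        raise ValueError("both abatement variants must be configured")
    return value_80_abatement if rng.random() < 0.5 else value_98_abatement


# ---------------------------------------------------------------------------
# Nylon combination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NylonRecipe:
    """Monomer masses and utilities to make 1 kg polymer by polycondensation."""

    name: str
    diamine: str
    diacid: str
    diamine_kg: float
    diacid_kg: float
    polymerization_steam_mj: float
    polymerization_electricity_mj: float
    transport: Distribution


def nylon_recipe(
    name: str,
    diamine: str,
    diacid: str,
    polymerization_steam_mj: float = 0.0,
    polymerization_electricity_mj: float = 0.0,
    transport: Distribution | None = None,
    water_per_bond: float = MOLAR_MASS["water"],
) -> NylonRecipe:
    """Condensation stoichiometry: each repeat unit releases two waters.

    Monomer input per kg polymer is M_monomer / (M_diamine + M_diacid - 2 M_H2O),
    so the two inputs together exceed 1 kg by exactly the condensate mass.
    """
    m_a = MOLAR_MASS[diamine]
    m_b = MOLAR_MASS[diacid]
    repeat = m_a + m_b - 2.0 * water_per_bond
    if repeat <= 0:
        raise ValueError("repeat unit mass must be positive")
    return NylonRecipe(
        name=name,
        diamine=diamine,
        diacid=diacid,
        diamine_kg=m_a / repeat,
        diacid_kg=m_b / repeat,
        polymerization_steam_mj=polymerization_steam_mj,
        polymerization_electricity_mj=polymerization_electricity_mj,
        transport=transport or Distribution("uniform", (100.0, 400.0), units="km"),
    )


def standard_recipes(polymerization_steam_mj: float = 6.0,
                     polymerization_electricity_mj: float = 2.0) -> dict[str, NylonRecipe]:
    """The four nylons compared on a like-for-like mass basis."""
    kw = dict(polymerization_steam_mj=polymerization_steam_mj,
              polymerization_electricity_mj=polymerization_electricity_mj)
    return {
        "nylon66": nylon_recipe("nylon66", "hmda", "adipic acid", **kw),
        "nylon46": nylon_recipe("nylon46", "putrescine", "adipic acid", **kw),
        "nylon410": nylon_recipe("nylon410", "putrescine", "sebacic acid", **kw),
        "nylon510": nylon_recipe("nylon510", "cadaverine", "sebacic acid", **kw),
    }


def nylon_climate_sample(
    recipe: NylonRecipe,
    monomer_climate: Mapping[str, float],
    background_climate: Mapping[str, float],
    steam_climate: float,
    electricity_climate: float,
    transport_km: float,
    transport_climate_per_tkm: float,
) -> float:
    """Per-iteration climate score of 1 kg nylon from its parts.

    ``monomer_climate`` carries per-kg scores for bio-based monomers computed
    in this iteration; ``background_climate`` per-kg scores for purchased
    (fossil/castor) monomers.  Transport moves both monomers to the
    polymerization site.
    """
    def monomer_score(m: str) -> float:
        if m in monomer_climate:
            return monomer_climate[m]
        if m in background_climate:
            return background_climate[m]
        raise MappingError(f"no climate score available for monomer {m!r}")

    mass = recipe.diamine_kg + recipe.diacid_kg
    return (
        recipe.diamine_kg * monomer_score(recipe.diamine)
        + recipe.diacid_kg * monomer_score(recipe.diacid)
        + recipe.polymerization_steam_mj * steam_climate
        + recipe.polymerization_electricity_mj * electricity_climate
        + mass / 1000.0 * transport_km * transport_climate_per_tkm
    )


def exceedance_fraction(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Share of paired iterations where candidate exceeds reference."""
    candidate = np.asarray(candidate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if candidate.shape != reference.shape:
        raise ValueError("samples must be paired iteration for iteration")
    ok = np.isfinite(candidate) & np.isfinite(reference)
    if not ok.any():
        return float("nan")
    return float(np.mean(candidate[ok] > reference[ok]))


def compare_nylons(
    nylon_samples: Mapping[str, np.ndarray],
    reference: str = "nylon66",
) -> pd.DataFrame:
    """Pairwise summary of per-kg-nylon samples against the fossil benchmark.

    Returns mean score, 95% percentile interval, exceedance fraction vs the
    reference and the mean relative difference (%) for each nylon.
    """
    ref = np.asarray(nylon_samples[reference], dtype=float)
    rows = []
    for name, samples in nylon_samples.items():
        s = np.asarray(samples, dtype=float)
        if s.shape != ref.shape:
            raise ValueError(f"iteration counts differ for {name!r} vs {reference!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = 100.0 * (s - ref) / np.abs(ref)
        rows.append({
            "nylon": name,
            "mean": float(np.nanmean(s)),
            "p2.5": float(np.nanpercentile(s, 2.5)),
            "p97.5": float(np.nanpercentile(s, 97.5)),
            "exceedance_vs_ref": exceedance_fraction(s, ref),
            "mean_rel_diff_pct": float(np.nanmean(rel)),
        })
    return pd.DataFrame(rows).set_index("nylon")


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


@dataclass
class HotspotBreakdown:
    """Per-category relative contributions with small stages grouped."""

    table: pd.DataFrame  # index = stage (incl. "others"), columns = categories


def hotspot_analysis(
    stage_contributions: pd.DataFrame,
    threshold_pct: float = 5.0,
) -> HotspotBreakdown:
    """Group stages below the threshold into "others", preserving 100% totals.

    ``stage_contributions`` holds signed absolute contributions (stage x
    category).  Contributions are normalized per category; stages whose
    absolute share is below the threshold in a category are merged into
    "others" for that category.
    """
    totals = stage_contributions.sum(axis=0)
    pct = 100.0 * stage_contributions.div(totals.replace(0.0, np.nan), axis=1)
    pct = pct.fillna(0.0)
    out = {}
    for cat in pct.columns:
        col = pct[cat]
        keep = col[np.abs(col) >= threshold_pct]
        others = col[np.abs(col) < threshold_pct].sum()
        entry = keep.to_dict()
        if others != 0.0 or len(keep) < len(col):
            entry["others"] = others
        out[cat] = entry
    table = pd.DataFrame(out).fillna(0.0)
    return HotspotBreakdown(table=table)
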