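"""Social hotspot index (SHI) aggregation for country-specific sectors.

Each country-specific sector (CSS) carries themed ordinal risk levels
grouped into five social categories.  The category score is the weighted
sum of theme risks normalized by the maximum possible weighted sum, scaled
to 100:

    SHI_cat = 100 * sum_T(R_avg,T * W_T) / sum_T(R_max * W_T)

with theme weights of 1.0 or 1.5 and themes lacking data removed from
numerator and denominator symmetrically.  The numeric mapping of ordinal
risk levels is configuration (default low=1 .. very_high=4); monotonicity
of the score in risk level holds for any increasing mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

RISK_LEVELS = ("low", "medium", "high", "very_high")
NO_DATA = "no_data"
DEFAULT_RISK_MAPPING = {"low": 1.0, "medium": 2.0, "high": 3.0, "very_high": 4.0}
ALLOWED_WEIGHTS = (1.0, 1.5)


class SocialDataError(ValueError):
    pass


@dataclass(frozen=True)
class SocialTheme:
    name: str  # e.g. "risk of child labour"
    category: str  # one of the five social categories
    risk_level: str  # ordinal level or no_data
    weight: float = 1.0  # W_T, 1.0 or 1.5

    def __post_init__(self) -> None:
        if self.risk_level not in RISK_LEVELS + (NO_DATA,):
            raise SocialDataError(f"unknown risk level {self.risk_level!r}")
        if self.weight not in ALLOWED_WEIGHTS:
            raise SocialDataError(f"theme weight must be 1.0 or 1.5, got {self.weight}")


@dataclass(frozen=True)
class CSSRecord:
    country: str
    sector: str
    themes: tuple[SocialTheme, ...]

    def __post_init__(self) -> None:
        if not self.country or not self.sector:
            raise SocialDataError("country and sector must be non-empty")
        if not self.themes:
            raise SocialDataError("a CSS record needs at least one theme")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, country: str, sector: str) -> "CSSRecord":
        sub = df[(df["country"] == country) & (df["sector"] == sector)]
        themes = tuple(
            SocialTheme(row.theme, row.category, row.risk_level, float(row.weight))
            for row in sub.itertuples()
        )
        return cls(country, sector, themes)


@dataclass(frozen=True)
class SHIScore:
    category: str
    value: float  # in [0, 100]; NaN when every theme lacks data
    n_themes: int  # themes with data included in the score
    hotspot_themes: tuple[str, ...] = ()  # themes at high / very_high


def weighted_shi(risks: Sequence[float], weights: Sequence[float],
                 r_max: float) -> float:
    """The normalized weighted-sum ratio, scaled to 100.

    Invariant under rescaling all weights by a common positive constant;
    exposed separately so that property holds for arbitrary positive weights
    even though curated data restricts weights to {1.0, 1.5}.
    """
    if len(risks) != len(weights) or not risks:
        raise SocialDataError("risks and weights must be non-empty and aligned")
    num = sum(r * w for r, w in zip(risks, weights))
    den = sum(r_max * w for w in weights)
    return 100.0 * num / den


def shi_category(
    themes: Sequence[SocialTheme],
    risk_mapping: Mapping[str, float] = DEFAULT_RISK_MAPPING,
) -> SHIScore:
    """Score one category from its themes (weight-scale invariant ratio)."""
    if not themes:
        raise SocialDataError("need at least one theme")
    category = themes[0].category
    risks, weights, hotspots = [], [], []
    for t in themes:
        if t.category != category:
            raise SocialDataError("themes passed to shi_category must share a category")
        if t.risk_level == NO_DATA:
            continue
        risks.append(risk_mapping[t.risk_level])
        weights.append(t.weight)
        if t.risk_level in ("high", "very_high"):
            hotspots.append(t.name)
    if not risks:
        return SHIScore(category, math.nan, 0, ())
    value = weighted_shi(risks, weights, risk_mapping["very_high"])
    return SHIScore(category, value, len(risks), tuple(hotspots))


def aggregate_shi(
    record: CSSRecord,
    risk_mapping: Mapping[str, float] = DEFAULT_RISK_MAPPING,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category SHI table and the ranked hotspot list for one CSS.

    The hotspot list holds themes at high or very_high risk sorted by their
    weighted numeric risk, most severe first.
    """
    by_cat: dict[str, list[SocialTheme]] = {}
    for t in record.themes:
        by_cat.setdefault(t.category, []).append(t)
    rows = []
    for category, themes in by_cat.items():
        score = shi_category(themes, risk_mapping)
        rows.append({
            "country": record.country,
            "sector": record.sector,
            "category": category,
            "shi": score.value,
            "n_themes": score.n_themes,
        })
    table = pd.DataFrame(rows)

    hot_rows = [
        {
            "theme": t.name,
            "category": t.category,
            "risk_level": t.risk_level,
            "weighted_risk": risk_mapping[t.risk_level] * t.weight,
        }
        for t in record.themes
        if t.risk_level in ("high", "very_high")
    ]
    hotspots = pd.DataFrame(hot_rows, columns=["theme", "category", "risk_level",
                                               "weighted_risk"])
    if not hotspots.empty:
        hotspots = hotspots.sort_values("weighted_risk", ascending=False,
                                        kind="stable").reset_index(drop=True)
    return table, hotspots
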