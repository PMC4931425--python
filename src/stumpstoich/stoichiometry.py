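"""Element-ratio algebra, the trophic stoichiometric ratio, and mitigation α.

The Trophic Stoichiometric Ratio compares food and consumer stoichiometry for
an element x:

    TSR_x = (C:x)_food / (C:x)_consumer.

TSR ≫ 1 means the food is relatively depleted in x compared with the
consumer's body; TSR ≥ 10 (the conservative default) marks a stoichiometric
mismatch constraining development.  Because the same C:x ratio appears above
and below, TSR is invariant to the units in which x is expressed, provided
food and consumer use the *same* unit — which this module enforces.

The mitigation index α = mean(TSR on low-fungus food) / mean(TSR on
high-fungus food), averaged over all species × sex pairs, quantifies how much
fungal colonization of the wood relaxes each element's mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (ELEMENTS, BeetleComposition, ElementProfile, round_half_up)
from .errors import (AlignmentError, ElementDivisionError, EmptyInputError,
                     UnitMismatchError)

#: Elements for which the mismatch analysis is run: everything except C
#: (the reference element) and S (no ergosterol relationship in the system).
DEFAULT_TSR_ELEMENTS: tuple[str, ...] = tuple(
    e for e in ELEMENTS if e not in ("C", "S"))

DEFAULT_MISMATCH_THRESHOLD = 10.0


def element_ratio(profile: ElementProfile, numerator: str,
                  denominator: str) -> float:
    """Plain concentration quotient numerator:denominator (no unit conversion)."""
    for sym in (numerator, denominator):
        if sym not in profile:
            raise ElementDivisionError(f"element {sym} absent from profile")
    den = profile[denominator]
    if den <= 0:
        raise ElementDivisionError(
            f"{numerator}:{denominator}: denominator {denominator} is {den!r}")
    return profile[numerator] / den


def tsr(food: ElementProfile, consumer: ElementProfile, element: str) -> float:
    """Trophic stoichiometric ratio (C:x)_food / (C:x)_consumer for one element."""
    for name, prof in (("food", food), ("consumer", consumer)):
        for sym in ("C", element):
            if sym not in prof:
                raise ElementDivisionError(
                    f"tsr({element}): {sym} absent from the {name} profile")
    if food.unit(element) != consumer.unit(element):
        raise UnitMismatchError(
            f"tsr({element}): food unit {food.unit(element)!r} != consumer "
            f"unit {consumer.unit(element)!r}")
    if food.unit("C") != consumer.unit("C"):
        raise UnitMismatchError("tsr: C expressed in different units")
    food_ratio = element_ratio(food, "C", element)
    consumer_ratio = element_ratio(consumer, "C", element)
    if consumer_ratio <= 0:
        raise ElementDivisionError(
            f"tsr({element}): consumer C:{element} ratio is {consumer_ratio!r}")
    return food_ratio / consumer_ratio


@dataclass(frozen=True)
class TSRTable:
    """TSR values by (species, sex, element) for one food profile."""

    entries: dict[tuple[str, str, str], float]
    food_label: str = ""

    def __post_init__(self):
        for key, value in self.entries.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"TSR entry {key} not finite positive: {value!r}")

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[2] for k in self.entries))

    def values_for(self, element: str) -> list[float]:
        return [v for (sp, sx, el), v in self.entries.items() if el == element]

    def to_frame(self):
        """Wide layout: one row per species × sex, one column per element."""
        import pandas as pd

        pairs = list(dict.fromkeys((sp, sx) for sp, sx, _ in self.entries))
        rows = []
        for sp, sx in pairs:
            row: dict[str, object] = {"species": sp, "sex": sx}
            for el in self.elements:
                row[el] = self.entries.get((sp, sx, el))
            rows.append(row)
        return pd.DataFrame(rows)


def tsr_table(food: ElementProfile,
              consumers: Sequence[BeetleComposition],
              elements: Iterable[str] = DEFAULT_TSR_ELEMENTS,
              food_label: str = "") -> TSRTable:
    """TSR for every consumer (species × sex) and element against one food."""
    consumers = list(consumers)
    if not consumers:
        raise EmptyInputError("tsr_table: no consumers")
    entries = {}
    for beetle in consumers:
        for element in elements:
            try:
                entries[(beetle.species, beetle.sex, element)] = tsr(
                    food, beetle.profile, element)
            except (ElementDivisionError, UnitMismatchError) as err:
                raise type(err)(
                    f"({beetle.species}, {beetle.sex}, {element}): {err}"
                ) from None
    return TSRTable(entries, food_label)


def classify_mismatch(tsr_value: float,
                      threshold: float = DEFAULT_MISMATCH_THRESHOLD) -> bool:
    """True iff the TSR marks a stoichiometric mismatch (boundary inclusive)."""
    return tsr_value >= threshold


@dataclass(frozen=True)
class MitigationResult:
    """Mitigation index α per element (low-fungus mean TSR / high-fungus mean)."""

    alpha_by_element: dict[str, float]

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        return {el: round_half_up(v, decimals)
                for el, v in self.alpha_by_element.items()}


def alpha(tsr_low: TSRTable, tsr_high: TSRTable) -> MitigationResult:
    """Mismatch mitigation α per element.

    α = mean of the low-table TSR entries over all (species, sex) pairs
    divided by the corresponding high-table mean.  Both tables must cover the
    same (species, sex, element) keys.
    """
    low_keys, high_keys = set(tsr_low.entries), set(tsr_high.entries)
    if low_keys != high_keys:
        missing_high = sorted(low_keys - high_keys)
        missing_low = sorted(high_keys - low_keys)
        raise AlignmentError(
            f"alpha: tables do not align; missing from high table: "
            f"{missing_high}; missing from low table: {missing_low}")
    result = {}
    for element in tsr_low.elements:
        low_vals = tsr_low.values_for(element)
        high_vals = tsr_high.values_for(element)
        result[element] = (sum(low_vals) / len(low_vals)) / \
                          (sum(high_vals) / len(high_vals))
    return MitigationResult(result)


def tsr_tables_from_frame(frame) -> tuple[TSRTable, TSRTable]:
    """Build (low, high) TSR tables from the bundled printed-table layout.

    Expects columns species, sex, group (low/high) and one column per element.
    """
    elements = [c for c in frame.columns
                if c not in ("species", "sex", "group")]
    tables = {}
    for group in ("low", "high"):
        sub = frame[frame["group"] == group]
        entries = {}
        for _, row in sub.iterrows():
            for el in elements:
                entries[(str(row["species"]), str(row["sex"]), el)] = \
                    float(row[el])
        tables[group] = TSRTable(entries, food_label=f"{group}-ergosterol stumps")
    return tables["low"], tables["high"]
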