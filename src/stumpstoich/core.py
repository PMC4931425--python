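"""Shared domain types for the stump-stoichiometry analyses.

The study system is a chronosequence of Scots pine (*Pinus sylvestris*) stumps
in early decay (roughly five months to five years after cutting), colonized by
fungi and inhabited by larvae of three xylophagous beetles.  Every stage of the
pipeline works with the same 12 essential elements; C, N and S are measured in
% of dry mass, the remaining nine in ppm of dry mass.  Ergosterol (µg/g d.m.),
a fungal membrane sterol, serves as the proxy for living fungal biomass and is
treated as a 13th pseudo-element where amount bookkeeping requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .errors import EmptyInputError, UnitMismatchError

#: The 12 elements tracked throughout, in canonical reporting order.
ELEMENTS: tuple[str, ...] = ("C", "N", "S", "P", "K", "Na", "Ca", "Mg",
                             "Fe", "Zn", "Mn", "Cu")

#: Pseudo-element symbol for ergosterol (µg/g d.m.).
ERGOSTEROL = "erg"

PERCENT_DM = "percent_dm"
PPM_DM = "ppm_dm"
UG_G_DM = "ug_g_dm"

#: Fixed unit convention: C, N, S as % d.m.; other elements as ppm d.m.
DEFAULT_UNITS: dict[str, str] = {
    **{e: PERCENT_DM for e in ("C", "N", "S")},
    **{e: PPM_DM for e in ELEMENTS if e not in ("C", "N", "S")},
    ERGOSTEROL: UG_G_DM,
}

_ALLOWED_SYMBOLS = frozenset(ELEMENTS) | {ERGOSTEROL}

#: Beetle species whose body compositions the mismatch analysis uses.
SPECIES: tuple[str, ...] = ("S_rubra", "A_rusticus", "C_mariana")
SEXES: tuple[str, ...] = ("female", "male")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero, matching how the source tables are printed.

    Python's builtin ``round`` is banker's rounding; printed ecological tables
    almost universally use half-away-from-zero, and the golden-table tests
    depend on the distinction (e.g. 3.35 → 3.4).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ElementProfile:
    """A concentration-by-element record with per-element units.

    Parameters
    ----------
    concentrations
        Map from element symbol to non-negative concentration.  Symbols must
        come from the fixed 12-element set (plus ``"erg"`` for ergosterol).
    units
        Map from element symbol to unit label.  Defaults to the package-wide
        convention (C, N, S in % d.m.; others ppm d.m.; erg µg/g d.m.).
    """

    concentrations: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.concentrations) - _ALLOWED_SYMBOLS
        if unknown:
            raise ValueError(f"unknown element symbols: {sorted(unknown)}")
        for sym, value in self.concentrations.items():
            if not (value >= 0):
                raise ValueError(f"negative concentration for {sym}: {value!r}")
        units = dict(self.units)
        for sym in self.concentrations:
            units.setdefault(sym, DEFAULT_UNITS[sym])
        object.__setattr__(self, "units", units)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(self.concentrations, key=_element_order))

    def __getitem__(self, symbol: str) -> float:
        return self.concentrations[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.concentrations

    def unit(self, symbol: str) -> str:
        return self.units[symbol]

    def scaled(self, factor: float) -> "ElementProfile":
        """Return a copy with every concentration multiplied by ``factor``."""
        return ElementProfile(
            {s: v * factor for s, v in self.concentrations.items()},
            dict(self.units),
        )


def _element_order(symbol: str) -> int:
    try:
        return ELEMENTS.index(symbol)
    except ValueError:
        return len(ELEMENTS)  # ergosterol sorts last


@dataclass(frozen=True)
class StumpSample:
    """One stump: identifier, age since cutting, ergosterol level and profile."""

    stump_id: str
    age_years: float
    ergosterol_ug_g: float
    profile: ElementProfile

    def __post_init__(self):
        if not (0 <= self.age_years <= 10):
            raise ValueError(
                f"stump {self.stump_id}: age_years={self.age_years!r} outside "
                "the plausible chronosequence range [0, 10]")
        if not (self.ergosterol_ug_g >= 0):
            raise ValueError(
                f"stump {self.stump_id}: negative ergosterol "
                f"{self.ergosterol_ug_g!r}")


@dataclass(frozen=True)
class BeetleComposition:
    """Body elemental profile of one beetle species × sex (imagines)."""

    species: str
    sex: str
    profile: ElementProfile

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if "C" not in self.profile or self.profile["C"] <= 0:
            raise ValueError(
                f"{self.species} {self.sex}: C concentration must be > 0 "
                "(required as a stoichiometric-ratio denominator)")


def mean_profile(samples: Iterable[StumpSample]) -> ElementProfile:
    """Arithmetic mean concentration per element over a group of stumps.

    All samples must share the same element set; units are preserved.
    """
    samples = list(samples)
    if not samples:
        raise EmptyInputError("mean_profile: no samples")
    first = samples[0].profile
    elements = set(first.concentrations)
    for s in samples[1:]:
        if set(s.profile.concentrations) != elements:
            raise UnitMismatchError(
                f"stump {s.stump_id} does not share the element set of "
                f"stump {samples[0].stump_id}")
        for sym in elements:
            if s.profile.unit(sym) != first.unit(sym):
                raise UnitMismatchError(
                    f"unit mismatch for {sym} between stumps "
                    f"{samples[0].stump_id} and {s.stump_id}")
    n = len(samples)
    means = {
        sym: sum(s.profile[sym] for s in samples) / n for sym in elements
    }
    return ElementProfile(means, dict(first.units))


def validate_consistent_units(profiles: Iterable[ElementProfile]) -> None:
    """Reject mixed units for the same element across a set of profiles.

    Ratio-based indices (TSR in particular) only cancel units when the same
    element is expressed identically in food and consumer tables.
    """
    seen: dict[str, str] = {}
    for i, profile in enumerate(profiles):
        for sym in profile.concentrations:
            unit = profile.unit(sym)
            if sym in seen and seen[sym] != unit:
                raise UnitMismatchError(
                    f"element {sym}: unit {unit!r} in profile {i} conflicts "
                    f"with {seen[sym]!r} seen earlier")
            seen.setdefault(sym, unit)


def profile_with_ergosterol(profile: ElementProfile,
                            ergosterol_ug_g: float) -> ElementProfile:
    """Attach ergosterol as a pseudo-element to an element profile."""
    conc = dict(profile.concentrations)
    conc[ERGOSTEROL] = ergosterol_ug_g
    return ElementProfile(conc, dict(profile.units))


def group_profile(samples: Iterable[StumpSample],
                  include_ergosterol: bool = True) -> ElementProfile:
    """Mean element profile of a stump group, optionally with mean ergosterol."""
    samples = list(samples)
    prof = mean_profile(samples)
    if include_ergosterol:
        erg = sum(s.ergosterol_ug_g for s in samples) / len(samples)
        prof = profile_with_ergosterol(prof, erg)
    return prof
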