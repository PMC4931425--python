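"""Enrichment coefficients under the exponential wood-decay model.

A decaying stump loses bulk mass (respiration, fragmentation) while fungal
transport can raise element *concentrations*.  Whether an element's absolute
amount grew is decided by the coefficient of difference

    β = (X_F / X_I) · (M_F / M_I),

the product of the final/initial concentration ratio and the remaining-mass
fraction, with M_F/M_I = exp(−k·t) under first-order mass loss.  β > 1 means
the absolute amount increased; this pipeline uses the conservative default
threshold β > 2 as evidence of net import from outside the stump.  Ergosterol
participates exactly like an element (a 13th column), since its absolute
amount obeys the same bookkeeping.

"Initial" and "final" states are operationalised by extreme-stump selection:
the least fungus-colonized young stumps (low ergosterol, aged under a year)
versus the most colonized old stumps (high ergosterol, aged five years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import ElementProfile, StumpSample, round_half_up
from .errors import ConfigError, ElementDivisionError, InsufficientDataError

DEFAULT_IMPORT_THRESHOLD = 2.0
#: Literature extremes of the first-order decay constant for coarse woody debris.
K_LOW = 0.0200
K_HIGH = 0.1101


def remaining_mass(k_per_year: float, t_years: float) -> float:
    """Fraction of stump mass remaining after ``t`` years: exp(−k·t)."""
    if k_per_year < 0 or t_years < 0:
        raise ValueError(
            f"remaining_mass: k and t must be non-negative, got "
            f"k={k_per_year!r}, t={t_years!r}")
    return math.exp(-k_per_year * t_years)


@dataclass(frozen=True)
class DecayScenario:
    """One remaining-mass scenario, labelled for output tables.

    Construct either from a decay constant and time (mass ratio computed) or
    directly from a known mass ratio via :meth:`from_mass_ratio` — exactly one
    of the two modes.
    """

    label: str
    k_per_year: float | None
    t_years: float | None
    mass_ratio: float

    def __post_init__(self):
        if not (0 < self.mass_ratio <= 1):
            raise ConfigError(
                f"scenario {self.label!r}: mass_ratio={self.mass_ratio!r} "
                "outside (0, 1]")

    @classmethod
    def from_decay(cls, label: str, k_per_year: float,
                   t_years: float) -> "DecayScenario":
        return cls(label, k_per_year, t_years,
                   remaining_mass(k_per_year, t_years))

    @classmethod
    def from_mass_ratio(cls, label: str, mass_ratio: float) -> "DecayScenario":
        return cls(label, None, None, float(mass_ratio))


@dataclass(frozen=True)
class EnrichmentResult:
    """β for one element (or ergosterol) under one or more scenarios."""

    element: str
    conc_ratio: float
    beta_by_scenario: dict[str, float]
    imported: dict[str, bool]


def select_extremes(stumps: Sequence[StumpSample],
                    n_low: int = 5, n_high: int = 5,
                    low_max_erg: float = 25.0, high_min_erg: float = 440.0,
                    low_max_age: float = 1.0, high_min_age: float = 5.0,
                    ) -> tuple[list[StumpSample], list[StumpSample]]:
    """Pick the extreme-fungal-colonization stump groups.

    Initial group: the ``n_low`` lowest-ergosterol stumps among those with
    ergosterol < ``low_max_erg`` µg/g and age < ``low_max_age`` years.
    Final group: the ``n_high`` highest-ergosterol stumps among those with
    ergosterol > ``high_min_erg`` µg/g and age ≥ ``high_min_age`` years.
    Ties are broken by lexicographic stump_id so selection is deterministic.
    """
    low_pool = [s for s in stumps
                if s.ergosterol_ug_g < low_max_erg and s.age_years < low_max_age]
    high_pool = [s for s in stumps
                 if s.ergosterol_ug_g > high_min_erg and s.age_years >= high_min_age]
    problems = []
    if len(low_pool) < n_low:
        problems.append(
            f"initial group: {len(low_pool)} stump(s) with ergosterol < "
            f"{low_max_erg} µg/g and age < {low_max_age} y, need {n_low}")
    if len(high_pool) < n_high:
        problems.append(
            f"final group: {len(high_pool)} stump(s) with ergosterol > "
            f"{high_min_erg} µg/g and age >= {high_min_age} y, need {n_high}")
    if problems:
        raise InsufficientDataError("; ".join(problems))
    low_pool.sort(key=lambda s: (s.ergosterol_ug_g, s.stump_id))
    high_pool.sort(key=lambda s: (-s.ergosterol_ug_g, s.stump_id))
    return low_pool[:n_low], high_pool[:n_high]


def beta(initial_profile: ElementProfile | Mapping[str, float],
         final_profile: ElementProfile | Mapping[str, float],
         scenarios: Sequence[DecayScenario],
         import_threshold: float = DEFAULT_IMPORT_THRESHOLD,
         ) -> list[EnrichmentResult]:
    """Coefficient of difference β per element per remaining-mass scenario.

    β = (final concentration / initial concentration) × mass_ratio.  An
    element is flagged imported under a scenario iff β > ``import_threshold``.
    Every element of the initial profile must appear in the final profile and
    have a strictly positive initial concentration.
    """
    init = dict(initial_profile.concentrations
                if isinstance(initial_profile, ElementProfile)
                else initial_profile)
    fin = dict(final_profile.concentrations
               if isinstance(final_profile, ElementProfile)
               else final_profile)
    missing = set(init) - set(fin)
    if missing:
        raise ElementDivisionError(
            f"beta: element(s) {sorted(missing)} absent from the final profile")
    results = []
    for element in init:
        if init[element] <= 0:
            raise ElementDivisionError(
                f"beta: initial concentration of {element} is "
                f"{init[element]!r}; cannot form the concentration ratio")
        conc_ratio = fin[element] / init[element]
        by_scenario = {s.label: conc_ratio * s.mass_ratio for s in scenarios}
        imported = {lbl: b > import_threshold for lbl, b in by_scenario.items()}
        results.append(EnrichmentResult(element, conc_ratio,
                                        by_scenario, imported))
    return results


def rescale_beta(beta_value: float, mass_ratio_from: float,
                 mass_ratio_to: float) -> float:
    """Convert β between remaining-mass scenarios.

    β is proportional to M_F/M_I, so β(scenario 2) = β(scenario 1) × m2/m1.
    Used to check the internal consistency of published two-scenario tables.
    """
    if mass_ratio_from <= 0:
        raise ValueError("mass_ratio_from must be > 0")
    return beta_value * (mass_ratio_to / mass_ratio_from)


def render_beta_table(results: Sequence[EnrichmentResult],
                      decimals: int = 1):
    """Rows (element, conc_ratio, β per scenario, imported flags), β rounded.

    Mirrors the published table layout: β printed to 1 decimal, bold import
    markers rendered as booleans.  Full precision is retained in ``results``.
    """
    import pandas as pd

    rows = []
    for r in results:
        row: dict[str, object] = {"element": r.element,
                                  "conc_ratio": r.conc_ratio}
        for label, value in r.beta_by_scenario.items():
            row[f"beta_{label}"] = round_half_up(value, decimals)
            row[f"imported_{label}"] = r.imported[label]
        rows.append(row)
    return pd.DataFrame(rows)
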