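"""End-to-end orchestration: simulate/ingest → extremes → β → TSR/α → fits → RDA.

``run_full`` drives every stage and writes one file per published-table shape:

* ``beta.csv``       — coefficient of difference per element per remaining-mass
                       scenario, plus import flags and a direction call
* ``tsr_alpha.csv``  — TSR per species × sex on the low- and high-ergosterol
                       food, plus the α row
* ``fits_<family>.csv`` — selected regression per response with r², AIC, p
* ``rda.json``       — eigenvalues, variance fractions, loadings, permutation p
* ``run_log.json``   — seed, package version, per-stage counts and parameters

Every output is a pure function of (inputs, configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from . import __version__
from .core import (BeetleComposition, StumpSample, group_profile,
                   round_half_up)
from .enrichment import (DEFAULT_IMPORT_THRESHOLD, K_HIGH, K_LOW,
                         DecayScenario, beta, render_beta_table,
                         select_extremes)
from .errors import ConfigError
from .io import read_beetles, read_stumps
from .ordination import rda_single_constraint, rda_to_dict
from .regression import RESPONSE_FAMILIES, fits_to_frame, run_suite
from .stoichiometry import (DEFAULT_MISMATCH_THRESHOLD, DEFAULT_TSR_ELEMENTS,
                            alpha, tsr_table)
from .synthetic import GeneratorConfig, generate_beetles, generate_stumps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    n_low: int = 5
    n_high: int = 5
    low_max_erg: float = 25.0
    high_min_erg: float = 440.0
    low_max_age: float = 1.0
    high_min_age: float = 5.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Full-pipeline configuration.

    Exactly one of ``stumps_path`` / ``generator`` must be supplied; beetles
    come from ``beetles_path`` when given, otherwise from the generator's
    (synthetic) beetle profiles.
    """

    stumps_path: str | None = None
    beetles_path: str | None = None
    generator: GeneratorConfig | None = None
    selection: SelectionParams = field(default_factory=SelectionParams)
    k_low: float = K_LOW
    k_high: float = K_HIGH
    t_years: float = 5.0
    import_threshold: float = DEFAULT_IMPORT_THRESHOLD
    mismatch_threshold: float = DEFAULT_MISMATCH_THRESHOLD
    tsr_elements: tuple[str, ...] = DEFAULT_TSR_ELEMENTS
    regression_families: tuple[str, ...] = RESPONSE_FAMILIES
    rda_permutations: int = 999
    out_dir: str = "stumpstoich_out"
    seed: int = 0

    def __post_init__(self):
        if (self.stumps_path is None) == (self.generator is None):
            raise ConfigError(
                "exactly one of stumps_path / generator must be supplied")
        unknown = set(self.regression_families) - set(RESPONSE_FAMILIES)
        if unknown:
            raise ConfigError(f"unknown regression families: {sorted(unknown)}")


def classify_direction(beta_low_mass: float, beta_high_mass: float,
                       threshold: float = DEFAULT_IMPORT_THRESHOLD) -> str:
    """Direction of change in an element's absolute amount across scenarios.

    ``increase`` when β exceeds the import threshold under both remaining-mass
    scenarios, ``decrease`` when β < 1 under both, ``ambiguous`` when only one
    scenario crosses the threshold, otherwise ``no_change``.
    """
    betas = (beta_low_mass, beta_high_mass)
    if all(b > threshold for b in betas):
        return "increase"
    if all(b < 1 for b in betas):
        return "decrease"
    if (beta_low_mass > threshold) != (beta_high_mass > threshold):
        return "ambiguous"
    return "no_change"


@dataclass(frozen=True)
class ReportBundle:
    """In-memory results of a full run (also written to ``out_dir``)."""

    stumps: list[StumpSample]
    beetles: list[BeetleComposition]
    initial_group: list[StumpSample]
    final_group: list[StumpSample]
    beta_frame: "object"
    tsr_alpha_frame: "object"
    alpha_by_element: dict[str, float]
    fits: dict[str, list]
    rda: dict
    run_log: dict


def _scenarios(config: AnalysisConfig) -> list[DecayScenario]:
    # Labelled by remaining-mass fraction, low mass first (faster decay).
    high_k = DecayScenario.from_decay("low_mass", config.k_high, config.t_years)
    low_k = DecayScenario.from_decay("high_mass", config.k_low, config.t_years)
    return [low_k, high_k]


def run_full(config: AnalysisConfig) -> ReportBundle:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"seed": config.seed,
                     "stumpstoich_version": __version__,
                     "python": platform.python_version(),
                     "stages": {}}

    # Stage 1 — ingest or simulate.
    if config.stumps_path is not None:
        stumps, dropped = read_stumps(config.stumps_path)
        source = f"csv:{config.stumps_path}"
    else:
        stumps, _truth = generate_stumps(config.generator, seed=config.seed)
        dropped, source = 0, "generator"
    if config.beetles_path is not None:
        beetles, b_dropped = read_beetles(config.beetles_path)
    else:
        gen = config.generator or GeneratorConfig()
        beetles, b_dropped = generate_beetles(gen, seed=config.seed), 0
    run_log["stages"]["ingest"] = {
        "source": source, "n_stumps": len(stumps),
        "stump_rows_dropped": dropped, "n_beetles": len(beetles),
        "beetle_rows_dropped": b_dropped}
    log.info("ingest: %d stumps (%d dropped), %d beetles",
             len(stumps), dropped, len(beetles))

    # Stage 2 — extreme-stump selection.
    sel = config.selection
    initial, final = select_extremes(
        stumps, sel.n_low, sel.n_high, sel.low_max_erg, sel.high_min_erg,
        sel.low_max_age, sel.high_min_age)
    run_log["stages"]["select_extremes"] = {
        "params": dataclasses.asdict(sel),
        "initial_ids": [s.stump_id for s in initial],
        "final_ids": [s.stump_id for s in final]}
    log.info("select_extremes: initial=%s final=%s",
             [s.stump_id for s in initial], [s.stump_id for s in final])

    # Stage 3 — enrichment coefficients (ergosterol as 13th element).
    initial_profile = group_profile(initial)
    final_profile = group_profile(final)
    scenarios = _scenarios(config)
    results = beta(initial_profile, final_profile, scenarios,
                   config.import_threshold)
    beta_frame = render_beta_table(results)
    beta_frame["direction"] = [
        classify_direction(r.beta_by_scenario["low_mass"],
                           r.beta_by_scenario["high_mass"],
                           config.import_threshold)
        for r in results]
    beta_frame.to_csv(out / "beta.csv", index=False, float_format="%.10g")
    run_log["stages"]["enrichment"] = {
        "scenarios": {s.label: s.mass_ratio for s in scenarios},
        "import_threshold": config.import_threshold}

    # Stage 4 — TSR tables and the mitigation row.
    food_low = group_profile(initial, include_ergosterol=False)
    food_high = group_profile(final, include_ergosterol=False)
    table_low = tsr_table(food_low, beetles, config.tsr_elements,
                          food_label="low-ergosterol stumps")
    table_high = tsr_table(food_high, beetles, config.tsr_elements,
                           food_label="high-ergosterol stumps")
    mitigation = alpha(table_low, table_high)
    tsr_alpha_frame = _tsr_alpha_frame(table_low, table_high, mitigation,
                                       pd)
    tsr_alpha_frame.to_csv(out / "tsr_alpha.csv", index=False,
                           float_format="%.10g")
    run_log["stages"]["tsr_alpha"] = {
        "elements": list(config.tsr_elements),
        "mismatch_threshold": config.mismatch_threshold}

    # Stage 5 — regression suite per family.
    fits = {}
    for family in config.regression_families:
        family_fits = run_suite(stumps, family)
        fits[family] = family_fits
        fits_to_frame(family_fits).to_csv(
            out / f"fits_{family}.csv", index=False, float_format="%.10g")
    run_log["stages"]["regression"] = {
        "families": list(config.regression_families), "n": len(stumps)}

    # Stage 6 — redundancy analysis.
    rda_result = rda_single_constraint(stumps,
                                       n_permutations=config.rda_permutations,
                                       seed=config.seed)
    rda_dict = rda_to_dict(rda_result)
    (out / "rda.json").write_text(json.dumps(rda_dict, indent=2))
    run_log["stages"]["rda"] = {"n_permutations": config.rda_permutations,
                                "perm_p": rda_result.perm_p}

    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return ReportBundle(stumps=stumps, beetles=beetles,
                        initial_group=initial, final_group=final,
                        beta_frame=beta_frame,
                        tsr_alpha_frame=tsr_alpha_frame,
                        alpha_by_element=mitigation.alpha_by_element,
                        fits=fits, rda=rda_dict, run_log=run_log)


def _tsr_alpha_frame(table_low, table_high, mitigation, pd):
    """Published-table layout: per species × sex TSR rows plus the α row.

    TSR and α values are printed to 1 decimal (full precision stays in the
    in-memory tables); the α row reuses :func:`stoichiometry.alpha` output
    directly so the report can never drift from the module computation.
    """
    elements = list(table_low.elements)
    rows = []
    pairs = list(dict.fromkeys((sp, sx) for sp, sx, _ in table_low.entries))
    for sp, sx in pairs:
        for label, table in (("TSR_L", table_low), ("TSR_H", table_high)):
            row = {"species": sp, "sex": sx, "quantity": label}
            for el in elements:
                row[el] = round_half_up(table.entries[(sp, sx, el)], 1)
            rows.append(row)
    alpha_row = {"species": "", "sex": "", "quantity": "alpha"}
    alpha_row.update({el: round_half_up(mitigation.alpha_by_element[el], 1)
                      for el in elements})
    rows.append(alpha_row)
    return pd.DataFrame(rows, columns=["species", "sex", "quantity"] + elements)
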