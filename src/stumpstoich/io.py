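"""CSV readers/writers for the two table schemas the pipeline touches.

Dialect is deliberately rigid: comma-separated, ``.`` decimal, UTF-8, one
header row.  Rows with missing or non-numeric values are dropped whole (never
imputed — the downstream analyses are ratio-based and imputation would
fabricate stoichiometry); the number of drops is returned and logged.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import ELEMENTS, ElementProfile, BeetleComposition, StumpSample
from .errors import EmptyInputError, FormatError

log = logging.getLogger(__name__)

STUMP_COLUMNS = ("stump_id", "age_years", "ergosterol_ug_g") + ELEMENTS
BEETLE_COLUMNS = ("species", "sex") + ELEMENTS


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return frame


def read_stumps(path: str | Path) -> tuple[list[StumpSample], int]:
    """Read a stump table; returns ``(samples, n_dropped)``.

    Any row with a missing/non-numeric age, ergosterol or element value is
    dropped with a logged warning.
    """
    frame = _read_table(path, STUMP_COLUMNS)
    numeric_cols = list(STUMP_COLUMNS[1:])
    coerced = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    keep = coerced.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        bad_ids = frame.loc[~keep, "stump_id"].astype(str).tolist()
        log.warning("read_stumps(%s): dropped %d row(s) with missing or "
                    "non-numeric values: %s", path, n_dropped, bad_ids)
    samples = []
    for _, row in pd.concat([frame.loc[keep, ["stump_id"]],
                             coerced.loc[keep]], axis=1).iterrows():
        profile = ElementProfile({e: float(row[e]) for e in ELEMENTS})
        samples.append(StumpSample(
            stump_id=str(row["stump_id"]),
            age_years=float(row["age_years"]),
            ergosterol_ug_g=float(row["ergosterol_ug_g"]),
            profile=profile,
        ))
    return samples, n_dropped


def write_stumps(samples: Sequence[StumpSample], path: str | Path) -> None:
    """Write a stump table in the canonical schema (12 significant digits)."""
    rows = []
    for s in samples:
        row = {"stump_id": s.stump_id, "age_years": s.age_years,
               "ergosterol_ug_g": s.ergosterol_ug_g}
        row.update({e: s.profile[e] for e in ELEMENTS})
        rows.append(row)
    pd.DataFrame(rows, columns=list(STUMP_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g")


def read_beetles(path: str | Path) -> tuple[list[BeetleComposition], int]:
    """Read a beetle body-composition table; returns ``(beetles, n_dropped)``."""
    frame = _read_table(path, BEETLE_COLUMNS)
    coerced = frame[list(ELEMENTS)].apply(pd.to_numeric, errors="coerce")
    keep = coerced.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("read_beetles(%s): dropped %d incomplete row(s)",
                    path, n_dropped)
    beetles = []
    for idx in frame.index[keep]:
        profile = ElementProfile(
            {e: float(coerced.at[idx, e]) for e in ELEMENTS})
        beetles.append(BeetleComposition(
            species=str(frame.at[idx, "species"]),
            sex=str(frame.at[idx, "sex"]),
            profile=profile,
        ))
    return beetles, n_dropped


def write_beetles(beetles: Sequence[BeetleComposition],
                  path: str | Path) -> None:
    rows = []
    for b in beetles:
        row = {"species": b.species, "sex": b.sex}
        row.update({e: b.profile[e] for e in ELEMENTS})
        rows.append(row)
    pd.DataFrame(rows, columns=list(BEETLE_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Bundled reference tables (printed, 1-decimal values) for golden tests.
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("stumpstoich.data").joinpath(name)


def load_printed_tsr() -> pd.DataFrame:
    """Published TSR table: species × sex × food group, 10 element columns.

    ``group`` is ``low``/``high`` for beetles feeding on the five lowest- and
    five highest-ergosterol stumps respectively.  Values are the printed
    1-decimal TSRs.
    """
    with resources.as_file(_data_path("table1_tsr.csv")) as p:
        return pd.read_csv(p)


def load_printed_alpha() -> dict[str, float]:
    """Published mitigation-index row (α per element, 1 decimal)."""
    with resources.as_file(_data_path("table1_alpha.csv")) as p:
        frame = pd.read_csv(p)
    return {c: float(frame[c].iloc[0]) for c in frame.columns}


def load_printed_beta() -> pd.DataFrame:
    """Published enrichment coefficients β for the two remaining-mass scenarios.

    One row per M_F/M_I value (0.90 and 0.58); columns: mass_ratio, the 12
    elements, and ``erg`` (ergosterol as a pseudo-element).
    """
    with resources.as_file(_data_path("table2_beta.csv")) as p:
        return pd.read_csv(p)
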