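"""Readers and writers for subject and item tables, and profile/config loading.

Tables are plain delimited files (CSV) or Parquet; the on-disk schema is the
column layout documented in :data:`SUBJECT_COLUMNS` and :data:`ITEM_COLUMNS`.
An optional SAS-transport (XPT) ingester maps survey-native variable names
onto this schema through a user-editable mapping, so real recall microdata
can be dropped in without touching code.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nutrients import NUTRIENT_PANEL, MilkProfile, NutrientVector


class SchemaError(ValueError):
    """An input table is missing required columns or uses unknown categories."""


class ParseError(ValueError):
    """A cell could not be parsed as the required type."""


class ConfigError(ValueError):
    """A structured config file is invalid."""


SEX_LEVELS = ("male", "female")
ETHNICITY_LEVELS = ("mexican_american", "other_hispanic", "nh_white", "nh_black", "other")
PIR_LEVELS = ("<1.35", "1.35-1.85", ">1.85")
ACTIVITY_LEVELS = ("sedentary", "moderate", "vigorous")
WEIGHT_STATUS_LEVELS = ("under", "normal", "over", "obese")

_CATEGORICALS = {
    "sex": SEX_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "pir_level": PIR_LEVELS,
    "physical_activity": ACTIVITY_LEVELS,
    "weight_status": WEIGHT_STATUS_LEVELS,
}

SUBJECT_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "ethnicity",
    "pir_level",
    "physical_activity",
    "weight_status",
    "pregnant_or_lactating",
    "recall_reliable",
    "day1_weight",
    "stratum_id",
    "psu_id",
)

ITEM_COLUMNS = (
    "subject_id",
    "food_code",
    "wweia_code",
    "occasion_code",
    "grams",
) + NUTRIENT_PANEL


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    return pd.read_csv(path, float_precision="round_trip")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required column(s): {missing}")


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise ParseError(
            f"{what} column {column!r}: non-numeric value {df[column].iloc[row - 1]!r} on row {row}"
        )
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0]) + 1
        raise ParseError(f"{what} column {column!r}: missing value on row {row}")
    return out.astype(float)


def _boolean(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    mapping = {
        True: True, False: False, 1: True, 0: False,
        "1": True, "0": False, "true": True, "false": False,
        "True": True, "False": False,
    }
    out = df[column].map(mapping)
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0]) + 1
        raise ParseError(f"{what} column {column!r}: unparseable flag on row {row}")
    return out.astype(bool)


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read a subject table; one validated row per child.

    Categorical fields are validated against their closed enumerations and
    unknown categories rejected; ``day1_weight`` must be numeric and
    nonnegative.
    """
    df = _read_table(path)
    _require_columns(df, SUBJECT_COLUMNS, "subject")
    df = df.loc[:, list(SUBJECT_COLUMNS)].copy()
    df["age_years"] = _numeric(df, "age_years", "subject").astype(int)
    df["day1_weight"] = _numeric(df, "day1_weight", "subject")
    if (df["day1_weight"] < 0).any():
        row = int(df.index[df["day1_weight"] < 0][0]) + 1
        raise ParseError(f"subject column 'day1_weight': negative weight on row {row}")
    for col, levels in _CATEGORICALS.items():
        vals = df[col].astype(str)
        unknown = sorted(set(vals) - set(levels))
        if unknown:
            raise SchemaError(f"subject column {col!r}: unknown categories {unknown}")
        df[col] = pd.Categorical(vals, categories=levels)
    for col in ("pregnant_or_lactating", "recall_reliable"):
        df[col] = _boolean(df, col, "subject")
    df["subject_id"] = df["subject_id"].astype(str)
    df["stratum_id"] = df["stratum_id"].astype(str)
    df["psu_id"] = df["psu_id"].astype(str)
    return df.reset_index(drop=True)


def read_items(path: str | Path) -> pd.DataFrame:
    """Read a food/beverage item table; one validated row per reported item.

    Nutrient columns are mapped by name onto the fixed 18-nutrient panel.
    Negative nutrient amounts are rejected, and an item of zero grams must
    carry an all-zero nutrient vector. Subject ids with no matching subject
    row are allowed here (the join happens downstream).
    """
    df = _read_table(path)
    _require_columns(df, ITEM_COLUMNS, "item")
    df = df.loc[:, list(ITEM_COLUMNS)].copy()
    if len(df) == 0:
        df["subject_id"] = df["subject_id"].astype(str)
        return df.reset_index(drop=True)
    for col in ("food_code", "wweia_code", "occasion_code"):
        df[col] = _numeric(df, col, "item").astype(int)
    df["grams"] = _numeric(df, "grams", "item")
    if (df["grams"] < 0).any():
        row = int(np.flatnonzero((df["grams"] < 0).to_numpy())[0]) + 1
        raise ParseError(f"item column 'grams': negative amount on row {row}")
    for col in NUTRIENT_PANEL:
        df[col] = _numeric(df, col, "item")
        if (df[col] < 0).any():
            row = int(np.flatnonzero((df[col] < 0).to_numpy())[0]) + 1
            raise ParseError(f"item column {col!r}: negative value on row {row}")
    zero_g = df["grams"].to_numpy() == 0
    if zero_g.any():
        nut = df.loc[zero_g, list(NUTRIENT_PANEL)].to_numpy()
        if (nut != 0).any():
            bad = int(np.flatnonzero(zero_g)[np.flatnonzero((nut != 0).any(axis=1))[0]]) + 1
            raise ParseError(f"item row {bad}: zero grams but nonzero nutrients")
    df["subject_id"] = df["subject_id"].astype(str)
    return df.reset_index(drop=True)


def _lossless(v: float) -> str:
    return repr(float(v))


def write_subjects(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_lossless)


def write_items(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_lossless)


def load_milk_profile(config: Mapping | str | Path) -> MilkProfile:
    """Build a :class:`MilkProfile` from a TOML file or an in-memory mapping.

    Expected layout::

        [milk_profile]
        grams_per_cup = 244.0
        [milk_profile.per_cup]
        energy = 122.0
        # ... one key per panel nutrient
    """
    if isinstance(config, (str, Path)):
        with open(config, "rb") as fh:
            config = tomllib.load(fh)
    section = config.get("milk_profile", config)
    per_cup = section.get("per_cup")
    if per_cup is None:
        raise ConfigError("milk profile config missing 'per_cup' table")
    try:
        vec = NutrientVector.from_mapping(per_cup)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if vec.energy <= 0:
        raise ConfigError("milk profile per-cup energy must be positive")
    try:
        return MilkProfile(per_cup=vec, grams_per_cup=float(section.get("grams_per_cup", 244.0)))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def read_xpt(path: str | Path, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Ingest a SAS-transport file, renaming survey-native variables.

    ``mapping`` maps source variable names (e.g. the survey's occasion or
    weight variables) to this package's schema names. Only mapped columns
    are kept. Validation happens later through :func:`read_subjects` /
    :func:`read_items` semantics on the renamed frame.
    """
    df = pd.read_sas(path, format="xport")
    missing = [src for src in mapping if src not in df.columns]
    if missing:
        raise SchemaError(f"XPT file missing mapped variable(s): {missing}")
    return df.loc[:, list(mapping)].rename(columns=dict(mapping))


def apply_xpt_mapping(df: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Rename survey-native columns of an already-loaded frame (see :func:`read_xpt`)."""
    missing = [src for src in mapping if src not in df.columns]
    if missing:
        raise SchemaError(f"frame missing mapped variable(s): {missing}")
    return df.loc[:, list(mapping)].rename(columns=dict(mapping))
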