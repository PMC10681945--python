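"""Shared fixtures: tiny hand-built subject/item tables and design helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from milksub import NUTRIENT_PANEL, SurveyDesign, default_category_map, default_milk_profile
from milksub.classify import OccasionMap


def make_items(rows: list[dict]) -> pd.DataFrame:
    """Build an item table from sparse row dicts; unmentioned nutrients are 0."""
    records = []
    for row in rows:
        rec = {"subject_id": "s1", "food_code": 0, "wweia_code": 9999,
               "occasion_code": 6, "grams": 100.0}
        rec.update({n: 0.0 for n in NUTRIENT_PANEL})
        rec.update(row)
        records.append(rec)
    cols = ["subject_id", "food_code", "wweia_code", "occasion_code", "grams",
            *NUTRIENT_PANEL]
    df = pd.DataFrame(records, columns=cols)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def make_subjects(rows: list[dict]) -> pd.DataFrame:
    records = []
    for i, row in enumerate(rows):
        rec = {"subject_id": f"s{i + 1}", "age_years": 10, "sex": "female",
               "ethnicity": "nh_white", "pir_level": ">1.85",
               "physical_activity": "moderate", "weight_status": "normal",
               "pregnant_or_lactating": False, "recall_reliable": True,
               "day1_weight": 1.0, "stratum_id": "S0", "psu_id": f"P{i % 2}"}
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


def srs_design(n: int) -> SurveyDesign:
    """Equal weights, one stratum, every subject its own PSU (SRS limit)."""
    return SurveyDesign(weight=np.ones(n), stratum=np.zeros(n, dtype=int),
                        psu=np.arange(n))


def random_design(rng: np.random.Generator, n_strata: int, psus: int,
                  per_psu_lo: int = 5, per_psu_hi: int = 15) -> SurveyDesign:
    """A small random stratified-cluster design with lognormal weights."""
    strata, psu_ids = [], []
    for h in range(n_strata):
        for j in range(psus):
            m = int(rng.integers(per_psu_lo, per_psu_hi + 1))
            strata.extend([h] * m)
            psu_ids.extend([j] * m)
    n = len(strata)
    return SurveyDesign(weight=rng.lognormal(0, 0.5, n),
                        stratum=np.array(strata), psu=np.array(psu_ids))


@pytest.fixture
def profile():
    return default_milk_profile()


@pytest.fixture
def cmap():
    return default_category_map()


@pytest.fixture
def omap():
    return OccasionMap()
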