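"""Survey-analog synthetic recall data with fully known truth.

Generates subject and item tables shaped like pooled 24-h recall microdata
from a stratified multistage survey of children aged 6-18 y: a multi-
stratum / multi-PSU design with lognormal weights, categorical demographic
covariates, and per-category beverage consumption whose per-capita mean
grams follow configurable linear age trends. Amounts are gamma distributed
(nonnegative, right-skewed, like real intake); nutrients are grams times a
fixed per-gram density vector per category; each item lands on a meal
occasion drawn from a category-specific allocation. A single composite
"rest of diet" item per subject supplies the non-beverage remainder of the
day so that totals and contribution ratios have realistic denominators.

Every true mean, slope and ratio implied by a spec is exportable as a
machine-readable truth ledger for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nutrients import DEFAULT_MILK_PER_CUP, NUTRIENT_PANEL

OCCASION_CODES = {"breakfast": 1, "lunch": 2, "dinner": 3, "snack": 6}
_AGES = np.arange(6, 19)


@dataclass(frozen=True)
class CategorySpec:
    """One consumption category: codes, amount model, occasions, densities."""

    name: str
    wweia_code: int
    food_code: int
    p_consume: float
    mean_age6: float          # per-capita mean grams/day at age 6
    slope: float              # change in per-capita mean grams/day per year of age
    gamma_shape: float = 2.0
    occasions: Mapping[str, float] = field(
        default_factory=lambda: {"breakfast": 0.25, "lunch": 0.25, "dinner": 0.25, "snack": 0.25})
    density: Mapping[str, float] = field(default_factory=dict)  # per-gram, sparse

    def mean_grams(self, age) -> np.ndarray:
        """Per-capita mean grams/day at (vector of) ages."""
        return self.mean_age6 + self.slope * (np.asarray(age, dtype=float) - 6.0)

    def density_vector(self) -> np.ndarray:
        return np.array([float(self.density.get(n, 0.0)) for n in NUTRIENT_PANEL])

    @property
    def meal_share(self) -> float:
        return float(self.occasions.get("lunch", 0.0) + self.occasions.get("dinner", 0.0))

    def validate(self) -> None:
        if not 0.0 <= self.p_consume <= 1.0:
            raise ValueError(f"{self.name}: p_consume outside [0, 1]")
        occ_total = sum(self.occasions.values())
        if abs(occ_total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: occasion probabilities sum to {occ_total}, not 1")
        if any(v < 0 for v in self.density.values()):
            raise ValueError(f"{self.name}: negative nutrient density")
        if np.any(self.mean_grams(_AGES) < 0):
            raise ValueError(f"{self.name}: implied mean grams negative within ages 6-18")
        if self.gamma_shape <= 0:
            raise ValueError(f"{self.name}: gamma shape must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of the synthetic population and consumption model."""

    n_subjects: int = 5000
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_log_sigma: float = 0.5
    male_prob: float = 0.51
    ethnicity_probs: Mapping[str, float] = field(default_factory=lambda: {
        "mexican_american": 0.14, "other_hispanic": 0.065, "nh_white": 0.57,
        "nh_black": 0.14, "other": 0.085})
    pir_probs: Mapping[str, float] = field(default_factory=lambda: {
        "<1.35": 0.33, "1.35-1.85": 0.11, ">1.85": 0.56})
    activity_probs: Mapping[str, float] = field(default_factory=lambda: {
        "sedentary": 0.14, "moderate": 0.23, "vigorous": 0.63})
    weight_status_probs: Mapping[str, float] = field(default_factory=lambda: {
        "under": 0.035, "normal": 0.62, "over": 0.16, "obese": 0.185})
    pregnant_frac: float = 116 / 26918
    unreliable_frac: float = 5475 / 26918
    categories: tuple[CategorySpec, ...] = ()

    def __post_init__(self) -> None:
        if not self.categories:
            object.__setattr__(self, "categories", default_categories())

    def validate(self) -> None:
        if self.psus_per_stratum < 2:
            raise ValueError("psus_per_stratum must be at least 2")
        if self.n_strata < 1:
            raise ValueError("n_strata must be at least 1")
        for probs, what in ((self.ethnicity_probs, "ethnicity"),
                            (self.pir_probs, "pir"),
                            (self.activity_probs, "activity"),
                            (self.weight_status_probs, "weight status")):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} probabilities sum to {total}, not 1")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"{what} probability outside [0, 1]")
        for frac, what in ((self.male_prob, "male_prob"),
                           (self.pregnant_frac, "pregnant_frac"),
                           (self.unreliable_frac, "unreliable_frac")):
            if not 0 <= frac <= 1:
                raise ValueError(f"{what} outside [0, 1]")
        for cat in self.categories:
            cat.validate()

    def category(self, name: str) -> CategorySpec:
        for cat in self.categories:
            if cat.name == name:
                return cat
        raise KeyError(name)

    def with_category(self, name: str, **changes) -> "GeneratorSpec":
        """Copy of the spec with one category's parameters replaced."""
        cats = tuple(replace(c, **changes) if c.name == name else c
                     for c in self.categories)
        if name not in {c.name for c in self.categories}:
            raise KeyError(name)
        return replace(self, categories=cats)


def _milk_density() -> dict[str, float]:
    return {n: v / 244.0 for n, v in DEFAULT_MILK_PER_CUP.items() if v}


def default_categories() -> tuple[CategorySpec, ...]:
    """The shipped consumption model.

    Per-capita means are anchored at age 7 to typical pooled-survey levels
    for US children (milk 210 g/d declining 2.64 g/d/y, flavored milk
    91.7 g/d declining 6.21 g/d/y, soft drinks 123 g/d rising 25.3 g/d/y,
    coffee/tea rising 13.1 g/d/y, ...), with energy densities that put
    caloric beverages near 18% of total energy and meal-occasion shares
    that put lunch+dinner nonmilk beverage energy near half a cup of milk.
    """
    return (
        CategorySpec("milk", 1002, 11100000, 0.62, 212.64, -2.64,
                     occasions={"breakfast": 0.5, "lunch": 0.2, "dinner": 0.2, "snack": 0.1},
                     density=_milk_density()),
        CategorySpec("flavored_milk", 1202, 11511100, 0.30, 97.91, -6.21,
                     occasions={"breakfast": 0.2, "lunch": 0.5, "dinner": 0.1, "snack": 0.2},
                     density={"energy": 0.8, "carbohydrate": 0.104, "dietary_fiber": 0.002,
                              "total_sugars": 0.096, "added_sugars": 0.022, "protein": 0.032,
                              "total_fat": 0.034, "mufa": 0.0098, "pufa": 0.0012, "sfa": 0.021,
                              "calcium": 1.12, "magnesium": 0.11, "potassium": 1.67,
                              "sodium": 0.66, "vitamin_a_re": 0.55, "folate_dfe": 0.05,
                              "vitamin_b12": 0.0045, "vitamin_d": 0.012}),
        CategorySpec("milk_substitutes", 1404, 11320000, 0.02, 3.84, -0.01,
                     occasions={"breakfast": 0.5, "lunch": 0.15, "dinner": 0.15, "snack": 0.2},
                     density={"energy": 0.45, "carbohydrate": 0.06, "dietary_fiber": 0.004,
                              "total_sugars": 0.04, "added_sugars": 0.008, "protein": 0.01,
                              "total_fat": 0.01, "mufa": 0.006, "pufa": 0.002, "sfa": 0.001,
                              "calcium": 1.2, "magnesium": 0.06, "potassium": 0.5,
                              "sodium": 0.4, "vitamin_a_re": 0.6, "folate_dfe": 0.02,
                              "vitamin_b12": 0.004, "vitamin_d": 0.01}),
        CategorySpec("fruit_juice_100", 7002, 61210000, 0.35, 94.63, -0.23,
                     occasions={"breakfast": 0.55, "lunch": 0.1, "dinner": 0.05, "snack": 0.3},
                     density={"energy": 0.46, "carbohydrate": 0.112, "dietary_fiber": 0.002,
                              "total_sugars": 0.09, "protein": 0.002, "total_fat": 0.001,
                              "calcium": 0.1, "magnesium": 0.1, "potassium": 1.8,
                              "sodium": 0.04, "vitamin_a_re": 0.02, "folate_dfe": 0.2}),
        CategorySpec("soft_drinks", 7202, 92410310, 0.42, 97.7, 25.3,
                     occasions={"breakfast": 0.05, "lunch": 0.15, "dinner": 0.15, "snack": 0.65},
                     density={"energy": 0.41, "carbohydrate": 0.106, "total_sugars": 0.104,
                              "added_sugars": 0.0247, "potassium": 0.02, "sodium": 0.04}),
        CategorySpec("fruit_drinks", 7204, 92510610, 0.40, 123.58, 1.42,
                     occasions={"breakfast": 0.1, "lunch": 0.15, "dinner": 0.15, "snack": 0.6},
                     density={"energy": 0.45, "carbohydrate": 0.115, "total_sugars": 0.11,
                              "added_sugars": 0.026, "calcium": 0.04, "magnesium": 0.02,
                              "potassium": 0.15, "sodium": 0.1, "vitamin_a_re": 0.005,
                              "folate_dfe": 0.05}),
        CategorySpec("sports_energy", 7206, 95310550, 0.08, 15.92, 4.08,
                     occasions={"breakfast": 0.05, "lunch": 0.15, "dinner": 0.15, "snack": 0.65},
                     density={"energy": 0.3, "carbohydrate": 0.078, "total_sugars": 0.06,
                              "added_sugars": 0.014, "magnesium": 0.02, "potassium": 0.3,
                              "sodium": 0.4}),
        CategorySpec("coffee_tea", 7302, 92101000, 0.12, 20.5, 13.1,
                     occasions={"breakfast": 0.6, "lunch": 0.05, "dinner": 0.05, "snack": 0.3},
                     density={"energy": 0.15, "carbohydrate": 0.035, "total_sugars": 0.03,
                              "added_sugars": 0.0071, "magnesium": 0.03, "potassium": 0.4,
                              "sodium": 0.02, "folate_dfe": 0.01}),
        CategorySpec("rest_of_diet", 9999, 99999999, 1.0, 998.8, 20.2, gamma_shape=6.0,
                     occasions={"breakfast": 0.25, "lunch": 0.25, "dinner": 0.3, "snack": 0.2},
                     density={"energy": 1.5, "carbohydrate": 0.188, "dietary_fiber": 0.0121,
                              "total_sugars": 0.0674, "added_sugars": 0.0109, "protein": 0.0517,
                              "total_fat": 0.062, "mufa": 0.0224, "pufa": 0.0136, "sfa": 0.0206,
                              "calcium": 0.579, "magnesium": 0.166, "potassium": 1.405,
                              "sodium": 2.633, "vitamin_a_re": 0.424, "folate_dfe": 0.477,
                              "vitamin_b12": 0.0032, "vitamin_d": 0.00201}),
    )


def default_generator_spec(n_subjects: int = 5000) -> GeneratorSpec:
    return GeneratorSpec(n_subjects=n_subjects)


_SUBJECT_DTYPES = {
    "subject_id": str, "age_years": int, "sex": str, "ethnicity": str,
    "pir_level": str, "physical_activity": str, "weight_status": str,
    "pregnant_or_lactating": bool, "recall_reliable": bool,
    "day1_weight": float, "stratum_id": str, "psu_id": str,
}


def generate_population(spec: GeneratorSpec, seed: int) -> pd.DataFrame:
    """Draw the subject table: design variables, demographics, eligibility flags."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _SUBJECT_DTYPES.items()})

    def cat(probs: Mapping[str, float]) -> np.ndarray:
        levels = list(probs)
        return rng.choice(levels, size=n, p=np.array([probs[k] for k in levels]))

    stratum = np.arange(n) % spec.n_strata  # balanced allocation
    psu = rng.integers(0, spec.psus_per_stratum, size=n)
    df = pd.DataFrame({
        "subject_id": [f"C{i:07d}" for i in range(n)],
        "age_years": rng.integers(6, 19, size=n),
        "sex": np.where(rng.random(n) < spec.male_prob, "male", "female"),
        "ethnicity": cat(spec.ethnicity_probs),
        "pir_level": cat(spec.pir_probs),
        "physical_activity": cat(spec.activity_probs),
        "weight_status": cat(spec.weight_status_probs),
        "pregnant_or_lactating": rng.random(n) < spec.pregnant_frac,
        "recall_reliable": rng.random(n) >= spec.unreliable_frac,
        "day1_weight": rng.lognormal(mean=0.0, sigma=spec.weight_log_sigma, size=n),
        "stratum_id": [f"S{h:02d}" for h in stratum],
        "psu_id": [f"P{j}" for j in psu],
    })
    return df


def generate_recalls(subjects: pd.DataFrame, spec: GeneratorSpec, seed: int) -> pd.DataFrame:
    """Draw the item table for a subject frame.

    Per subject and category: Bernoulli consumption, a gamma amount around
    the age-linear per-capita mean (conditional mean = per-capita mean /
    consumption probability, so per-capita means match the trend exactly),
    nutrients = grams x density, occasion from the category allocation.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = len(subjects)
    age = subjects["age_years"].to_numpy(dtype=float)
    sid = subjects["subject_id"].to_numpy()
    frames = []
    for cat in spec.categories:  # fixed order keeps the draw stream reproducible
        consumes = rng.random(n) < cat.p_consume
        mu = cat.mean_grams(age)
        occ_names = list(cat.occasions)
        occ_p = np.array([cat.occasions[k] for k in occ_names])
        occ_codes = np.array([OCCASION_CODES[k] for k in occ_names])
        occ = occ_codes[rng.choice(len(occ_names), size=n, p=occ_p)]
        if cat.p_consume <= 0 or not consumes.any():
            continue
        cond_mean = mu[consumes] / cat.p_consume
        grams = rng.gamma(cat.gamma_shape, cond_mean / cat.gamma_shape)
        nutr = np.outer(grams, cat.density_vector())
        frame = pd.DataFrame({
            "subject_id": sid[consumes],
            "food_code": cat.food_code,
            "wweia_code": cat.wweia_code,
            "occasion_code": occ[consumes],
            "grams": grams,
        })
        for j, name in enumerate(NUTRIENT_PANEL):
            frame[name] = nutr[:, j]
        frames.append(frame)
    if not frames:
        cols = ["subject_id", "food_code", "wweia_code", "occasion_code", "grams",
                *NUTRIENT_PANEL]
        return pd.DataFrame({c: pd.Series(dtype=float if c not in
                                          ("subject_id",) else str) for c in cols})
    return pd.concat(frames, ignore_index=True)


def _group_mean(cat: CategorySpec, lo: int, hi: int) -> float:
    ages = np.arange(lo, hi + 1)
    return float(cat.mean_grams(ages).mean())


def export_truth(spec: GeneratorSpec, path: str | Path | None = None) -> dict:
    """Every true mean, slope and ratio the spec implies, as a nested dict.

    Expectations pool ages 6-18 uniformly (the generator's age law) and use
    the fact that weights are drawn independently of intake, so weighted
    population expectations equal unweighted ones. Optionally written as
    TOML for round-tripping.
    """
    spec.validate()
    beverage = [c for c in spec.categories if c.name != "rest_of_diet"]
    milk_groups = {"milk", "flavored_milk", "milk_substitutes"}
    truth: dict = {"categories": {}}
    for cat in spec.categories:
        e = float(cat.density.get("energy", 0.0))
        truth["categories"][cat.name] = {
            "p_consume": cat.p_consume,
            "mean_grams_age6": cat.mean_age6,
            "slope_g_per_y": cat.slope,
            "energy_density_kcal_per_g": e,
            "meal_share": cat.meal_share,
            "mean_grams_6_8": _group_mean(cat, 6, 8),
            "mean_grams_9_13": _group_mean(cat, 9, 13),
            "mean_grams_14_18": _group_mean(cat, 14, 18),
            "mean_grams_pooled": _group_mean(cat, 6, 18),
        }

    def pooled_energy(cats) -> float:
        return sum(_group_mean(c, 6, 18) * float(c.density.get("energy", 0.0))
                   for c in cats)

    total_energy = pooled_energy(spec.categories)
    incl = pooled_energy(beverage)
    excl = pooled_energy([c for c in beverage if c.name not in milk_groups])
    replaced = sum(_group_mean(c, 6, 18) * float(c.density.get("energy", 0.0)) * c.meal_share
                   for c in beverage if c.name not in milk_groups)
    per_cup_energy = DEFAULT_MILK_PER_CUP["energy"]
    truth["derived"] = {
        "total_energy_kcal": total_energy,
        "beverage_energy_share_incl_milk_pct": 100.0 * incl / total_energy,
        "beverage_energy_share_excl_milk_pct": 100.0 * excl / total_energy,
        "expected_replaced_energy_kcal": replaced,
        "expected_cup_equivalents": replaced / per_cup_energy,
        "pregnant_frac": spec.pregnant_frac,
        "unreliable_frac": spec.unreliable_frac,
    }
    if path is not None:
        write_toml(truth, path)
    return truth


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_toml(data: Mapping, path: str | Path) -> None:
    """Minimal TOML emitter for nested mappings of scalars and lists."""
    lines: list[str] = []

    def emit(table: Mapping, prefix: tuple[str, ...]) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, Mapping)}
        subtables = {k: v for k, v in table.items() if isinstance(v, Mapping)}
        if prefix and (scalars or not subtables):
            lines.append("[" + ".".join(f'"{p}"' if "." in p else p for p in prefix) + "]")
        for k, v in scalars.items():
            key = k if k.replace("_", "").replace("-", "").isalnum() else f'"{k}"'
            lines.append(f"{key} = {_toml_value(v)}")
        if scalars:
            lines.append("")
        for k, v in subtables.items():
            emit(v, prefix + (k,))

    emit(data, ())
    Path(path).write_text("\n".join(lines) + "\n")
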