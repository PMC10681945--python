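"""Per-subject nutrient-modeling scenarios built on the milk-NFS profile.

Two deterministic what-if models, applied to each subject's reported daily
intake:

1. *Add a serving*: one cup-equivalent of milk, NFS is added to the day's
   totals. No energy is removed, so totals rise by exactly the per-cup
   profile.
2. *Isocaloric replacement*: every qualifying nonmilk caloric beverage
   consumed at lunch or dinner is removed and replaced by the amount of
   milk carrying the same energy, so total energy is unchanged while the
   nutrient mix shifts toward milk's.

Both models operate on nutrient totals; the item table itself is never
rewritten. An audit helper can emit the per-item replacement ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BeverageCategoryMap, OccasionMap, meal_beverage_mask
from .nutrients import NUTRIENT_PANEL, MilkProfile, NutrientVector

#: Which beverage group each replacement scope swaps out at meals.
REPLACEMENT_SCOPES = {
    "all_caloric": "caloric_bev_excl_milk",
    "ssb_only": "ssb",
    "milk_substitutes_only": "milk_substitutes",
}


@dataclass(frozen=True)
class ModelResult:
    """One subject's modeled day: baseline and adjusted nutrient totals."""

    baseline: NutrientVector
    adjusted: NutrientVector
    replaced_energy: float
    cup_equivalents: float


@dataclass(frozen=True)
class TableModelResult:
    """Population version of :class:`ModelResult`: frames indexed by subject."""

    baseline: pd.DataFrame
    adjusted: pd.DataFrame
    replaced_energy: pd.Series
    cup_equivalents: pd.Series


@dataclass(frozen=True)
class MeaningfulChange:
    """The 10%-change rule applied to a pair of population means."""

    percent: float
    meaningful: bool
    undefined_baseline: bool = False


def add_milk_serving(baseline: NutrientVector, profile: MilkProfile) -> ModelResult:
    """Scenario 1: add one cup-equivalent of milk to a subject's daily totals."""
    return ModelResult(baseline=baseline,
                       adjusted=baseline + profile.per_cup,
                       replaced_energy=0.0,
                       cup_equivalents=1.0)


def replacement_scope_select(scope: str):
    """Item predicate for a replacement scope.

    Returns a callable ``(items, omap, cmap) -> boolean mask`` selecting the
    items the isocaloric model removes: caloric (energy > 0) members of the
    scope's beverage group consumed at lunch or dinner.
    """
    if scope not in REPLACEMENT_SCOPES:
        raise ValueError(
            f"unknown replacement scope {scope!r}; expected one of {sorted(REPLACEMENT_SCOPES)}"
        )
    group = REPLACEMENT_SCOPES[scope]

    def predicate(items: pd.DataFrame,
                  omap: OccasionMap | None = None,
                  cmap: BeverageCategoryMap | None = None) -> np.ndarray:
        return meal_beverage_mask(items, omap, cmap, group=group)

    return predicate


def subject_totals(items: pd.DataFrame, subject_ids) -> pd.DataFrame:
    """Daily 18-nutrient totals per subject over all reported items."""
    index = pd.Index([str(s) for s in subject_ids], name="subject_id")
    if len(items) == 0:
        return pd.DataFrame(0.0, index=index, columns=list(NUTRIENT_PANEL))
    totals = items.groupby("subject_id")[list(NUTRIENT_PANEL)].sum()
    return totals.reindex(index, fill_value=0.0).astype(float)


def add_milk_serving_table(baseline: pd.DataFrame, profile: MilkProfile) -> TableModelResult:
    """Scenario 1 applied to a per-subject totals frame."""
    adjusted = baseline + profile.per_cup.values
    zeros = pd.Series(0.0, index=baseline.index)
    return TableModelResult(baseline=baseline, adjusted=adjusted,
                            replaced_energy=zeros,
                            cup_equivalents=zeros + 1.0)


def isocaloric_replace(items: pd.DataFrame, subject_ids, profile: MilkProfile,
                       omap: OccasionMap | None = None,
                       cmap: BeverageCategoryMap | None = None,
                       scope: str = "all_caloric",
                       audit: bool = False) -> TableModelResult | tuple[TableModelResult, pd.DataFrame]:
    """Scenario 2: isocaloric replacement of meal beverages with milk.

    For each subject, the items selected by ``scope`` at lunch/dinner are
    removed from the daily totals and milk (per-kcal profile) is added back
    at exactly the removed energy. Subjects with no qualifying items are
    returned unchanged. With ``audit=True`` also returns the per-item
    replacement ledger.
    """
    baseline = subject_totals(items, subject_ids)
    predicate = replacement_scope_select(scope)
    if len(items) == 0:
        mask = np.zeros(0, dtype=bool)
    else:
        mask = predicate(items, omap, cmap)
    replaced = items.loc[mask] if len(items) else items
    removed = (replaced.groupby("subject_id")[list(NUTRIENT_PANEL)].sum()
               .reindex(baseline.index, fill_value=0.0).astype(float))
    energy = removed["energy"]
    milk_back = np.outer(energy.to_numpy(), profile.per_kcal.values)
    adjusted = baseline - removed + pd.DataFrame(milk_back, index=baseline.index,
                                                 columns=list(NUTRIENT_PANEL))
    result = TableModelResult(baseline=baseline, adjusted=adjusted,
                              replaced_energy=energy.rename("replaced_energy"),
                              cup_equivalents=(energy / profile.per_cup.energy
                                               ).rename("cup_equivalents"))
    if audit:
        ledger = replaced.loc[:, ["subject_id", "food_code", "wweia_code",
                                  "occasion_code", "grams", "energy"]].copy()
        ledger["milk_grams_back"] = ledger["energy"] / profile.per_cup.energy * profile.grams_per_cup
        return result, ledger.reset_index(drop=True)
    return result


def isocaloric_replace_subject(items: pd.DataFrame, subject_id: str,
                               profile: MilkProfile,
                               omap: OccasionMap | None = None,
                               cmap: BeverageCategoryMap | None = None,
                               scope: str = "all_caloric") -> ModelResult:
    """Scenario 2 for a single subject, returned as scalar vectors."""
    res = isocaloric_replace(items[items["subject_id"] == str(subject_id)],
                             [subject_id], profile, omap, cmap, scope)
    return ModelResult(
        baseline=NutrientVector(res.baseline.iloc[0].to_numpy()),
        adjusted=NutrientVector(res.adjusted.iloc[0].to_numpy()),
        replaced_energy=float(res.replaced_energy.iloc[0]),
        cup_equivalents=float(res.cup_equivalents.iloc[0]),
    )


def flag_meaningful_change(baseline_mean: float, adjusted_mean: float,
                           threshold: float = 10.0) -> MeaningfulChange:
    """Apply the 10%-change rule to a baseline/adjusted pair of means.

    Used for the add-a-serving scenario, where every subject receives the
    same deterministic increment and a conventional significance test would
    be meaningless; a change of at least ``threshold`` percent in either
    direction counts as meaningful. A nonpositive baseline leaves the
    percent undefined and is flagged separately.
    """
    if baseline_mean <= 0:
        return MeaningfulChange(percent=float("nan"), meaningful=False,
                                undefined_baseline=True)
    pct = 100.0 * (adjusted_mean - baseline_mean) / baseline_mean
    return MeaningfulChange(percent=pct, meaningful=abs(pct) >= threshold)
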