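"""Subject exclusion rules and code-driven beverage classification.

Beverage groups are defined purely from the 4-digit WWEIA category code of
each item: the first two digits identify the subgroup (10 = milk, 12 =
flavored milk, 70 = 100% juice, 72 = sugar-sweetened beverages, 73 =
coffee/tea, ...), and a handful of exact 4-digit categories (1404 milk
substitutes, 7202 soft drinks, 7204 fruit drinks) refine them. Groups
overlap by design: one cola belongs at once to soft drinks, SSBs and both
caloric-beverage aggregates. "Caloric beverages, excluding milk" is
operationalized as every beverage-range subgroup (70-79) except diet
beverages (71) and waters (77, 78), and excluding the milk groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .nutrients import NUTRIENT_PANEL

logger = logging.getLogger(__name__)

BEVERAGE_GROUPS = (
    "milk",
    "flavored_milk",
    "milk_substitutes",
    "fruit_juice_100",
    "ssb",
    "soft_drinks",
    "fruit_drinks",
    "coffee_tea",
    "caloric_bev_excl_milk",
    "caloric_bev_incl_milk",
)

#: Beverage-range subgroup prefixes considered "caloric" (diet beverages 71
#: and plain/flavored waters 77, 78 are out).
CALORIC_BEV_PREFIXES = frozenset({70, 72, 73, 74, 75, 76, 79})
_BEVERAGE_RANGE = frozenset(range(70, 80))


@dataclass(frozen=True)
class CategoryRule:
    """Predicate over a 4-digit WWEIA code: prefix or exact-code match."""

    group: str
    prefixes: frozenset[int] = frozenset()
    codes: frozenset[int] = frozenset()
    exclude_prefixes: frozenset[int] = frozenset()
    exclude_codes: frozenset[int] = frozenset()

    def matches(self, wweia_code: int) -> bool:
        prefix = wweia_code // 100
        if prefix in self.exclude_prefixes or wweia_code in self.exclude_codes:
            return False
        return prefix in self.prefixes or wweia_code in self.codes


@dataclass(frozen=True)
class BeverageCategoryMap:
    """Ordered classification rules mapping WWEIA codes to beverage groups."""

    rules: tuple[CategoryRule, ...]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(r.group for r in self.rules)

    def rule(self, group: str) -> CategoryRule:
        for r in self.rules:
            if r.group == group:
                return r
        raise KeyError(group)

    def validate(self, probe_codes: Iterable[int] | None = None) -> None:
        """Check structural invariants on a probe set of codes.

        The milk groups must be pairwise disjoint; soft drinks and fruit
        drinks must sit inside SSBs; the including-milk aggregate must cover
        the excluding-milk aggregate plus all milk groups.
        """
        if probe_codes is None:
            probe_codes = range(1000, 10000)
        names = [r.group for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("duplicate group names in category map")
        have = set(names)
        need_nested = {"ssb", "soft_drinks", "fruit_drinks",
                       "caloric_bev_excl_milk", "caloric_bev_incl_milk",
                       "milk", "flavored_milk", "milk_substitutes"}
        if not need_nested <= have:
            return  # partial custom maps skip nesting checks
        for code in probe_codes:
            m = {g: self.rule(g).matches(code) for g in need_nested}
            if m["milk"] + m["flavored_milk"] + m["milk_substitutes"] > 1:
                raise ValueError(f"milk groups overlap on code {code}")
            if (m["soft_drinks"] or m["fruit_drinks"]) and not m["ssb"]:
                raise ValueError(f"soft/fruit drinks not nested in ssb on code {code}")
            incl = m["caloric_bev_excl_milk"] or m["milk"] or m["flavored_milk"] or m["milk_substitutes"]
            if incl and not m["caloric_bev_incl_milk"]:
                raise ValueError(f"including-milk aggregate fails to cover code {code}")


def default_category_map() -> BeverageCategoryMap:
    """The shipped 10-group map (subgroup prefixes + exact categories)."""
    return BeverageCategoryMap(rules=(
        CategoryRule("milk", prefixes=frozenset({10})),
        CategoryRule("flavored_milk", prefixes=frozenset({12})),
        CategoryRule("milk_substitutes", codes=frozenset({1404})),
        CategoryRule("fruit_juice_100", prefixes=frozenset({70})),
        CategoryRule("ssb", prefixes=frozenset({72})),
        CategoryRule("soft_drinks", codes=frozenset({7202})),
        CategoryRule("fruit_drinks", codes=frozenset({7204})),
        CategoryRule("coffee_tea", prefixes=frozenset({73})),
        CategoryRule("caloric_bev_excl_milk", prefixes=CALORIC_BEV_PREFIXES),
        CategoryRule("caloric_bev_incl_milk",
                     prefixes=CALORIC_BEV_PREFIXES | frozenset({10, 12}),
                     codes=frozenset({1404})),
    ))


def load_category_map(config: Mapping) -> BeverageCategoryMap:
    """Build a map from a TOML-style mapping: ``[[category_map.rules]]`` entries."""
    section = config.get("category_map", config)
    rules = []
    for entry in section["rules"]:
        rules.append(CategoryRule(
            group=entry["group"],
            prefixes=frozenset(entry.get("prefixes", ())),
            codes=frozenset(entry.get("codes", ())),
            exclude_prefixes=frozenset(entry.get("exclude_prefixes", ())),
            exclude_codes=frozenset(entry.get("exclude_codes", ())),
        ))
    return BeverageCategoryMap(rules=tuple(rules))


_warned_codes: set[int] = set()


def classify_item(wweia_code: int, cmap: BeverageCategoryMap | None = None) -> frozenset[str]:
    """All beverage groups whose predicate matches this WWEIA code.

    Non-beverage codes return the empty set. A code inside the caloric
    beverage range that no rule captures is logged once and returns empty.
    """
    cmap = cmap or default_category_map()
    code = int(wweia_code)
    if not 1000 <= code <= 9999:
        raise ValueError(f"WWEIA category code must have 4 digits, got {code}")
    groups = frozenset(r.group for r in cmap.rules if r.matches(code))
    if not groups and code // 100 in CALORIC_BEV_PREFIXES and code not in _warned_codes:
        _warned_codes.add(code)
        logger.warning("beverage-range WWEIA code %d matched no group", code)
    return groups


def group_membership(items: pd.DataFrame, cmap: BeverageCategoryMap | None = None) -> pd.DataFrame:
    """Boolean item-by-group membership frame (vectorized classify)."""
    cmap = cmap or default_category_map()
    codes = items["wweia_code"].to_numpy(dtype=int)
    prefixes = codes // 100
    out = {}
    for r in cmap.rules:
        m = np.isin(prefixes, list(r.prefixes)) | np.isin(codes, list(r.codes))
        if r.exclude_prefixes:
            m &= ~np.isin(prefixes, list(r.exclude_prefixes))
        if r.exclude_codes:
            m &= ~np.isin(codes, list(r.exclude_codes))
        out[r.group] = m
    return pd.DataFrame(out, index=items.index)


def apply_exclusions(subjects: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop ineligible subjects; return the kept frame and a tally by reason.

    Reasons are tested in fixed precedence — pregnancy/lactation first, then
    unreliable or incomplete recall, then age outside 6-18 y — so a subject
    failing several rules is counted once, under the first.
    """
    pregnant = subjects["pregnant_or_lactating"].to_numpy(dtype=bool)
    unreliable = ~subjects["recall_reliable"].to_numpy(dtype=bool)
    age = subjects["age_years"].to_numpy()
    bad_age = (age < 6) | (age > 18)
    reason = np.where(pregnant, "pregnant_or_lactating",
                      np.where(unreliable, "unreliable_recall",
                               np.where(bad_age, "age_out_of_range", "")))
    kept = subjects.loc[reason == ""].reset_index(drop=True)
    tally = {str(r): int(c)
             for r, c in zip(*np.unique(reason[reason != ""], return_counts=True))}
    return kept, tally


@dataclass(frozen=True)
class OccasionMap:
    """Meal-occasion codes that count as lunch or dinner.

    Defaults cover the English and Spanish recall labels: lunch = Lunch,
    Almuerzo; dinner = Dinner, Supper, Cena. Fully configurable.
    """

    lunch: frozenset[int] = frozenset({2, 11})
    dinner: frozenset[int] = frozenset({3, 4, 14})
    known: frozenset[int] = frozenset(range(1, 20))
    _warned: set = field(default_factory=set, compare=False, repr=False)

    @property
    def meal_codes(self) -> frozenset[int]:
        return self.lunch | self.dinner

    def is_meal(self, occasion_code: int) -> bool:
        code = int(occasion_code)
        if code not in self.known and code not in self._warned:
            self._warned.add(code)
            logger.warning("unknown occasion code %d treated as non-meal", code)
        return code in self.meal_codes


def load_occasion_map(config: Mapping) -> OccasionMap:
    section = config.get("occasion_map", config)
    kwargs = {}
    for key in ("lunch", "dinner", "known"):
        if key in section:
            kwargs[key] = frozenset(int(c) for c in section[key])
    return OccasionMap(**kwargs)


def is_meal_beverage(item: Mapping, omap: OccasionMap | None = None,
                     cmap: BeverageCategoryMap | None = None,
                     group: str = "caloric_bev_excl_milk") -> bool:
    """True iff the item is a caloric beverage of ``group`` consumed at lunch or dinner.

    "Caloric" requires strictly positive energy, so zero-kcal diet drinks at
    meals are never replacement candidates.
    """
    omap = omap or OccasionMap()
    if not omap.is_meal(int(item["occasion_code"])):
        return False
    if float(item["energy"]) <= 0:
        return False
    return group in classify_item(int(item["wweia_code"]), cmap)


def meal_beverage_mask(items: pd.DataFrame, omap: OccasionMap | None = None,
                       cmap: BeverageCategoryMap | None = None,
                       group: str = "caloric_bev_excl_milk") -> np.ndarray:
    """Vectorized :func:`is_meal_beverage` over an item table."""
    omap = omap or OccasionMap()
    member = group_membership(items, cmap)[group].to_numpy()
    at_meal = items["occasion_code"].astype(int).isin(omap.meal_codes).to_numpy()
    caloric = items["energy"].to_numpy() > 0
    return member & at_meal & caloric


def per_subject_category_intake(items: pd.DataFrame,
                                subject_ids: Iterable[str],
                                cmap: BeverageCategoryMap | None = None) -> pd.DataFrame:
    """Daily grams and nutrients per subject per beverage group.

    Every subject in ``subject_ids`` gets a row for every group, zero-filled
    when nothing was consumed, so per-capita means average consumers and
    nonconsumers alike. Columns are a (group, field) MultiIndex with field
    in ``('grams',) + NUTRIENT_PANEL``.
    """
    cmap = cmap or default_category_map()
    index = pd.Index([str(s) for s in subject_ids], name="subject_id")
    fields = ("grams",) + NUTRIENT_PANEL
    membership = group_membership(items, cmap) if len(items) else None
    blocks = {}
    for r in cmap.rules:
        if len(items) == 0:
            agg = pd.DataFrame(0.0, index=index, columns=list(fields))
        else:
            sub = items.loc[membership[r.group].to_numpy(), ["subject_id", *fields]]
            agg = (sub.groupby("subject_id")[list(fields)].sum()
                   .reindex(index, fill_value=0.0))
        for f in fields:
            blocks[(r.group, f)] = agg[f].astype(float)
    out = pd.DataFrame(blocks, index=index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "field"])
    return out


def classification_audit(items: pd.DataFrame,
                         cmap: BeverageCategoryMap | None = None) -> pd.DataFrame:
    """Item counts and total grams per beverage group (audit log)."""
    cmap = cmap or default_category_map()
    if len(items) == 0:
        return pd.DataFrame({"group": list(cmap.groups), "n_items": 0, "total_grams": 0.0})
    member = group_membership(items, cmap)
    rows = [{"group": g,
             "n_items": int(member[g].sum()),
             "total_grams": float(items.loc[member[g].to_numpy(), "grams"].sum())}
            for g in cmap.groups]
    return pd.DataFrame(rows)
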