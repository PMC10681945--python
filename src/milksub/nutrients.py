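"""Fixed 18-nutrient panel, nutrient vectors, and the milk-NFS profile.

The package tracks a fixed panel of 18 nutrients for every food item and
every modeled diet: energy plus the macro- and micronutrients most relevant
to child beverage intake (calcium, potassium, vitamin D and added sugars in
particular). Added sugars are carried in USDA teaspoon equivalents
end-to-end; a gram conversion constant is exposed for reporting only and is
never used in intake arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Panel order is fixed; all tables and vectors use exactly these names.
NUTRIENT_PANEL: tuple[str, ...] = (
    "energy",
    "carbohydrate",
    "dietary_fiber",
    "total_sugars",
    "added_sugars",
    "protein",
    "total_fat",
    "mufa",
    "pufa",
    "sfa",
    "calcium",
    "magnesium",
    "potassium",
    "sodium",
    "vitamin_a_re",
    "folate_dfe",
    "vitamin_b12",
    "vitamin_d",
)

NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kcal",
    "carbohydrate": "g",
    "dietary_fiber": "g",
    "total_sugars": "g",
    "added_sugars": "tsp eq",
    "protein": "g",
    "total_fat": "g",
    "mufa": "g",
    "pufa": "g",
    "sfa": "g",
    "calcium": "mg",
    "magnesium": "mg",
    "potassium": "mg",
    "sodium": "mg",
    "vitamin_a_re": "ug RE",
    "folate_dfe": "ug DFE",
    "vitamin_b12": "ug",
    "vitamin_d": "ug",
}

#: Reporting convention for translating teaspoon equivalents of added sugar
#: into grams. Used only for cross-checks and display, never internally.
GRAMS_ADDED_SUGAR_PER_TSP = 4.2

#: Individual fatty-acid classes may slightly exceed total fat in published
#: nutrient databases because components are rounded independently.
_FAT_ROUNDING_SLACK = 1.05

_INDEX = {name: i for i, name in enumerate(NUTRIENT_PANEL)}


class NutrientVector:
    """An 18-component nutrient amount, in panel order and panel units.

    Supports componentwise addition/subtraction and scalar multiplication,
    which is all the substitution arithmetic needs.
    """

    __slots__ = ("values",)

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float)
        if arr.shape != (len(NUTRIENT_PANEL),):
            raise ValueError(
                f"expected {len(NUTRIENT_PANEL)} nutrient components, got shape {arr.shape}"
            )
        self.values = arr

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "NutrientVector":
        missing = [n for n in NUTRIENT_PANEL if n not in mapping]
        if missing:
            raise ValueError(f"nutrient mapping missing components: {missing}")
        return cls([float(mapping[n]) for n in NUTRIENT_PANEL])

    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls(np.zeros(len(NUTRIENT_PANEL)))

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[_INDEX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return float(self.values[_INDEX[name]])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(NUTRIENT_PANEL, self.values)}

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values + other.values)

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values - other.values)

    def __mul__(self, scalar: float) -> "NutrientVector":
        return NutrientVector(self.values * float(scalar))

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NutrientVector) and bool(
            np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{n}={v:g}" for n, v in zip(NUTRIENT_PANEL, self.values))
        return f"NutrientVector({parts})"

    def validate(self, *, tsp_grams: float = GRAMS_ADDED_SUGAR_PER_TSP) -> None:
        """Check panel invariants; raise ``ValueError`` on violation.

        All components must be nonnegative; each fatty-acid class may not
        exceed total fat by more than database rounding slack; added sugars
        (converted to grams) may not exceed total sugars.
        """
        v = self.values
        if np.any(v < 0):
            bad = [n for n, x in zip(NUTRIENT_PANEL, v) if x < 0]
            raise ValueError(f"negative nutrient components: {bad}")
        fat = self.total_fat
        for fa in ("mufa", "pufa", "sfa"):
            if self[fa] > fat * _FAT_ROUNDING_SLACK + 1e-12:
                raise ValueError(f"{fa} ({self[fa]}) exceeds total fat ({fat}) beyond rounding slack")
        if self.added_sugars * tsp_grams > self.total_sugars * (1 + 1e-9) + 1e-9:
            raise ValueError(
                f"added sugars ({self.added_sugars} tsp eq = "
                f"{self.added_sugars * tsp_grams:g} g) exceed total sugars ({self.total_sugars} g)"
            )


@dataclass(frozen=True)
class MilkProfile:
    """Nutrient content of fluid milk, NFS (a blend over fat levels).

    ``per_cup`` is the nutrient content of one cup-equivalent serving and
    drives the add-a-serving model; ``per_kcal`` (derived) drives isocaloric
    replacement. ``grams_per_cup`` is used only to express replacement
    volumes in cup equivalents, never in energy arithmetic.
    """

    per_cup: NutrientVector
    grams_per_cup: float = 244.0
    per_kcal: NutrientVector = field(init=False)

    def __post_init__(self) -> None:
        if self.per_cup.energy <= 0:
            raise ValueError("milk profile per-cup energy must be positive")
        if self.per_cup.added_sugars != 0:
            raise ValueError("milk NFS carries no added sugars")
        self.per_cup.validate()
        scaled = self.per_cup.values / self.per_cup.energy
        scaled[_INDEX["energy"]] = 1.0  # exact by construction
        object.__setattr__(self, "per_kcal", NutrientVector(scaled))


#: One cup of milk, NFS: each component is the across-age-group average of
#: the adjusted-minus-baseline differences the add-a-serving model produces,
#: which pins the profile to three independent printed-table cross-checks
#: per nutrient.
DEFAULT_MILK_PER_CUP: dict[str, float] = {
    "energy": 122.0,
    "carbohydrate": 12.0,
    "dietary_fiber": 0.0,
    "total_sugars": 12.3,
    "added_sugars": 0.0,
    "protein": 8.07,
    "total_fat": 4.8,
    "mufa": 1.3,
    "pufa": 0.23,
    "sfa": 2.9,
    "calcium": 290.3,
    "magnesium": 27.3,
    "potassium": 358.0,
    "sodium": 103.0,
    "vitamin_a_re": 123.7,
    "folate_dfe": 11.3,
    "vitamin_b12": 1.14,
    "vitamin_d": 2.99,
}


def default_milk_profile() -> MilkProfile:
    """The shipped milk-NFS profile (see ``DEFAULT_MILK_PER_CUP``)."""
    return MilkProfile(per_cup=NutrientVector.from_mapping(DEFAULT_MILK_PER_CUP))
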