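"""Editable scoring standards for the two diet-quality indexes.

The adapted index keeps 10 density-scored components summing to 75
points (the seafood/plant-protein and grain components are dropped, as
the underlying food databases cannot separate them). The national-
guideline index has 7 components of 10 points each (70 total) with
sex- and age-specific portion recommendations.

Both tables are plain dataclasses with CSV round-tripping so that a
different component set can be dropped in without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

# Portion constants
CUP_G = 250.0
OZ_G = 28.25
OZ_ML = 29.57

ADEQUACY = "adequacy"
MODERATION = "moderation"


@dataclass(frozen=True)
class ComponentStandard:
    """Density cutpoints for one scored component.

    Adequacy components score linearly from ``density_for_zero``
    (default 0) up to full points at ``density_for_max``. Moderation
    components are reverse-scored: full points at or below
    ``density_for_max``, zero at or beyond ``density_for_zero``.
    """

    name: str
    kind: str
    unit: str
    max_points: float
    density_for_max: float
    density_for_zero: float = 0.0

    def __post_init__(self):
        if self.kind not in (ADEQUACY, MODERATION):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.max_points <= 0:
            raise ValueError("max_points must be > 0")
        if self.kind == MODERATION and self.density_for_zero <= self.density_for_max:
            raise ValueError("moderation requires density_for_zero > density_for_max")

    def score(self, density: float) -> float:
        lo, hi = self.density_for_zero, self.density_for_max
        if self.kind == ADEQUACY:
            if hi == lo:
                return self.max_points if density >= hi else 0.0
            frac = (density - lo) / (hi - lo)
        else:
            frac = (lo - density) / (lo - hi)
        return self.max_points * min(1.0, max(0.0, frac))


# Density cutpoints per 1000 kcal (cup-eq, oz-eq, grams, % energy or
# fatty-acid ratio, as labelled). 5+5+5+5+10+5+10+10+10+10 = 75.
DEFAULT_HEI_COMPONENTS = [
    ComponentStandard("total_fruits", ADEQUACY, "cup_eq", 5.0, 0.8),
    ComponentStandard("whole_fruits", ADEQUACY, "cup_eq", 5.0, 0.4),
    ComponentStandard("total_vegetables", ADEQUACY, "cup_eq", 5.0, 1.1),
    ComponentStandard("greens_and_beans", ADEQUACY, "cup_eq", 5.0, 0.2),
    ComponentStandard("dairy", ADEQUACY, "cup_eq", 10.0, 1.3),
    ComponentStandard("total_protein_foods", ADEQUACY, "oz_eq", 5.0, 2.5),
    ComponentStandard("fatty_acids", ADEQUACY, "ratio", 10.0, 2.5, 1.2),
    ComponentStandard("sodium", MODERATION, "g", 10.0, 1.1, 2.0),
    ComponentStandard("added_sugars", MODERATION, "pct_energy", 10.0, 6.5, 26.0),
    ComponentStandard("saturated_fats", MODERATION, "pct_energy", 10.0, 8.0, 16.0),
]


@dataclass(frozen=True)
class HEIStandards:
    components: tuple[ComponentStandard, ...] = tuple(DEFAULT_HEI_COMPONENTS)
    cup_g: float = CUP_G
    oz_g: float = OZ_G
    oz_ml: float = OZ_ML

    def __post_init__(self):
        total = sum(c.max_points for c in self.components)
        if abs(total - 75.0) > 1e-9:
            raise ValueError(f"component max points sum to {total}, expected 75")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")

    @property
    def max_score(self) -> float:
        return sum(c.max_points for c in self.components)

    def component(self, name: str) -> ComponentStandard:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "component": c.name,
                    "kind": c.kind,
                    "unit": c.unit,
                    "max_points": c.max_points,
                    "density_for_max": c.density_for_max,
                    "density_for_zero": c.density_for_zero,
                }
                for c in self.components
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HEIStandards":
        df = pd.read_csv(path)
        comps = tuple(
            ComponentStandard(
                name=r.component,
                kind=r.kind,
                unit=r.unit,
                max_points=float(r.max_points),
                density_for_max=float(r.density_for_max),
                density_for_zero=float(r.density_for_zero),
            )
            for r in df.itertuples(index=False)
        )
        return cls(components=comps)


# Reference daily energy requirements used to convert recommended
# portions/day into portions per 1000 kcal.
REFERENCE_KCAL = {"male": 2650.0, "female": 2100.0}

GABA_COMPONENTS = [
    "dairy",
    "meats_eggs",
    "fruits",
    "vegetables",
    "beans_nuts",
    "cereals_tubers",
    "fiber",
]

# grams per portion; fiber is scored in grams directly
DEFAULT_GRAMS_PER_PORTION = {
    "dairy": 200.0,
    "meats_eggs": 90.0,
    "fruits": 120.0,
    "vegetables": 80.0,
    "beans_nuts": 50.0,
    "cereals_tubers": 80.0,
    "fiber": 1.0,
}

# recommended portions/day by (sex, age_group)
DEFAULT_RECOMMENDED_PORTIONS = {
    ("male", "18-40"): {
        "dairy": 3.0, "meats_eggs": 3.5, "fruits": 4.0, "vegetables": 3.0,
        "beans_nuts": 2.0, "cereals_tubers": 6.5, "fiber": 36.0,
    },
    ("male", "41-62"): {
        "dairy": 3.0, "meats_eggs": 3.0, "fruits": 4.0, "vegetables": 3.0,
        "beans_nuts": 2.0, "cereals_tubers": 6.0, "fiber": 34.0,
    },
    ("female", "18-40"): {
        "dairy": 3.0, "meats_eggs": 2.5, "fruits": 3.5, "vegetables": 2.5,
        "beans_nuts": 1.5, "cereals_tubers": 5.0, "fiber": 28.0,
    },
    ("female", "41-62"): {
        "dairy": 3.0, "meats_eggs": 2.5, "fruits": 3.5, "vegetables": 2.5,
        "beans_nuts": 1.5, "cereals_tubers": 4.5, "fiber": 26.0,
    },
}


@dataclass(frozen=True)
class GABAStandards:
    """7-component portion-based standards, 10 points each (70 total)."""

    grams_per_portion: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_GRAMS_PER_PORTION.items()
    )
    recommended_portions: tuple = tuple(
        (sex_age, tuple(v.items()))
        for sex_age, v in DEFAULT_RECOMMENDED_PORTIONS.items()
    )
    max_points_per_component: float = 10.0
    reference_kcal: tuple[tuple[str, float], ...] = tuple(REFERENCE_KCAL.items())

    def __post_init__(self):
        if abs(self.max_score - 70.0) > 1e-9:
            raise ValueError("component max points must sum to 70")

    @property
    def components(self) -> list[str]:
        return [name for name, _ in self.grams_per_portion]

    @property
    def max_score(self) -> float:
        return self.max_points_per_component * len(self.grams_per_portion)

    def portion_grams(self, component: str) -> float:
        return dict(self.grams_per_portion)[component]

    def recommendation(self, sex: str, age_group: str) -> dict[str, float]:
        table = {k: dict(v) for k, v in self.recommended_portions}
        try:
            return table[(sex, age_group)]
        except KeyError as exc:
            raise KeyError(
                f"no portion recommendations for sex={sex!r}, age_group={age_group!r}"
            ) from exc

    def ref_kcal(self, sex: str) -> float:
        return dict(self.reference_kcal)[sex]

    def to_csv(self, path) -> None:
        rows = []
        for (sex, age), recs in self.recommended_portions:
            for comp, portions in recs:
                rows.append(
                    {
                        "component": comp,
                        "sex": sex,
                        "age_group": age,
                        "grams_per_portion": self.portion_grams(comp),
                        "recommended_portions": portions,
                        "max_points": self.max_points_per_component,
                        "reference_kcal": self.ref_kcal(sex),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GABAStandards":
        df = pd.read_csv(path)
        gpp = tuple(
            df.drop_duplicates("component")[["component", "grams_per_portion"]]
            .itertuples(index=False, name=None)
        )
        recs = {}
        for r in df.itertuples(index=False):
            recs.setdefault((r.sex, r.age_group), {})[r.component] = float(
                r.recommended_portions
            )
        ref = tuple(
            df.drop_duplicates("sex")[["sex", "reference_kcal"]]
            .itertuples(index=False, name=None)
        )
        max_pts = float(df["max_points"].iloc[0])
        return cls(
            grams_per_portion=gpp,
            recommended_portions=tuple(
                (k, tuple(v.items())) for k, v in recs.items()
            ),
            max_points_per_component=max_pts,
            reference_kcal=ref,
        )
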