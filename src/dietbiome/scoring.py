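"""Diet-quality measures: adapted 75-point index, 70-point guideline
index, ultraprocessed-calorie percentage, and macronutrient-range
classification.

Scores are density-based: intakes are first converted to portions (or
% of energy) per 1000 kcal, which makes every index invariant to the
overall amount eaten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standards import ADEQUACY, GABAStandards, HEIStandards

AMDR_RANGES = {
    "carbohydrate": (50.0, 65.0),
    "protein": (14.0, 20.0),
    "fat": (20.0, 35.0),
}


class UndefinedDensityError(ValueError):
    """Raised when a per-1000-kcal density is requested at kcal <= 0."""


def component_density(
    grams: dict[str, float], grams_per_portion: dict[str, float], kcal: float
) -> dict[str, float]:
    """Portions consumed per 1000 kcal for each component.

    density_c = (grams_c / grams_per_portion_c) / (kcal / 1000)
    """
    if kcal <= 0:
        raise UndefinedDensityError("kcal must be > 0 to form densities")
    per_1000 = kcal / 1000.0
    return {
        c: (grams.get(c, 0.0) / grams_per_portion[c]) / per_1000
        for c in grams_per_portion
    }


def score_adapted_hei(
    densities: dict[str, float], standards: HEIStandards | None = None
) -> tuple[float, dict[str, float]]:
    """Score per-1000-kcal densities against the adapted 75-point index.

    ``densities`` maps component name -> density in that component's unit
    (cup-eq or oz-eq per 1000 kcal, % energy, grams/1000 kcal, or the
    (MUFA+PUFA)/SFA ratio). Missing components score as their worst case
    (0 for adequacy, full points for moderation at zero intake).
    Returns ``(total, per-component partial scores)``.
    """
    standards = standards or HEIStandards()
    known = {c.name for c in standards.components}
    unknown = set(densities) - known
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    partial = {
        c.name: c.score(float(densities.get(c.name, 0.0)))
        for c in standards.components
    }
    return sum(partial.values()), partial


def score_gaba(
    group_grams: dict[str, float],
    kcal: float,
    sex: str,
    age_group: str,
    standards: GABAStandards | None = None,
) -> tuple[float, dict[str, float]]:
    """Score component grams against sex/age portion recommendations.

    Each of the 7 components contributes up to 10 points, linearly in
    the ratio of consumed to recommended portion density (per 1000 kcal),
    capped at the component maximum.
    """
    standards = standards or GABAStandards()
    if kcal <= 0:
        raise UndefinedDensityError("kcal must be > 0")
    recs = standards.recommendation(sex, age_group)
    ref_per_1000 = standards.ref_kcal(sex) / 1000.0
    per_1000 = kcal / 1000.0
    partial = {}
    for comp in standards.components:
        gpp = standards.portion_grams(comp)
        density = (group_grams.get(comp, 0.0) / gpp) / per_1000
        rec_density = recs[comp] / ref_per_1000
        frac = min(1.0, max(0.0, density / rec_density))
        partial[comp] = standards.max_points_per_component * frac
    return sum(partial.values()), partial


def upf_percentage(
    item_kcal: pd.DataFrame,
    db: pd.DataFrame,
    ambiguous_policy: str = "as_upf",
) -> float:
    """Percent of calories from ultraprocessed items.

    ``item_kcal`` needs columns ``item_id`` and ``kcal``. Items whose
    ultraprocessed status is ambiguous count as ultraprocessed under
    ``as_upf`` (the primary policy) and as not under ``as_not_upf``
    (the sensitivity analysis).
    """
    if ambiguous_policy not in {"as_upf", "as_not_upf"}:
        raise ValueError(f"unknown policy {ambiguous_policy!r}")
    status = db.set_index("item_id")["upf_status"]
    missing = set(item_kcal["item_id"]) - set(status.index)
    if missing:
        raise KeyError(f"items not in food database: {sorted(missing)[:5]}")
    total = float(item_kcal["kcal"].sum())
    if total <= 0:
        raise UndefinedDensityError("total kcal must be > 0")
    st = status.loc[item_kcal["item_id"]].to_numpy()
    is_upf = st == "ultraprocessed"
    if ambiguous_policy == "as_upf":
        is_upf |= st == "ambiguous"
    return 100.0 * float(item_kcal["kcal"].to_numpy()[is_upf].sum()) / total


@dataclass(frozen=True)
class AMDRResult:
    acceptable: bool
    shares: dict[str, float]
    flags: dict[str, str]  # low / ok / high per macronutrient


def amdr_classify(carb_g: float, protein_g: float, fat_g: float) -> AMDRResult:
    """Classify a macronutrient split against the acceptable ranges.

    Energy shares use 4/4/9 kcal per gram over the macronutrient energy
    total; acceptable iff carbohydrate in [50,65]%, protein in [14,20]%
    and fat in [20,35]% (closed intervals).
    """
    if min(carb_g, protein_g, fat_g) < 0:
        raise ValueError("intakes must be non-negative")
    energy = {
        "carbohydrate": 4.0 * carb_g,
        "protein": 4.0 * protein_g,
        "fat": 9.0 * fat_g,
    }
    total = sum(energy.values())
    if total <= 0:
        raise UndefinedDensityError("zero macronutrient energy")
    shares = {k: 100.0 * v / total for k, v in energy.items()}
    flags = {}
    for k, (lo, hi) in AMDR_RANGES.items():
        s = shares[k]
        flags[k] = "low" if s < lo else ("high" if s > hi else "ok")
    return AMDRResult(
        acceptable=all(f == "ok" for f in flags.values()), shares=shares, flags=flags
    )


# ---------------------------------------------------------------------------
# cohort-level scoring from recalls

# how the 11 food groups feed the adapted index components; fractions
# split groups that map to more than one component
_HEI_GROUP_MAP = {
    "total_fruits": [("fruits", 1.0)],
    "whole_fruits": [("fruits", 0.5)],
    "total_vegetables": [("vegetables", 1.0)],
    "greens_and_beans": [("beans", 1.0)],
    "dairy": [("dairy", 1.0)],
    "total_protein_foods": [("meats", 1.0), ("eggs", 1.0), ("beans", 1.0), ("nuts", 1.0)],
}

_GABA_GROUP_MAP = {
    "dairy": ["dairy"],
    "meats_eggs": ["meats", "eggs"],
    "fruits": ["fruits"],
    "vegetables": ["vegetables"],
    "beans_nuts": ["beans", "nuts"],
    "cereals_tubers": ["cereals", "tubers"],
}


def hei_inputs(
    group_grams: dict[str, float],
    nutrients: dict[str, float],
    kcal: float,
    group_kcal: dict[str, float] | None = None,
    standards: HEIStandards | None = None,
) -> dict[str, float]:
    """Derive adapted-index component densities from food-group grams
    and nutrient totals of one day.

    Cup/ounce equivalents use the configured portion constants; added
    sugars are approximated by the calorie share of the sugars food
    group; sodium density is g per 1000 kcal.
    """
    standards = standards or HEIStandards()
    if kcal <= 0:
        raise UndefinedDensityError("kcal must be > 0")
    per_1000 = kcal / 1000.0
    dens: dict[str, float] = {}
    for comp, parts in _HEI_GROUP_MAP.items():
        grams = sum(group_grams.get(g, 0.0) * w for g, w in parts)
        portion = standards.oz_g if standards.component(comp).unit == "oz_eq" else standards.cup_g
        dens[comp] = (grams / portion) / per_1000
    sfa = nutrients.get("sfa_g", 0.0)
    mufa = nutrients.get("mufa_g", 0.0)
    pufa = nutrients.get("pufa_g", 0.0)
    dens["fatty_acids"] = (mufa + pufa) / sfa if sfa > 0 else standards.component("fatty_acids").density_for_max
    dens["sodium"] = (nutrients.get("sodium_mg", 0.0) / 1000.0) / per_1000
    dens["saturated_fats"] = 100.0 * 9.0 * sfa / kcal
    if group_kcal is not None:
        dens["added_sugars"] = 100.0 * group_kcal.get("sugars", 0.0) / kcal
    else:
        dens["added_sugars"] = 0.0
    return dens


def gaba_inputs(group_grams: dict[str, float], nutrients: dict[str, float]) -> dict[str, float]:
    """Map 11 food groups + fiber onto the 7 guideline components."""
    out = {
        comp: sum(group_grams.get(g, 0.0) for g in groups)
        for comp, groups in _GABA_GROUP_MAP.items()
    }
    out["fiber"] = nutrients.get("fiber_g", 0.0)
    return out


def score_cohort(
    recalls: pd.DataFrame,
    db: pd.DataFrame,
    covariates: pd.DataFrame,
    hei_standards: HEIStandards | None = None,
    gaba_standards: GABAStandards | None = None,
    ambiguous_policy: str = "as_upf",
) -> pd.DataFrame:
    """Per-person diet quality (day-1 recall): adapted index, guideline
    index and % calories from ultraprocessed food.
    """
    from .intake import aggregate_food_groups, attach_item_energy, compute_nutrients

    hei_standards = hei_standards or HEIStandards()
    gaba_standards = gaba_standards or GABAStandards()
    day1 = recalls[recalls["day"] == 1]
    groups = aggregate_food_groups(day1, db).set_index("person_id")
    nutr = compute_nutrients(day1, db).set_index("person_id")
    items = attach_item_energy(day1, db)
    meta = covariates.set_index("person_id")

    group_kcal = (
        items.merge(db[["item_id", "food_group"]], on="item_id")
        .groupby(["person_id", "food_group"])["kcal"]
        .sum()
    )

    rows = []
    for pid in covariates["person_id"]:
        if pid not in nutr.index:
            continue
        nrow = nutr.loc[pid].to_dict()
        grow = groups.loc[pid].to_dict()
        kcal = nrow["kcal"]
        gk = group_kcal.loc[pid].to_dict() if pid in group_kcal.index.get_level_values(0) else {}
        hei, _ = score_adapted_hei(
            hei_inputs(grow, nrow, kcal, gk, hei_standards), hei_standards
        )
        gaba, _ = score_gaba(
            gaba_inputs(grow, nrow),
            kcal,
            meta.loc[pid, "sex"],
            meta.loc[pid, "age_group"],
            gaba_standards,
        )
        upf = upf_percentage(
            items[items["person_id"] == pid], db, ambiguous_policy
        )
        amdr = amdr_classify(
            nrow.get("carbohydrate_g", 0.0),
            nrow.get("protein_g", 0.0),
            nrow.get("fat_g", 0.0),
        )
        rows.append(
            {
                "person_id": pid,
                "hei": hei,
                "gaba": gaba,
                "upf_pct": upf,
                "amdr_acceptable": amdr.acceptable,
            }
        )
    return pd.DataFrame(rows)
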