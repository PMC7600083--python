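"""Food-group aggregation, nutrient computation and usual-intake BLUPs.

Daily intakes come straight from the recall records and the composition
table. Usual intakes shrink each person's mean toward the cohort mean
with a one-way random-effects BLUP whose variance components are the
unbalanced method-of-moments (ANOVA) estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FOOD_GROUPS

NUTRIENT_COLUMNS = [
    "kcal",
    "carbohydrate_g",
    "protein_g",
    "fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "fiber_g",
    "cholesterol_mg",
    "sodium_mg",
    "calcium_mg",
    "potassium_mg",
    "magnesium_mg",
    "zinc_mg",
    "vitamin_c_mg",
    "folate_ug",
]


class ItemLookupError(KeyError):
    """A recall references items absent from the food database."""

    def __init__(self, items):
        self.items = sorted(items)
        super().__init__(f"items not in food database: {self.items[:10]}")


def _check_items(recalls: pd.DataFrame, db: pd.DataFrame) -> None:
    missing = set(recalls["item_id"]) - set(db["item_id"])
    if missing:
        raise ItemLookupError(missing)


def aggregate_food_groups(recalls: pd.DataFrame, db: pd.DataFrame) -> pd.DataFrame:
    """Per person-day grams by the 11 food groups (total mass conserved)."""
    _check_items(recalls, db)
    merged = recalls.merge(db[["item_id", "food_group"]], on="item_id")
    wide = (
        merged.pivot_table(
            index=["person_id", "day"],
            columns="food_group",
            values="grams",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=FOOD_GROUPS, fill_value=0.0)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def attach_item_energy(recalls: pd.DataFrame, db: pd.DataFrame) -> pd.DataFrame:
    """Recall records with per-record kcal from the composition table."""
    _check_items(recalls, db)
    kcal100 = db.set_index("item_id")["kcal"]
    merged = recalls.copy()
    merged["kcal"] = (
        merged["grams"].to_numpy() / 100.0 * kcal100.loc[merged["item_id"]].to_numpy()
    )
    return merged


def compute_nutrients(
    recalls: pd.DataFrame,
    db: pd.DataFrame,
    nutrients: list[str] | None = None,
) -> pd.DataFrame:
    """Per person-day nutrient totals: sum of grams/100 * composition."""
    _check_items(recalls, db)
    nutrients = nutrients or [c for c in NUTRIENT_COLUMNS if c in db.columns]
    missing_cols = [c for c in nutrients if c not in db.columns]
    if missing_cols:
        raise KeyError(f"composition table lacks nutrient columns: {missing_cols}")
    comp = db.set_index("item_id")[nutrients]
    merged = recalls.merge(comp, left_on="item_id", right_index=True)
    for c in nutrients:
        merged[c] = merged["grams"] / 100.0 * merged[c]
    out = (
        merged.groupby(["person_id", "day"], as_index=False)[nutrients]
        .sum()
        .sort_values(["person_id", "day"], ignore_index=True)
    )
    return out


class IdentifiabilityError(ValueError):
    """No person has repeated recalls: variance components cannot be
    separated. Re-run with ``transform='none'`` on person means
    (pass-through) or supply repeat days."""


@dataclass
class BlupModel:
    """Fitted one-way random-effects model for one nutrient."""

    nutrient: str
    grand_mean: float
    sigma2_between: float
    sigma2_within: float
    transform: str

    @property
    def lam(self):  # shrinkage at n_i = 1, for reference
        denom = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / denom if denom > 0 else 0.0


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log1p":
        return np.log1p(x)
    if transform == "none":
        return x
    raise ValueError(f"unknown transform {transform!r}")


def _back_transform(x: np.ndarray, transform: str) -> np.ndarray:
    return np.expm1(x) if transform == "log1p" else x


def estimate_blup(
    daily: pd.DataFrame,
    value_col: str,
    transform: str = "log1p",
) -> tuple[pd.DataFrame, BlupModel]:
    """Usual-intake BLUPs for one nutrient.

    Fits x_ij = mu + b_i + e_ij on the transformed scale. Variance
    components use the unbalanced one-way ANOVA estimators with
    Searle's n0 = (N - sum n_i^2 / N) / (a - 1); a negative
    between-person estimate is clamped to 0. Each person's BLUP is
    mu + lambda_i (xbar_i - mu) with lambda_i = s2_b / (s2_b + s2_w/n_i),
    then back-transformed. Persons with one recall shrink via the
    cohort-level components.
    """
    df = daily[["person_id", value_col]].dropna()
    y = _transform(df[value_col].to_numpy(dtype=float), transform)
    df = df.assign(_y=y)
    groups = df.groupby("person_id")["_y"]
    n_i = groups.size()
    a = len(n_i)
    N = int(n_i.sum())
    if a < 2:
        raise ValueError("need >= 2 persons")
    if (n_i > 1).sum() == 0:
        raise IdentifiabilityError(IdentifiabilityError.__doc__)

    means = groups.mean()
    grand = float(df["_y"].mean())
    ssw = float(((df["_y"] - df["person_id"].map(means)) ** 2).sum())
    ssb = float((n_i * (means - grand) ** 2).sum())
    msw = ssw / (N - a) if N > a else 0.0
    msb = ssb / (a - 1)
    n0 = (N - float((n_i**2).sum()) / N) / (a - 1)
    s2_b = max(0.0, (msb - msw) / n0)
    s2_w = msw

    denom = s2_b + s2_w / n_i
    lam = np.where(denom > 0, s2_b / denom, 0.0)
    blup_t = grand + lam * (means - grand)
    out = pd.DataFrame(
        {
            "person_id": means.index,
            "n_recalls": n_i.to_numpy(),
            "blup": _back_transform(blup_t.to_numpy(), transform),
            "blup_transformed": blup_t.to_numpy(),
            "person_mean_transformed": means.to_numpy(),
            "lambda": lam,
        }
    ).reset_index(drop=True)
    model = BlupModel(
        nutrient=value_col,
        grand_mean=grand,
        sigma2_between=s2_b,
        sigma2_within=s2_w,
        transform=transform,
    )
    return out, model


def estimate_usual_intakes(
    daily: pd.DataFrame,
    nutrients: list[str] | None = None,
    transform: str = "log1p",
) -> tuple[pd.DataFrame, dict[str, BlupModel]]:
    """BLUP usual intakes for every nutrient column; wide output."""
    nutrients = nutrients or [
        c for c in daily.columns if c not in ("person_id", "day")
    ]
    models: dict[str, BlupModel] = {}
    merged: pd.DataFrame | None = None
    for nut in nutrients:
        table, model = estimate_blup(daily, nut, transform)
        models[nut] = model
        col = table[["person_id", "blup"]].rename(columns={"blup": nut})
        merged = col if merged is None else merged.merge(col, on="person_id")
    return merged, models


def micronutrient_adequacy(
    usual: pd.DataFrame,
    requirements: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Classify usual intake per nutrient as deficient/adequate/excess.

    ``requirements`` columns: nutrient, sex, lower, upper (upper may be
    NaN for no upper bound). Cutoffs are sex-specific, so the same
    intake can be deficient for one sex and in excess for the other.
    """
    req = requirements.set_index(["nutrient", "sex"])
    sex = covariates.set_index("person_id")["sex"]
    nutrients = [c for c in usual.columns if c != "person_id"]
    rows = []
    for r in usual.itertuples(index=False):
        pid = r.person_id
        for nut in nutrients:
            key = (nut, sex.loc[pid])
            if key not in req.index:
                raise KeyError(f"no requirement row for {key}")
            lower = float(req.loc[key, "lower"])
            upper = req.loc[key, "upper"]
            val = getattr(r, nut)
            if val < lower:
                label = "deficient"
            elif pd.notna(upper) and val > float(upper):
                label = "excess"
            else:
                label = "adequate"
            rows.append({"person_id": pid, "nutrient": nut, "status": label})
    return pd.DataFrame(rows)
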