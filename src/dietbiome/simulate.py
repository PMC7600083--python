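"""Synthetic cohorts with planted diet->microbiota effects.

Generates the four inputs the analysis pipeline consumes — covariates,
a food database, 24-h recall records and an OTU table + tree — with
configurable planted effects so that every downstream stage has a
ground-truth recovery test.

All randomness flows from one master seed: each generator derives its
own child stream via ``numpy.random.SeedSequence(seed).spawn`` so that
the same (seed, config) pair is byte-reproducible and generators do not
perturb each other's streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import TreeNode, write_newick

CITIES = ["bogota", "medellin", "cali", "barranquilla", "bucaramanga"]
SEXES = ["male", "female"]
AGE_GROUPS = ["18-40", "41-62"]
BMI_CLASSES = ["lean", "overweight", "obese"]
FOOD_GROUPS = [
    "dairy",
    "meats",
    "eggs",
    "beans",
    "nuts",
    "fruits",
    "vegetables",
    "cereals",
    "tubers",
    "fats",
    "sugars",
]

# Mass concentrated on levels 2-4 (>80%), matching an urban strata mix.
SES_PROBS = {1: 0.05, 2: 0.30, 3: 0.35, 4: 0.20, 5: 0.06, 6: 0.04}

# Per-sex-and-age daily kcal means; sex marginals under a balanced design
# are 2135 (males) and 1750 (females).
DEFAULT_KCAL_MEANS = {
    ("male", "18-40"): 2240.0,
    ("male", "41-62"): 2030.0,
    ("female", "18-40"): 1830.0,
    ("female", "41-62"): 1670.0,
}

# typical macro composition per 100 g: (carb, protein, fat, fiber)
_GROUP_MACROS = {
    "dairy": (5.0, 3.5, 3.5, 0.0),
    "meats": (0.5, 20.0, 12.0, 0.0),
    "eggs": (1.0, 13.0, 10.0, 0.0),
    "beans": (20.0, 8.0, 1.0, 7.0),
    "nuts": (20.0, 18.0, 50.0, 8.0),
    "fruits": (12.0, 0.8, 0.4, 2.5),
    "vegetables": (5.0, 2.0, 0.4, 2.5),
    "cereals": (60.0, 9.0, 3.0, 4.0),
    "tubers": (20.0, 2.0, 0.3, 2.0),
    "fats": (1.0, 0.5, 90.0, 0.0),
    "sugars": (90.0, 0.5, 1.0, 0.2),
}

# SFA/MUFA/PUFA split of total fat (Dirichlet means) per group
_FAT_SPLIT = {
    "dairy": (0.65, 0.28, 0.07),
    "meats": (0.40, 0.45, 0.15),
    "eggs": (0.33, 0.45, 0.22),
    "beans": (0.25, 0.25, 0.50),
    "nuts": (0.10, 0.55, 0.35),
    "fruits": (0.25, 0.35, 0.40),
    "vegetables": (0.25, 0.30, 0.45),
    "cereals": (0.20, 0.30, 0.50),
    "tubers": (0.30, 0.30, 0.40),
    "fats": (0.30, 0.40, 0.30),
    "sugars": (0.50, 0.30, 0.20),
}

MICRONUTRIENTS = [
    "cholesterol_mg",
    "sodium_mg",
    "calcium_mg",
    "potassium_mg",
    "magnesium_mg",
    "zinc_mg",
    "vitamin_c_mg",
    "folate_ug",
]

# per-100g micronutrient scale per group (rough, only relative structure matters)
_GROUP_MICROS = {
    "dairy": (12, 50, 120, 150, 12, 0.4, 1, 5),
    "meats": (70, 70, 10, 300, 25, 4.0, 0, 8),
    "eggs": (370, 140, 55, 130, 12, 1.3, 0, 45),
    "beans": (0, 5, 50, 400, 50, 1.5, 2, 150),
    "nuts": (0, 5, 100, 600, 200, 3.0, 1, 60),
    "fruits": (0, 2, 15, 200, 12, 0.2, 40, 20),
    "vegetables": (0, 20, 40, 250, 15, 0.4, 25, 50),
    "cereals": (0, 300, 20, 150, 40, 1.5, 0, 30),
    "tubers": (0, 10, 15, 400, 25, 0.4, 15, 20),
    "fats": (5, 250, 5, 20, 2, 0.1, 0, 1),
    "sugars": (2, 60, 20, 60, 10, 0.3, 2, 5),
}

DEFAULT_CLASS_PROBS = {
    "Clostridia": 0.45,
    "Bacteroidia": 0.25,
    "Bacilli": 0.07,
    "Gammaproteobacteria": 0.05,
    "Actinobacteria": 0.07,
    "Verrucomicrobiae": 0.03,
    "Erysipelotrichi": 0.04,
    "Deltaproteobacteria": 0.02,
    "Coriobacteriia": 0.02,
}

CLASS_TO_PHYLUM = {
    "Clostridia": "Firmicutes",
    "Bacilli": "Firmicutes",
    "Erysipelotrichi": "Firmicutes",
    "Bacteroidia": "Bacteroidetes",
    "Gammaproteobacteria": "Proteobacteria",
    "Deltaproteobacteria": "Proteobacteria",
    "Actinobacteria": "Actinobacteria",
    "Coriobacteriia": "Actinobacteria",
    "Verrucomicrobiae": "Verrucomicrobia",
}


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    """Child generator for a named stream under one master seed.

    Stream names are hashed into the spawn key so each generator gets an
    independent, reproducible substream.
    """
    key = [ord(c) for c in stream]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth diet->OTU effect planted in the simulator.

    ``effect_size`` is the log-abundance shift per 1 SD of ``driver``;
    ``role`` steers taxonomy labelling (SCFA producers become Clostridia,
    bile-tolerant/pathogen OTUs become Bacteroidia/Gammaproteobacteria).
    """

    target_otus: tuple[str, ...]
    driver: str
    effect_size: float
    direction: str = "+"
    role: str | None = None

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.direction not in {"+", "-"}:
            raise ValueError("direction must be '+' or '-'")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "+" else -1.0


def generate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Balanced covariate table over city x sex x age_group x bmi_class.

    Cell counts differ by at most 1; socioeconomic level is sampled with
    levels 2-4 holding >80% of the mass.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng_for(seed, "covariates")
    cells = [
        (c, s, a, b)
        for c in CITIES
        for s in SEXES
        for a in AGE_GROUPS
        for b in BMI_CLASSES
    ]
    order = rng.permutation(len(cells))
    assignments = [cells[order[i % len(cells)]] for i in range(n)]
    rng.shuffle(assignments)
    ses = rng.choice(list(SES_PROBS), size=n, p=list(SES_PROBS.values()))
    df = pd.DataFrame(assignments, columns=["city", "sex", "age_group", "bmi_class"])
    df.insert(0, "person_id", [f"P{i:04d}" for i in range(n)])
    df["ses"] = ses.astype(int)
    return df


def generate_food_database(
    n_items: int,
    seed: int,
    ambiguous_frac: float = 0.07,
    upf_frac: float = 0.30,
) -> pd.DataFrame:
    """Food item table: group, ultraprocessed status and composition/100 g.

    Groups are assigned cyclically so every one of the 11 groups has at
    least one item; kcal is consistent with the 4/4/9 macronutrient rule
    within +/-5% by construction.
    """
    if n_items < len(FOOD_GROUPS):
        raise ValueError(f"n_items must be >= {len(FOOD_GROUPS)}")
    if not 0 <= ambiguous_frac <= 1 or not 0 <= upf_frac <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = _rng_for(seed, "food_database")
    groups = [FOOD_GROUPS[i % len(FOOD_GROUPS)] for i in range(n_items)]

    rows = []
    for i, group in enumerate(groups):
        carb0, prot0, fat0, fiber0 = _GROUP_MACROS[group]
        jitter = rng.lognormal(mean=0.0, sigma=0.25, size=4)
        carb = carb0 * jitter[0]
        prot = prot0 * jitter[1]
        fat = fat0 * jitter[2]
        fiber = fiber0 * jitter[3]
        kcal = (4 * carb + 4 * prot + 9 * fat) * rng.uniform(0.96, 1.04)
        split = rng.dirichlet(np.array(_FAT_SPLIT[group]) * 30)
        micros = {
            name: scale * rng.lognormal(0.0, 0.3)
            for name, scale in zip(MICRONUTRIENTS, _GROUP_MICROS[group])
        }
        rows.append(
            {
                "item_id": f"F{i:04d}",
                "food_group": group,
                "kcal": kcal,
                "carbohydrate_g": carb,
                "protein_g": prot,
                "fat_g": fat,
                "sfa_g": fat * split[0],
                "mufa_g": fat * split[1],
                "pufa_g": fat * split[2],
                "fiber_g": fiber,
                **micros,
            }
        )
    df = pd.DataFrame(rows)

    n_amb = int(round(ambiguous_frac * n_items))
    n_upf = int(round(upf_frac * (n_items - n_amb)))
    status = np.array(["not_ultraprocessed"] * n_items, dtype=object)
    idx = rng.permutation(n_items)
    status[idx[:n_amb]] = "ambiguous"
    status[idx[n_amb : n_amb + n_upf]] = "ultraprocessed"
    df.insert(2, "upf_status", status)
    return df


def generate_recalls(
    covariates: pd.DataFrame,
    db: pd.DataFrame,
    seed: int,
    repeat_fraction: float = 0.21,
    n_repeat: int | None = None,
    kcal_means: dict[tuple[str, str], float] | None = None,
    between_sd: float = 280.0,
    within_between_ratio: float = 1.5,
    mean_items_per_day: float = 10.0,
) -> pd.DataFrame:
    """24-h recall records (person_id, day, item_id, grams).

    Day-1 caloric totals are drawn around sex-and-age means (defaults
    collapse to 2135 kcal for males, 1750 for females under a balanced
    design). Within-person day-to-day variance is ``within_between_ratio``
    times the between-person variance. ``ceil(repeat_fraction * n)``
    persons get a second recall day unless ``n_repeat`` overrides.
    """
    if not 0 <= repeat_fraction <= 1:
        raise ValueError("repeat_fraction must be in [0, 1]")
    if len(db) == 0:
        raise ValueError("food database is empty")
    kcal_means = kcal_means or DEFAULT_KCAL_MEANS
    rng = _rng_for(seed, "recalls")
    n = len(covariates)
    if n_repeat is None:
        n_repeat = math.ceil(repeat_fraction * n)
    if n_repeat > n:
        raise ValueError("n_repeat exceeds cohort size")
    repeat_ids = set(
        covariates["person_id"].iloc[rng.permutation(n)[:n_repeat]]
    )
    within_sd = between_sd * math.sqrt(within_between_ratio)
    kcal_per_g = (db["kcal"] / 100.0).to_numpy()
    item_ids = db["item_id"].to_numpy()

    records = []
    for row in covariates.itertuples(index=False):
        mu = kcal_means[(row.sex, row.age_group)]
        usual = mu + rng.normal(0.0, between_sd)
        days = (1, 2) if row.person_id in repeat_ids else (1,)
        for day in days:
            target = max(600.0, usual + rng.normal(0.0, within_sd))
            k = min(len(db), 3 + rng.poisson(max(0.0, mean_items_per_day - 3)))
            chosen = rng.choice(len(db), size=k, replace=False)
            raw = rng.lognormal(mean=math.log(80.0), sigma=0.5, size=k)
            scale = target / float(raw @ kcal_per_g[chosen])
            grams = raw * scale
            for j, g in zip(chosen, grams):
                records.append((row.person_id, day, item_ids[j], g))
    return pd.DataFrame(records, columns=["person_id", "day", "item_id", "grams"])


def generate_tree(n_leaves: int, seed: int, mean_branch_length: float = 0.1) -> TreeNode:
    """Random rooted bifurcating tree by random joins, exponential lengths."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = _rng_for(seed, "tree")
    nodes = [TreeNode(name=f"OTU{i:04d}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        for child in (left, right):
            if child.length is None:
                child.length = float(rng.exponential(mean_branch_length)) + 1e-6
        nodes.append(TreeNode(children=[left, right]))
    return nodes[0]


def _assign_taxonomy(
    otu_ids: list[str],
    effects: list[PlantedEffect],
    rng: np.random.Generator,
) -> pd.DataFrame:
    classes = np.array(
        rng.choice(
            list(DEFAULT_CLASS_PROBS),
            size=len(otu_ids),
            p=list(DEFAULT_CLASS_PROBS.values()),
        ),
        dtype=object,
    )
    index = {otu: k for k, otu in enumerate(otu_ids)}
    for eff in effects:
        if eff.role == "scfa":
            for otu in eff.target_otus:
                classes[index[otu]] = "Clostridia"
        elif eff.role == "pathogen":
            for otu in eff.target_otus:
                classes[index[otu]] = rng.choice(
                    ["Bacteroidia", "Gammaproteobacteria"]
                )
    return pd.DataFrame(
        {
            "otu_id": otu_ids,
            "phylum": [CLASS_TO_PHYLUM[c] for c in classes],
            "class": classes,
            "label": [f"{c} sp. {o}" for c, o in zip(classes, otu_ids)],
        }
    )


def generate_microbiome(
    covariates: pd.DataFrame,
    diet_drivers: pd.DataFrame,
    tree: TreeNode,
    effects: list[PlantedEffect],
    seed: int,
    depth_range: tuple[int, int] = (3667, 20000),
    base_sd: float = 1.5,
    person_sd: float = 0.4,
    city_sd: float = 0.6,
    sex_sd: float = 0.3,
    bmi_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OTU count table + taxonomy under a log-normal/multinomial model.

    Per-sample OTU log-abundance = base + planted effects (scaled by the
    z-scored driver) + city/sex/BMI offsets + person noise; counts are
    multinomial at a per-sample depth uniform in ``depth_range``.
    Returns ``(counts, taxonomy)`` with counts indexed by person_id.
    """
    otu_ids = tree.leaf_names()
    otu_index = {o: k for k, o in enumerate(otu_ids)}
    for eff in effects:
        unknown = [o for o in eff.target_otus if o not in otu_index]
        if unknown:
            raise ValueError(f"planted-effect OTUs not in tree: {unknown}")
    missing = [d.driver for d in effects if d.driver not in diet_drivers.columns]
    if missing:
        raise ValueError(f"drivers missing from diet_drivers: {missing}")
    if len(diet_drivers) != len(covariates):
        raise ValueError("diet_drivers rows must align with covariates")

    rng = _rng_for(seed, "microbiome")
    n = len(covariates)
    p = len(otu_ids)
    base = rng.normal(0.0, base_sd, size=p)

    city_off = {c: rng.normal(0.0, city_sd, size=p) for c in CITIES}
    sex_off = {s: rng.normal(0.0, sex_sd, size=p) for s in SEXES}
    bmi_off = {b: rng.normal(0.0, bmi_sd, size=p) for b in BMI_CLASSES}

    loga = np.tile(base, (n, 1))
    drivers = diet_drivers.reset_index(drop=True)
    for eff in effects:
        x = drivers[eff.driver].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        cols = [otu_index[o] for o in eff.target_otus]
        loga[:, cols] += eff.sign * eff.effect_size * z[:, None]
    for i, row in enumerate(covariates.itertuples(index=False)):
        loga[i] += city_off[row.city] + sex_off[row.sex] + bmi_off[row.bmi_class]
    loga += rng.normal(0.0, person_sd, size=(n, p))

    probs = np.exp(loga - loga.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    lo, hi = depth_range
    depths = rng.integers(lo, hi + 1, size=n)
    counts = np.vstack([rng.multinomial(d, pr) for d, pr in zip(depths, probs)])

    counts_df = pd.DataFrame(
        counts, index=pd.Index(covariates["person_id"], name="person_id"), columns=otu_ids
    )
    taxonomy = _assign_taxonomy(otu_ids, effects, rng)
    return counts_df, taxonomy


@dataclass
class SimulatedCohort:
    """Bundle of all synthetic inputs for one cohort."""

    covariates: pd.DataFrame
    food_db: pd.DataFrame
    recalls: pd.DataFrame
    tree: TreeNode
    otu_counts: pd.DataFrame
    taxonomy: pd.DataFrame
    effects: list[PlantedEffect] = field(default_factory=list)

    def write(self, out_dir) -> dict[str, str]:
        """Write all pieces as plain-text files; returns name -> path."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "covariates": os.path.join(out_dir, "covariates.csv"),
            "food_db": os.path.join(out_dir, "food_db.csv"),
            "recalls": os.path.join(out_dir, "recalls.csv"),
            "otu_table": os.path.join(out_dir, "otu_table.tsv"),
            "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
            "tree": os.path.join(out_dir, "tree.nwk"),
        }
        self.covariates.to_csv(paths["covariates"], index=False)
        self.food_db.to_csv(paths["food_db"], index=False)
        self.recalls.to_csv(paths["recalls"], index=False)
        # OTU table convention: rows = OTUs, columns = samples
        self.otu_counts.T.rename_axis("otu_id").to_csv(paths["otu_table"], sep="\t")
        self.taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
        with open(paths["tree"], "w") as fh:
            fh.write(write_newick(self.tree) + "\n")
        return paths


def simulate_cohort(
    n: int,
    seed: int,
    n_items: int = 120,
    n_otus: int = 150,
    effects: list[PlantedEffect] | None = None,
    n_planted: int = 5,
    planted_effect_size: float = 1.0,
    depth_range: tuple[int, int] = (3667, 20000),
    repeat_fraction: float = 0.21,
) -> SimulatedCohort:
    """One-call cohort: covariates, foods, recalls, tree, microbiome.

    When ``effects`` is None, plants two default communities: ``n_planted``
    fiber-responsive SCFA producers (+) and ``n_planted`` fat-responsive
    bile-tolerant OTUs (+), giving downstream recovery tests a target.
    """
    from .intake import compute_nutrients

    covariates = generate_covariates(n, seed)
    food_db = generate_food_database(n_items, seed)
    recalls = generate_recalls(
        covariates, food_db, seed, repeat_fraction=repeat_fraction
    )
    tree = generate_tree(n_otus, seed)
    otu_ids = tree.leaf_names()

    daily = compute_nutrients(recalls, food_db)
    drivers = (
        daily[daily["day"] == 1]
        .set_index("person_id")
        .loc[covariates["person_id"]]
        .reset_index()
    )
    if effects is None:
        rng = _rng_for(seed, "planted_choice")
        picks = rng.choice(len(otu_ids), size=2 * n_planted, replace=False)
        effects = [
            PlantedEffect(
                target_otus=tuple(otu_ids[k] for k in picks[:n_planted]),
                driver="fiber_g",
                effect_size=planted_effect_size,
                direction="+",
                role="scfa",
            ),
            PlantedEffect(
                target_otus=tuple(otu_ids[k] for k in picks[n_planted:]),
                driver="sfa_g",
                effect_size=planted_effect_size,
                direction="+",
                role="pathogen",
            ),
        ]
    counts, taxonomy = generate_microbiome(
        covariates,
        drivers.select_dtypes(include="number"),
        tree,
        effects,
        seed,
        depth_range=depth_range,
    )
    return SimulatedCohort(covariates, food_db, recalls, tree, counts, taxonomy, effects)
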