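# dietbiome

Analysis pipeline pairing 24-h dietary-recall data with 16S gut-microbiota
profiles: diet-quality scoring, usual-intake estimation, diversity metrics
and a statistical association layer — plus a synthetic-cohort generator with
planted diet→OTU effects so that every stage has a ground-truth test.

## What it does

- **`dietbiome.simulate`** — synthetic cohorts: balanced covariates
  (5 cities × sex × age group × BMI class, socioeconomic levels 2–4
  carrying >80% of mass), a food database over 11 food groups with an
  ultraprocessed/ambiguous flag, 24-h recall records with configurable
  repeat fraction, random phylogenies, and OTU count tables drawn from a
  log-normal + multinomial model with planted, configurable diet effects.
- **`dietbiome.scoring`** — three diet-quality measures: an adapted
  Healthy Eating Index capped at 75 points (seafood/whole-grain
  components excluded), a 70-point national-guideline index with sex- and
  age-specific portion recommendations, and the percentage of calories
  from ultraprocessed food (with an `as_upf` / `as_not_upf` policy for
  ambiguous items), plus macronutrient-range classification
  (carb 50–65%, protein 14–20%, fat 20–35% of energy).
- **`dietbiome.intake`** — food-group aggregation (mass-conserving),
  per-day nutrient computation from a per-100 g composition table, and
  usual-intake estimation via one-way random-effects BLUPs
  (method-of-moments variance components, unbalanced designs, optional
  log1p transform).
- **`dietbiome.microbiota`** — rarefaction to a common depth
  (hypergeometric subsampling, no silent sample drops), Shannon/observed/
  evenness alpha diversity, weighted and unweighted UniFrac by a single
  post-order tree traversal, top-*n* OTU filtering with a median
  relative-abundance floor, and class-level taxonomic profiles.
- **`dietbiome.association`** — z-score PCA, dummy-coded covariate
  residualization, multivariable-adjusted alpha-diversity regressions,
  single-factor PERMANOVA, symmetric Procrustes with a permutation test,
  and random-forest OTU-community selection (out-of-bag MSE-increase
  importance, recursive feature elimination maximizing OOB explained
  variance, Spearman-signed directions).
- **`dietbiome.pipeline` / CLI** — an end-to-end `run-all` producing all
  result tables as plain CSV/TSV with a reproducibility manifest.

## CLI

```bash
# generate a synthetic cohort
dietbiome simulate --n 120 --seed 42 --out-dir sim/

# stage-by-stage
dietbiome score-diet --recalls sim/recalls.csv --fooddb sim/food_db.csv \
    --covariates sim/covariates.csv --ambiguous-policy as_upf -o quality.csv
dietbiome estimate-intake --recalls sim/recalls.csv --fooddb sim/food_db.csv \
    --transform log1p --out-dir intake/
dietbiome diversity --otu-table sim/otu_table.tsv --tree sim/tree.nwk \
    --taxonomy sim/taxonomy.tsv --depth auto --seed 42 --out-dir div/

# everything at once from a config file
dietbiome run-all --config run.yaml --out-dir results/
```

Example `run.yaml`:

```yaml
seed: 42
simulate:            # or an `inputs:` block with paths to the five files
  n: 120
  n_items: 80
  n_otus: 120
depth: auto          # rarefaction depth policy: auto = min sample sum
ambiguous_policy: as_upf
rf:
  n_trees: 50000     # pipeline default; tests use reduced forests
  top_n: 100
  min_median_rel: 0.0001
  variables: [hei, gaba, upf_pct, fiber_g, sfa_g]
permutations:
  permanova: 999
  procrustes: 10000
```

Scoring standards (component cutpoints, portion sizes, sex/age
recommendations) are editable CSVs; see
`dietbiome.standards.HEIStandards.to_csv` / `GABAStandards.to_csv`.

## Layout

```
src/dietbiome/
  simulate.py     synthetic cohorts + planted effects
  standards.py    editable scoring standards (75- and 70-point indexes)
  scoring.py      diet-quality measures
  intake.py       food groups, nutrients, BLUP usual intakes
  tree.py         Newick parse/write + traversal
  microbiota.py   rarefaction, alpha diversity, UniFrac, filters
  association.py  PCA, PERMANOVA, Procrustes, random forest
  pipeline.py     run-all orchestration + manifest
  cli.py          click entry points
tests/            unit, property and acceptance suites
scripts/acceptance.py
```
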