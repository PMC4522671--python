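# forestbeta

Phylogenetic and functional beta diversity at local scales in
stem-mapped forest plots: do species assemblages turn over through space
because of **environmental filtering** (deterministic, niche-based) or
because of **dispersal limitation and drift** (neutral)?

`forestbeta` implements the full analysis chain used to ask that
question of forest-dynamics-plot (FDP) data — a fully mapped census,
a community phylogeny, species trait means and gridded soil samples —
plus a synthetic forest generator that produces all of those inputs
under named assembly scenarios, so every step can be validated against
a known truth.

## The statistics at the core

For two subplot communities k₁ and k₂ and a species distance δ
(cophenetic distance on the phylogeny, or on a UPGMA trait dendrogram
built from the first three principal components of the trait table):

* mean pairwise distance ("basal" turnover)

  D_pw = [ Σ_{i∈k₁} δ̄_{i,k₂} + Σ_{j∈k₂} δ̄_{j,k₁} ] / (n_{k₁} + n_{k₂})

  where δ̄_{i,k} is the mean δ from species i to all species of k;

* mean nearest-neighbour distance ("terminal" turnover), D_nn, with
  min in place of the mean;

* abundance-weighted forms D_pw′ and D_nn′, each species term weighted
  by its within-community relative abundance f_i and the sum divided
  by 2.

Observed values are standardized against a tip-shuffle null model
(species names permuted across the tips of the tree or dendrogram, the
community matrix held fixed, 999 shuffles by default):

  S.E.S. = −(observed − null mean) / null sd

so *negative* S.E.S. means turnover faster than expected given the
observed species turnover. Beta diversity is then decomposed by
multiple regression on distance matrices (MRM) into pure geographic,
pure environmental and shared fractions, where the environmental
distance is the Euclidean distance between subplots on the first three
principal components of block-kriged soil variables. A 20 m habitat
map (valley / slope / ridge, from elevation, slope and convexity)
supports a within- vs across-habitat contrast of S.E.S. values.

## Worked example

Simulate a 1-ha plot assembled under strong environmental filtering and
run the full analysis:

```bash
forestbeta run-all --preset filtered --seed 1 --out runs/filtered
```

or drive the same computation from Python (numbered scripts under
`analysis/` do exactly this):

```bash
python analysis/01_simulate_scenarios.py
python analysis/02_run_pipeline.py
python analysis/03_scenario_discrimination.py
```

The discrimination script prints, for 10 replicate plots per scenario
(this exact output, seed 1):

```
filtered: pure_env > pure_geo in 10 / 10 replicates
neutral:  pure_geo >= pure_env in 10 / 10 replicates
                    r2_full  pure_geo  pure_env
scenario metric
filtered func_dnn     0.418     0.021     0.287
         func_dpw     0.265     0.009     0.222
         phylo_dnn    0.384     0.032     0.238
         phylo_dpw    0.217     0.019     0.142
neutral  func_dnn     0.281     0.215     0.010
         func_dpw     0.047     0.029     0.013
         phylo_dnn    0.280     0.216     0.012
         phylo_dpw    0.060     0.046     0.005
```

Read: when communities are assembled by niche filtering, environmental
distance explains most of the explainable variation in both
phylogenetic (`phylo_`) and functional (`func_`) dissimilarity (pure
environmental fraction ≫ pure geographic), and the ranking flips under
neutral assembly — the signature the variation-partitioning design is
meant to detect. `analysis/04_habitat_contrast.py` prints the matching
habitat-level result (within-habitat S.E.S. above across-habitat
S.E.S., Student's t, 9/10 replicates at seed 1), and
`analysis/05_null_calibration.py` verifies the null model is centred
(pooled S.E.S. mean +0.018, 5.6% of values beyond ±1.96).

## Layout

| path | contents |
| --- | --- |
| `src/forestbeta/` | the library: io, grid, simulate, traitspace, soilenv, beta, nullses, mrm, habitat, pipeline, experiments, cli |
| `analysis/` | numbered narrative drivers over the library |
| `tests/` | pytest suite (unit, property and end-to-end tests) |
| `docs/methods.md` | model and procedure documentation |
| `scripts/acceptance.py` | from-scratch recomputation of headline numbers |
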