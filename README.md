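# steeprank

Tools for asking whether the *steepness* of a dominance hierarchy predicts
how strongly fitness-related benefits track individual dominance rank,
across many social groups and species.

The package implements the full analysis chain:

1. **`steeprank.dominance`** — validation of win–loss sociomatrices,
   Dij-corrected normalized David's scores (cardinal ranks), hierarchy
   steepness (absolute OLS slope of sorted cardinal scores against ordinal
   ranks) with a binomial randomization test, ordinal ranking, and the
   modified Landau linearity index with its randomization test.
2. **`steeprank.elo_steepness`** — sequential Elo ratings, randomized-order
   Elo with repeatability (ICC) steepness, and a simplified Bayesian
   latent-strength model giving posterior steepness with credible intervals
   on the cumulative-winning-probability scale (`Elo_Bayes`) and via
   per-dyad Beta posteriors of the dyadic dominance index (`DS_Bayes`).
3. **`steeprank.effect_sizes`** — rank–benefit Pearson correlations with
   the "dominants gain more ⇒ positive" sign convention, conversions from
   chi-square and mean±SD statistics, Fisher's Z with sampling variance
   1/(n−3), and the averaging rules for multiple measures/matrices.
4. **`steeprank.phylo`** — Newick parsing, Grafen branch lengths
   (ultrametric, depth 1), and the species correlation matrix used as a
   phylogenetic random-effect structure.
5. **`steeprank.meta`** — multilevel meta-regression with known sampling
   variances and three variance components (species, group-in-species,
   phylogenetic), ML/REML fitting, full-vs-control likelihood-ratio tests,
   omnibus moderator test (Q_M), residual heterogeneity (Q_E),
   phylogenetic-signal ratio with LRT, and small-study / time-lag
   publication-bias meta-regressions.
6. **`steeprank.synthetic_data`** — Yule species trees, logistic-contest
   interaction matrices with latent abilities, benefit tables with a chosen
   rank–benefit correlation, and complete datasets with a ground-truth
   ledger for recovery testing.
7. **`steeprank.pipeline` / `steeprank.cli`** — dataset schema and
   orchestration of the 8 steepness × rank-basis models (4 methods ×
   {cardinal, ordinal}), the linear-hierarchy restricted rerun, interaction
   and steepness-only model sets, and report output.

## CLI

```sh
steeprank --seed 1 steepness matrix.csv --method all
steeprank linearity matrix.csv
steeprank simulate config.yaml --out my_dataset
steeprank effects my_dataset --out effects.csv
steeprank meta my_dataset [--restricted] [--interaction setting] [--simple]
steeprank reproduce my_dataset --out report
```

A YAML config can tune each stage via blocks `elo:`, `bayes:`,
`linearity:`, `meta:` and `simulate:`, e.g.

```yaml
seed: 1
elo:
  n_randomizations: 1000
bayes:
  n_chains: 4
  n_iter: 1500
  burn_in: 1000
linearity:
  rand_null: 10000
simulate:
  n_species: 10
  groups_per_species: 2
```

## Dataset directory schema

`dataset.csv` (one row per record; several rows may share a `record_id`
when multiple benefit measures are averaged) with columns:

```
record_id, group, species, matrix, benefit, benefit_type, duration_months,
setting, sex, dispersal, social_org, origin, pub_year, n
```

plus `matrices/<group>.csv` (labelled sociomatrix, winners in rows),
`benefits/<record_id>.csv` (`individual,benefit_value`), and `tree.nwk`
(Newick; non-ultrametric trees get Grafen branch lengths).  Rows without
raw files may instead carry precomputed `r` and per-method steepness
columns (`steepness_nds`, `steepness_elo_rpt`, `steepness_elo_bayes`,
`steepness_ds_bayes`), with an optional `linear` flag for the restricted
analysis.  Rows with `n < 4` are excluded with a logged reason.

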