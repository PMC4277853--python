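# pollinet

Structure and invasion analysis of bipartite plant–pollinator networks.

`pollinet` implements a four-level analysis of how exotic plants integrate
into pollination networks:

1. **Community / network structure** — richness counts, connectance family
   (`C = L/PA`, `C_P`, `C_A`), NODF nestedness, relative nestedness against
   a probabilistic (averaged-fill) null ensemble, and plant phylogenetic
   diversity from a dated tree.
2. **Species level** — rank-normalized degree, nestedness-contribution
   z-scores (focal-species rewiring ensembles), and phylogenetic uniqueness.
3. **Interaction level** — mutual dependences and mass-action interaction
   preferences Γ (log-additive least-squares fit over observed cells), with
   binomial / OLS regressions on exotic status.
4. **Pollinator level** — a mixed-effects logistic contrast of empirical vs
   degree-preserving swap-randomized networks, modelling the probability
   that a pollinator interacts with an exotic plant from its ranked degree
   `k`, ranked nestedness contribution `c` and their interaction, with a
   random intercept per network.

A synthetic-data module generates networks, ultrametric phylogenies and
whole study sets with planted, recoverable structure, so the entire pipeline
is testable offline.

## Package layout

| module | contents |
| --- | --- |
| `pollinet.network_io` | `BipartiteNetwork`, `PlantPhylogeny`, CSV/TSV + YAML readers/writers, Newick parsing, validation |
| `pollinet.null_models` | averaged-fill cell model, focal-species rewiring, checkerboard swap chains, seeded ensembles |
| `pollinet.nestedness` | NODF, relative nestedness, nestedness contributions, rank normalization |
| `pollinet.phylo_metrics` | phylogenetic diversity and per-plant uniqueness |
| `pollinet.interactions` | dependences, mass-action preferences Γ |
| `pollinet.invasion` | Kruskal–Wallis comparisons, prevalence trends, dependence/preference regressions, the mixed-effects attachment model |
| `pollinet.glmm` | random-intercept logistic regression via adaptive Gauss–Hermite quadrature (validated against lme4) |
| `pollinet.synthetic` | synthetic networks, phylogenies, study sets, planted exotic attachment |
| `pollinet.catalog` | bundled reference catalog of the survey's exotic plant records |
| `pollinet.cli` | pipeline orchestration + `pollinet` command-line interface |

## Command line

```bash
# write a synthetic study set in the pipeline's input format
pollinet simulate --out data/ --seed 1 --n-invaded 5 --n-uninvaded 5 --quantitative

# metric tables only
pollinet metrics --in data/ --out reports/ --seed 1 --n-null-reps 200

# full analysis (group comparisons, regressions, attachment contrast)
pollinet analyze --in data/ --out reports/ --seed 1 --n-swap-reps 100

# analysis plus the prediction-grid report
pollinet report --in data/ --out reports/ --seed 1
```

Inputs are `<id>.csv` (plants as rows, pollinators as columns, labeled) plus
`<id>.yaml` sidecars (`network_id`, `location`, `quantitative`,
`exotic_plants`).  Every stage derives its randomness from the single
`--seed`, and each output directory carries a `manifest.json` recording the
configuration verbatim; re-runs are reproducible.

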