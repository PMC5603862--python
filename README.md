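# qsarfs

Wrapper feature selection for QSAR descriptor tables with four selectors —
a plain genetic algorithm (GA), an object-migration learning automaton (LA),
and their two hybrids: a mixed variant that applies the automaton's
reward/penalize update inside every GA generation, and a sequential variant
whose GA phase seeds a subsequent LA phase. Candidate subsets are scored by
the RMSE of a multiple linear regression refit on the training rows (lower is
better), with leave-one-out cross-validation available as an alternative
fitness mode.

The package also covers the surrounding workflow:

* **`qsarfs.data`** — CSV descriptor-table I/O and validation, constant-column
  removal, a |Pearson r| > 0.80 inter-correlation filter, an activity-ranked
  systematic train/test split, and the feature budget (20% of the training-set
  size, floored).
* **`qsarfs.fitness`** — OLS fitting, RMSE, and subset evaluation
  (train-fit or LOOCV).
* **`qsarfs.ga` / `qsarfs.la` / `qsarfs.hybrid`** — the four selectors; fixed
  seeds make every run bit-reproducible.
* **`qsarfs.modeling`** — least-squares SVR (RBF kernel, one dense block
  solve), LOOCV grid search over (gamma, sigma²), external-validation
  statistics (Q², r², through-origin r0², rm², regression-through-origin
  slopes k/k' with their pass thresholds), and leverage-based
  applicability-domain assessment (h* = 3p/n) for Williams plots.
* **`qsarfs.synthetic`** — seeded generators for descriptor tables with a
  planted linear signal, constant columns, and near-duplicate correlated
  pairs, so every component is testable without external data.
* **`qsarfs.cli`** — `qsarfs run / compare / synth` commands with TOML
  configuration and multi-seed summary reporting.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: published
arithmetic (split sizes, feature budgets, the leverage threshold), an
exhaustive-search oracle check for all four selectors, the hybrid-vs-GA
convergence ordering over paired seeds, automaton state-machine invariants
under 10⁵ random operations, agreement of the OLS and LS-SVR solvers with
independent oracles, validation-statistic sanity checks, and planted-
coefficient recovery.

## CLI

```bash
# write synthetic fixtures (CSV + ground-truth JSON)
qsarfs synth --out fixtures/

# run one selector for 10 seeded repeats
qsarfs run --config experiment.toml --algorithm mgala --seed 0 --repeats 10 --out results/

# run every algorithm in [compare] and merge mean convergence curves
qsarfs compare --config experiment.toml --out results/
```

Minimal `experiment.toml`:

```toml
[dataset]
path = "fixtures/small_a.csv"
activity_column = "pIC50"
id_column = "compound_id"

[run]
algorithm = "sgala"
n_repeats = 10

[sgala]
ga_generations = 60
la_epochs = 40

[compare]
algorithms = ["ga", "la", "sgala", "mgala"]
```

Unset values fall back to the published defaults: population 100,
GA generations 100, LA epochs 100, crossover 0.7, mutation 0.3, automaton
memory 3, sequential phases 60 + 40, mixed generations 100.

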