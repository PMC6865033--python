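# netaging

A binomial gene-network model of cellular aging for replicative-lifespan
data. The model composes `m` essential modules in series; each module holds
`n` redundant gene interactions whose strengths decay exponentially at a
constant rate `lam` (non-aging parts) and is wired binomially at birth
(each interaction active with probability `p`). This yields the
three-parameter hazard

    mu(t) = R * (1 + t/t0)^(n-1),      t0 = (1-p)/(p*lam)

which behaves like a Gompertz hazard with coefficient `G = (n-1)/t0` for
`t << t0`: exponential mortality acceleration emerging from purely
non-aging components.

The package provides:

- **`netaging.core`** — closed-form module/network hazard, survival and
  density functions, Gompertz and Weibull reference models, and the
  mappings between mechanistic `(m, n, p, lam)` and phenomenological
  `(R, t0, n)` parameters.
- **`netaging.fitting`** — maximum-likelihood fitting of the network,
  Gompertz and Weibull models to per-cell lifespans, AIC comparison, and
  bootstrap-with-replacement uncertainty.
- **`netaging.simulate`** — exact inverse-CDF sampling from the closed
  form, mechanistic network simulation (binomially wired modules,
  exponential interaction decay), and binned empirical-hazard diagnostics.
- **`netaging.strains`** — cross-strain analyses over fitted parameter
  tables: Strehler–Mildvan correlation, generic column correlations, a
  product-of-coefficients mediation test with percentile bootstrap,
  interaction-decay back-calculation under an assumed `p`, and column
  summaries. A 15-strain wild-isolate parameter table ships with the
  package (`netaging.load_wild_isolates()`).
- **`netaging.io` / `netaging.cli`** — long-format lifespan CSV/TSV I/O,
  fit-table TSV output, run configuration, and a `netaging` command-line
  tool.

## Command line

```sh
# simulate lifespans from the closed form or the mechanistic network
netaging simulate --params 0.0047,56.2,7.9 -n 1000 --seed 1 --out rls.csv
netaging simulate --mech 1000,7,0.7,0.005 -n 1000 --seed 1 --out mech.csv

# fit and compare models on a lifespan CSV (strain_id,lifespan per row)
netaging fit --input rls.csv --model network
netaging compare --input rls.csv

# bootstrap uncertainty, written as a fit-table TSV
netaging bootstrap --input rls.csv --model all -B 100 --seed 1 --out fits.tsv

# cross-strain analyses (default table: the packaged wild isolates)
netaging correlate                     # Strehler-Mildvan: G ~ log10(R)
netaging correlate --x gompertz_R --y t0 --log10-x
netaging mediate -B 1000 --seed 1
netaging decay-summary --p-assumed 0.7
```

All commands are deterministic for a fixed `--seed`.

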