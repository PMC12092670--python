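# floralnoise

Quantitative analysis of stochastic gene expression in floral meristems:
per-nucleus fluorescence tables in, tissue-scale pattern-variability maps
and cell-scale noise decompositions out.

## Who this is for

Developmental biologists quantifying reporter expression in meristems (or
any roughly dome-shaped tissue) from segmented confocal stacks, and
modelers studying how tissues form reproducible expression patterns out of
noisy single-cell expression. The package takes long-format CSV tables of
quantified nuclei — bud id, developmental stage, 3-D coordinates, one or
two fluorescence channels — and provides:

- **Registration and tiling**: per-bud normalization of x/y coordinates by
  the 80th percentile of the radial coordinate, a 1.3× radial outlier
  discard, and binning into 0.25 × 0.25 tiles of a shared coordinate
  system, so buds of different sizes are directly comparable.
- **Pattern variability (CV) maps**: per-bud tile-mean heatmaps normalized
  to the bud total, pooled across the buds of a stage into per-tile mean,
  SD and CV = SD/mean maps; ratio channels (e.g. mDII/DII) for
  ratiometric perception reporters.
- **Dual-reporter noise decomposition**: with two reporters c₁, c₂ driven
  by identical promoters in the same cells,

      η²_ext = (⟨c₁c₂⟩ − ⟨c₁⟩⟨c₂⟩) / (⟨c₁⟩⟨c₂⟩)
      η²_int = ⟨(c₁ − c₂)²⟩ / (2⟨c₁⟩⟨c₂⟩)

  pooled over all cells, and conditioned on tile position and stage,
  η²|(x, y, s), which removes deterministic positional/stage structure
  from the extrinsic component. η²_tot = η²_ext + η²_int holds as an
  algebraic identity.
- **Resampling statistics**: exhaustive/Monte-Carlo two-sample permutation
  tests, Bonferroni adjustment, bootstrap percentile CIs, and compact
  letter displays for multi-group comparisons.
- **A synthetic meristem generator** with separable extrinsic, intrinsic
  and measurement noise and closed-form ground truth
  (η²_ext = e^(σ_ext²) − 1, η²_int = e^(σ_ext²)(e^(σ_int²) − 1)), plus
  perturbation scenarios (cell-number reduction, uniform induction, bead
  measurement-error control) for in-silico experiments on spatial
  averaging of cellular noise.

See `docs/methods.md` for the full model and estimator conventions.

## Worked example

Simulate a two-stage dual-reporter cohort, register it, and fit the noise
decomposition:

```python
import floralnoise as fn

sims = fn.generate_cohort({"2b": 10, "2c": 8}, None, None, seed=7)
cohort = fn.register_cohort([bud for bud, _ in sims])
model = fn.DualReporterNoise.from_cohort(cohort, ("c1", "c2"))
res = model.fit(seed=7, n_bootstrap=500)
print(res.summary())
```

```
Dual-reporter noise decomposition
======================================================
channels: c1, c2
n cells (pooled): 5800

                             eta^2         eta
pooled extrinsic            0.5261      0.7253
pooled intrinsic            0.6455      0.8034
pooled total                1.1716      1.0824
  eta2_ext 95% CI: [0.4756, 0.5826]
  eta2_int 95% CI: [0.5949, 0.7014]

conditional on (tile, stage): 136 bins, 5800 cells
cond. extrinsic             0.1598      0.3997
cond. intrinsic             0.4905      0.7004
```

Read: pooled over all 5,800 cells, extrinsic and intrinsic noise look
comparable (η² ≈ 0.53 vs 0.65) — but the pooled extrinsic term absorbs the
deterministic spatial pattern (here, four incipient-sepal expression
maxima). Conditioning on tile position and stage removes that structure:
extrinsic noise drops to η² ≈ 0.16 while intrinsic noise stays at ≈ 0.49,
revealing that cell-intrinsic stochasticity dominates. (The generating
model used σ_ext = 0.3, σ_int = 0.6, i.e. true conditional values
0.094 and 0.474; the residual excess in the extrinsic estimate is the
within-tile gradient of the smooth pattern.)

The same workflow runs from the shell:

```sh
floralnoise simulate --stages 2b,2c --out run/ --seed 7
floralnoise register --in run/nuclei.csv --out run/registered.csv
floralnoise heatmap --in run/nuclei.csv --channel c1 --out run/heatmaps
floralnoise noise --in run/nuclei.csv --c1 c1 --c2 c2 --mode by-tile --out run/noise.csv
floralnoise full-run --out run/full --seed 7
```

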