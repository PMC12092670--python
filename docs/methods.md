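# Methods

## Problem setting

Floral meristems (buds) express developmental reporters — an auxin-signaling
transcriptional reporter being the motivating case — with visible
cell-to-cell stochasticity. Two questions drive the analysis this package
implements:

1. How variable is the *tissue-scale* expression pattern from bud to bud,
   and how does that variability change with developmental stage?
2. How much of the *cell-scale* variability is extrinsic (shared cellular
   state) versus intrinsic (stochasticity of expression itself), once the
   deterministic positional and stage structure of the pattern is removed?

Inputs are long-format per-nucleus tables: bud identifier, stage label,
3-D nucleus coordinates in the bud frame (origin at the bud center,
x lateral, y abaxial, z apical; micrometers), an optional distance to the
bud surface, and one or two fluorescence channels in arbitrary units.

## Registration and tiling

Buds differ in size, so each bud's x and y coordinates are normalized by
the 80th percentile of its radial coordinate r = sqrt(x² + y²). The
percentile uses linear interpolation between order statistics
(h = (n−1)p/100 + 1), i.e. NumPy's default, identical to R's default
quantile type 7. Nuclei with r above 1.3 times that percentile are then
discarded as outliers; the percentile is computed on the *pre-discard* set,
since the discard rule references the same scale. Normalized coordinates
are binned into 0.25 × 0.25 tiles anchored at the origin, half-open and
lower-inclusive, so a coordinate exactly on a boundary belongs to the
higher tile. z is neither normalized nor tiled. Both the percentile, the
multiplier and the binwidth are `StudyConfig` fields.

Degenerate cases: an empty bud is an error; a bud whose nuclei all sit on
the z axis has no radial scale and is rejected; a single-nucleus bud is
allowed with a warning (its own radius becomes the scale).

## Pattern heatmaps and cross-bud variability

Per bud and channel, the arithmetic mean signal of the nuclei in each
occupied tile is computed and normalized to the sum over occupied tiles,
yielding a dimensionless *pattern heatmap* that is invariant to uniform
rescaling of the bud's signals (gain differences between imaging sessions
drop out). Unoccupied tiles are treated as missing data, not zeros —
pooling zeros would deflate means and inflate CV at the bud rim. An
all-zero bud is reported as all-zero with a warning.

Across the buds of one stage, each tile receives the count of contributing
buds, mean, sample SD (n−1 denominator, the convention of the statistical
environments this analysis style comes from; switchable) and
CV = SD/mean. Tiles contributed by fewer than 3 buds are dropped, and a
tile whose cross-bud mean is zero has an undefined CV and is excluded from
CV outputs. The long table of (stage, tile, CV) values feeds stagewise
pairwise permutation tests with Bonferroni adjustment and a compact letter
display.

For ratiometric perception reporters, a per-nucleus ratio channel
(numerator/denominator, e.g. mDII/DII) is added before tiling; nuclei with
a zero denominator are excluded and counted in the log.

## Dual-reporter noise decomposition

With two reporters c₁, c₂ driven by identical promoters in the same cell,
the plug-in moment estimators are

    η²_ext = (⟨c₁c₂⟩ − ⟨c₁⟩⟨c₂⟩) / (⟨c₁⟩⟨c₂⟩)
    η²_int = ⟨(c₁ − c₂)²⟩ / (2⟨c₁⟩⟨c₂⟩)
    η²_tot = ((⟨c₁²⟩ + ⟨c₂²⟩)/2 − ⟨c₁⟩⟨c₂⟩) / (⟨c₁⟩⟨c₂⟩)

with ⟨·⟩ the mean over the pooled cells. η²_tot = η²_ext + η²_int is an
algebraic identity of these definitions and is asserted to 1e-12 in tests.
No bias correction is applied; the estimators are the quoted formulas
literally. The raw η²_ext is a covariance estimate and may be negative in
finite samples; it is reported unclamped with a flag, and the headline η
values are square roots of the zero-clamped η². Both η and η² are emitted
everywhere to avoid scale ambiguity.

Pooling all cells regardless of position and stage folds deterministic
differences in mean expression (incipient-organ regions, stage trends)
into the extrinsic component. The conditional decomposition
η²|(x, y, s) therefore pools, per (tile, stage) bin, the cells of all buds
of that stage at that tile, and applies the same estimators per bin. Bins
with fewer than `min_cells_per_noise_bin` (default 5; the underlying
studies state no minimum, so it is explicit configuration) or a zero
channel mean are dropped.

Aggregation across bins uses pooled moments (ratio of sums): each bin
contributes n·(numerator moment) and n·⟨c₁⟩⟨c₂⟩ to a single ratio. This
weights high-signal, well-populated bins naturally and is markedly more
stable than averaging per-bin ratios, whose denominators are noisy in
small bins; for a single bin both definitions coincide.

Depth-binned analysis: for reporters expressed in inner tissue layers,
cells are first filtered to expressing cells
(max(c₁, c₂) > `expressing_threshold`) and binned by distance to the bud
surface (default 3 µm bins). Only intrinsic noise is reported by default:
omitting non-expressing cells truncates the joint distribution and biases
the covariance-based extrinsic estimate downward, so η²_ext is computed
but flagged `eta2_ext_biased_expressing_filter`.

A statsmodels-style entry point wraps the estimators:
`DualReporterNoise` is constructed from a cells DataFrame
(`from_dataframe`) or registered cohort (`from_cohort`), and `fit()`
returns a results object carrying the pooled estimate, per-stage
conditional maps, bootstrap percentile CIs for the pooled η², and a
`summary()` table.

## Resampling statistics

Two-sample comparisons use a permutation test on the difference of group
means (the underlying studies do not name their statistic; a median option
exists for sensitivity checks), two-sided. When C(n_a+n_b, n_a) ≤ 1e5 all
assignments are enumerated exactly; otherwise Monte-Carlo permutations
with the add-one rule p = (1 + #{|T*| ≥ |T_obs|})/(n_perm + 1), which
never returns zero. Comparisons of |T*| to |T_obs| use a 1e-12 relative
tie guard so exact ties are not lost to float rounding. Defaults:
100,000 permutations, 10,000 bootstrap resamples (percentile 2.5/97.5
CIs), Bonferroni adjustment for families of pairwise tests, and a compact
letter display built by insert-and-absorb: the pair-splitting step
preserves co-membership of every non-significant pair and absorption
removes subset columns, so two groups share a letter exactly when their
difference is not significant.

## Synthetic meristem generator

No public per-nucleus dataset accompanies the analysis, so the package
ships a generative model whose noise decomposition is known in closed
form. Nuclei are placed on the upper hemisphere of a sphere of radius R:
area-uniform (z ~ U[0, R], exact for a sphere), a deterministic Fibonacci
lattice for layout-reproducibility tests, or a co-located cluster for the
bead control. Each cell's deterministic mean is

    µ(x, y) = floor + baseline + Σ focus Gaussians + Σ patch Gaussians

in normalized coordinates: stage-appropriate defaults place random
Poisson-distributed patches (expected 3/bud) in young stages, two lateral
foci at the stage-2a transition, and four incipient-sepal foci at ±0.8 on
the axes (amplitude 120, width 0.2, versus baseline 20) in late stage 2.
Signals are

    c_r = µ · E · I_r + m_r,  E = exp(N(0, σ_ext²)), I_r = exp(N(0, σ_int²))

with E shared per cell, I_r independent per reporter, and m_r ≥ 0
half-normal measurement noise of scale σ_meas (truncation preserves
signal non-negativity). The lognormal construction gives

    η²_ext = e^(σ_ext²) − 1,   η²_int = e^(σ_ext²)(e^(σ_int²) − 1)

in the measurement-noise-free, constant-µ regime; every simulated bud
carries a truth sidecar with these values, and the estimators are tested
to recover them (2% relative at 1e5 cells).

Defaults σ_ext = 0.3, σ_int = 0.6 encode the qualitative finding the
pipeline is built to detect — conditional intrinsic noise exceeding
conditional extrinsic noise for the auxin-signaling reporter — at
moderate overall amplitude. Per-stage cell counts default to 60 (youngest)
through 400 (oldest), an order-of-magnitude choice for upper-epidermis
cell numbers; per-stage cohort sizes default to the observed cohort
(22/14/17/10/8 buds for stages 1a–2c). All are explicit configuration.

`quantize_binwidth` evaluates µ at tile centers of the same
percentile-normalized grid the registration stage produces (the generator
normalizes its realized radii exactly as registration will), making µ
exactly constant within every downstream tile. This supports exact
conditioning tests: with a quantized pattern and no stochastic noise,
every conditional η²_ext vanishes to float precision while the pooled
η²_ext retains the full positional variance.

Perturbation scenarios transform (geometry, model): `oryzalin` retains
41% of cells and `hydroxyurea` 67% (the reported cell-number decreases of
the corresponding treatments; configurable), `2,4-D` replaces the pattern
with a spatially uniform elevated baseline (induction level 120) leaving
noise untouched, `beads` is a co-located cluster with σ_ext = σ_int = 0
and σ_meas > 0 (instrument error only), `mock` is the identity.

What the generator does *not* emulate: cell growth, division and lineage;
mechanistic auxin transport; anisotropic nucleus shapes; spatially
correlated extrinsic noise; signal attenuation with depth; segmentation
errors. Passing tests therefore demonstrate correctness of the estimators
and pipeline logic under a known model, not robustness to every artifact
of real confocal data.

## In-silico experiments

*Conditioning experiment.* Simulates a structured cohort and contrasts the
pooled decomposition with the conditional one; with deterministic spatial
structure the pooled extrinsic estimate strictly exceeds the median
conditional tile estimate.

*Spatial-averaging experiment.* Simulates single-stage cohorts (default
20 buds each) under an identical expression model at different cell
numbers per bud (default 400 vs 60, the mock/microtubule-inhibitor
contrast). Tile CV across buds rises sharply when cells are few — with
~1 cell per tile per bud the tile mean is an almost unaveraged single-cell
draw — and the permutation test on the CV distributions (Bonferroni over
the reduced levels) detects this. Cellular noise, by contrast, is a
per-cell property: its estimate depends on the total number of pooled
cells, not on cells per bud, so the η comparison runs on supplementary
same-model cohorts enlarged to 1e5 pooled cells per level. At that size
the Monte-Carlo error of the aggregated η̂ (≈2% per level) sits well below
the 10% level-independence bound the experiment reports against; at 1,200
pooled cells (20 buds × 60) the η²_ext estimator's ~25% SE would swamp
the comparison, which is a statement about estimator variance, not about
spatial averaging.

## Numerical choices and conventions

- Percentile: linear interpolation (R type 7), configurable.
- Tile grid anchored at the origin; half-open, lower-inclusive bins.
- Sample SD with n−1 denominator throughout.
- Monte-Carlo p-values use the add-one rule; exhaustive enumeration below
  1e5 assignments.
- PRNG: NumPy PCG64. Cohorts derive one substream per bud by mixing the
  master seed, a CRC32 of the stage label, and the bud index through
  `SeedSequence`, so changing one stage's bud count does not perturb any
  other bud's realization.
- All experiment runners are bit-deterministic under (config, seed); run
  directories carry a config snapshot and a 16-hex config hash that is
  stamped as a `#` comment line on every derived CSV.
- Problem sizes in the shipped tests and the acceptance script (1e5 cells
  for estimator recovery, 10 buds × 300 cells for the conditioning check,
  2000 replicates at 999 permutations for calibration, 1e5 pooled cells
  per level for the η comparison) were chosen so each check's Monte-Carlo
  error is small against the tolerance it asserts.

## Known limitations

- The generative model is an artifact convention: the real system's noise
  need not be lognormal or spatially homogeneous, and measurement noise
  need not be additive half-normal.
- The conditional extrinsic estimate retains any within-tile gradient of
  the true mean field as apparent extrinsic noise; finer binwidths trade
  this bias against per-bin sample size.
- Raw η²_ext < 0 is reported, not corrected; heavy-tailed signals make
  the extrinsic estimator slow to converge (relative SE ≈ 10% at 1e4
  cells under the default σ's).
- The CSV schema is a package convention with a column-mapping layer; it
  does not parse any specific third-party export dialect.
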