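# Methods

This note documents the statistical model behind `cytoprofile`, the
synthetic screen generator used to exercise it, the numerical
conventions that fix otherwise ambiguous steps, and the limits of what
the package's tests demonstrate.

## Analysis model

The pipeline treats a screen as a two-level aggregation followed by a
distance-based decision rule and a permutation-scored clustering:

* **Cell → well.** The well profile is the per-feature mean over the
  well's cells. Averaging discards cell-to-cell heterogeneity by design:
  the profile describes the typical cell in a well, and downstream
  statistics are all well-level. A feature value is missing in a well
  only if it is missing for every cell there; a feature missing in every
  well of the experiment is dropped with a logged list rather than
  imputed.
* **Well → compound.** The compound profile is the element-wise median
  over the compound's replicate wells; even replicate counts use the
  midpoint of the two central order statistics. The median is robust to
  a single failed replicate, which is the dominant replicate-level
  failure mode in plated screens. The median over all mock (DMSO) wells
  — the median mock profile — is the fixed reference point of the
  analysis.
* **Activity.** A compound is active when the Euclidean distance from
  its profile to the median mock exceeds the empirical 95th percentile
  of the single-well mock distances. The construction is deliberately
  asymmetric: the null distribution is built from individual wells while
  compounds are replicate medians, so under the null the median shrinks
  toward the mock centre and fewer than 5% of inert compounds are
  called. The test suite asserts this shrinkage directionally and checks
  the single-well calibration exactly (below). Distances are taken on
  untransformed features; large-magnitude features therefore dominate,
  which is intentional — the pipeline evaluates the measurements, not a
  normalization scheme. A per-plate mock z-scoring switch exists for
  screens with strong batch effects but is off by default.
* **QC.** Plate-to-plate and well-to-well coefficients of variation are
  |sample SD / mean| (n−1 denominator; the convention is fixed here
  because nothing downstream pins it). A CV is undefined exactly when
  the reference mean is zero, and undefined values are recorded with a
  reason, never silently dropped. The response magnitude standardizes
  active-compound wells against same-plate mock well statistics and
  reports the maximum of |z| per feature — the absolute value, not the
  signed maximum, so down-regulated features register equally; the
  choice is recorded in the output's scope column. A per-cell
  standardization variant (mock statistics over individual cells) is
  available behind a flag.
* **Clustering and enrichment.** Active ∧ annotated compounds are
  clustered with cosine distance (direction, not magnitude, of the
  profile) and single linkage; every internal node (n−1 for n leaves) is
  a candidate cluster. For each candidate and each term observed in it
  (m ≥ 1), the score is the fraction of uniform size-k subsets of the
  universe with at least m term carriers. Subsets are drawn without
  replacement — a random "cluster" is a set of compounds. The exact
  hypergeometric upper tail P(X ≥ m | N, M, k) is emitted next to every
  permutation fraction: it is the n→∞ limit of the fraction and the
  stable quantity for testing. Ranking is by permutation fraction with
  deterministic tie-breaks (larger m, smaller exact tail, node id,
  term); no multiple-testing correction is applied because the fractions
  only order the clusters.

## Synthetic screen generator

The generator emulates the tabular output of a high-content screen with
enough structure to make every pipeline stage falsifiable:

* **Layout.** `n_layouts = n_plates / n_replicates` distinct plate
  layouts, each plated `n_replicates` times with replicates in identical
  well positions (as when one source plate is pinned onto several assay
  plates). Mock wells occupy positions drawn once per layout from the
  seed. The layout must balance exactly
  (`n_compounds·n_replicates + mock_wells_per_plate·n_plates =
  n_plates·wells_per_plate`); the default instance is 20 plates × 384
  wells, 1600 compounds in quadruplicate, 64 mock wells per plate.
* **Features.** A per-feature baseline b_f is drawn once per experiment
  with log-normal scales (median 100, σ = 0.5 on the log scale),
  mimicking the orders-of-magnitude spread between, say, area and
  intensity features. All other scales are relative to b_f, so
  untransformed Euclidean and cosine distances behave as they do on real
  feature tables (large features dominate).
* **Cell model.** Cell value = b_f + group effect + plate shift +
  position offset + cell noise. Cell noise is Gaussian with SD
  `cell_noise_sd`·b_f (default 0.10, a 10% per-cell coefficient of
  variation). The plate shift is a per-plate, per-feature Gaussian with
  SD `plate_shift_sd`·b_f (default 0.02); the position offset is a fixed
  per-feature direction times an edge-gradient (0 at the plate centre, 1
  on the rim) times `well_position_sd`·b_f (default 0.03). The defaults
  (`DEFAULT_NOISE`) describe a well-behaved screen: plate-to-plate CVs
  of a few percent — far below the 0.2 level that would mark a feature
  as irreproducible — with visible edge artifacts. Cells per well are
  uniform on an inclusive range; the default (1500, 2000) matches a
  real plated density and is scaled down (typically 3–100 cells/well) in
  tests and scripts, since every structural count and every calibration
  property is invariant to it and simulation cost is linear in it.
* **Planted mechanisms.** Each of `n_mechanism_groups` groups shifts a
  random `affected_feature_fraction` of the features by
  `effect_magnitude` cell-level mock SDs in a shared signed direction;
  group members optionally jitter around that direction. Ungrouped
  compounds have exactly zero effect, so a zero-effect screen is a pure
  null in which compound and mock wells are exchangeable. Annotations
  give each grouped compound its group's term with probability
  `coverage` (annotation databases never cover a library fully) and
  scatter decoy terms uniformly at a small rate.
* **Randomness.** Everything flows from one master seed through named
  substreams (baseline, platemap, effects, cells, annotations); cell
  tables additionally key their stream on the plate id (CRC32), so any
  plate regenerates identically in isolation and in any order. Identical
  config + seed reproduces every output file byte-for-byte; the CSV
  readers parse floats in round-trip mode so re-running a downstream
  stage from intermediate files is also bit-exact.

**What the generator does not model** — and hence what passing tests do
not show about real screens: segmentation errors and debris, correlated
features (real CellProfiler features are highly collinear), non-Gaussian
and cell-count-dependent noise, cytotoxic cell loss, temporal drift
within a plate run, and row/column striping beyond the radial edge
gradient. Recovery results on planted groups are best-case in the sense
that planted effects are exactly shared within a group; real
mechanism-of-action classes are heterogeneous.

## Numerical conventions and degenerate inputs

* Quantile for the activity cutoff: linear interpolation between order
  statistics (quantile q of sorted x₁…xₙ at rank 1+(n−1)q) — fixed for
  cross-language reproducibility. Ties at the cutoff are inactive
  (strictly "greater than" marks active).
* Distances over missing values use the features defined in both the
  profile and the reference.
* Zero-norm profiles cannot enter cosine clustering and raise an error
  naming the compound; designs whose layout does not balance raise an
  error naming the mismatch; a plate with fewer than two mock wells is
  skipped (with a warning) by the well-to-well CV, and fewer than two
  plates with mocks is an error for the plate-to-plate CV.
* Permutation draws are shared across terms for a given cluster size and
  seeded per (seed, k), so enrichment results are independent of cluster
  enumeration order.

## Testing design

* Aggregation, CV and distance operations are pinned to hand-computed
  values and to properties (permutation invariance, scale equivariance
  with an exactly representable factor, median bounding by replicate
  extremes).
* Single-linkage output is checked against a brute-force agglomeration
  on small matrices; subtree enumeration against the n−1 arithmetic;
  Newick output by re-parsing with an independent library.
* Permutation enrichment is validated against two oracles: the closed
  -form hypergeometric tail and exhaustive enumeration of all C(N,k)
  subsets for N ≤ 12. The exhaustive sweep checks on the order of 2000
  fractions at once, so it uses a simultaneous binomial band (Bonferroni
  at 1% family-wise error, a per-check multiplier of about 4.5 SEs at
  10⁵ draws) rather than a flat 3-SE band, which a sweep of that size
  would cross somewhere with near certainty; the individual worked
  examples keep their plain 3-SE bands.
* Null calibration of the activity cutoff is measured on held-out
  all-mock plates simulated under cell-level noise only. Independence of
  wells is what makes the binomial error bar exact; under plate-level
  artifacts the held-out pass rate is still unbiased at the percentile
  but its Monte-Carlo error is inflated by the small number of held-out
  plates, so the calibration experiment removes them by design.
* Planted-mechanism recovery runs ten seeded screens at the standard
  design scaled to 100 cells/well and 100 features, with 8 groups of 5
  compounds at effect 2 mock SDs; a group counts as recovered when its
  exact member set appears as a candidate cluster scoring below every
  non-planted (cluster, term) record on the exact tail. The suite
  requires ≥ 90% recovery.

## Known limitations

* The activity rule is a global distance: compounds that perturb few
  features strongly can be out-scored by diffuse noise on
  high-magnitude features unless standardization is enabled.
* Single linkage chains: a handful of intermediate profiles can merge
  two mechanistically distinct groups below their own merge heights.
  The subtree enumeration partially compensates (the pure subgroups
  remain candidates), but ranked output should be read subtree-wise,
  not as a flat partition.
* Permutation fractions at 10⁴ draws resolve ranks down to ~10⁻⁴; for
  smaller tails the reported exact hypergeometric value is the
  meaningful quantity.
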