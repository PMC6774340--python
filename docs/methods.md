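# Methods

This note documents the statistical procedures implemented in `noduleco`,
the model behind the synthetic survey generator, the numerical conventions,
and the design decisions taken where the procedure admitted more than one
reasonable reading.

## Survey model and quality control

The unit of observation is a vertically oriented seafloor photograph with a
known imaged area (1.71 m² at the 3 m reference altitude; for datasets
without per-image areas the quadratic footprint law
`area = ref_area·(altitude/ref_altitude)²` applies, which assumes a fixed
camera field of view). Quality control applies three filters **in order**:
(1) remove transect-junction images (vehicle turning), (2) keep every
second remaining image per transect starting from the first, (3) keep
altitudes within [2, 4] m. The alternation parity (keep 1st, 3rd, …) and
the junction→alternation→altitude order are conventions of this package;
the alternation restarts at each transect. Specimens on dropped images are
excluded downstream.

Unknown categorical labels in specimen tables degrade to `"unknown"` with a
warning rather than failing, so partially annotated datasets remain usable.

## Equal-count cover classes

Images sorted by (cover, image_id) are swept greedily: class j closes at
the first image where the cumulative focal-group count reaches
round(j·T/k). Ties in cover stay adjacent but may straddle a breakpoint —
breakpoints are defined on image order, not cover value. A class is forced
closed when only one image per remaining class is left, so all k classes
are non-empty. Each class can over- or undershoot its target by less than
the largest single-image count, which bounds the class-count spread by
twice that count (the spread can exceed one single-image count, e.g.
per-image counts [4,4,2] at k = 2 give classes [8,2]).

Metazoans and xenophyophores are partitioned separately by default
(group-specific breakpoints for group-specific standing stocks);
`shared_breakpoints=True` reuses the metazoan classes for xenophyophores.
Compositional analyses always use the metazoan partition.

## Bootstrap-like resampling

Two stopping rules, both drawing images uniformly with replacement within
one class:

* **count rule** (default min_count = 500, reps = 1000): stop at the first
  draw reaching ≥ min_count focal specimens. Stopping is minimal — the last
  image was necessary — so the overshoot is bounded by the largest
  per-image count.
* **area rule** (default window 650–670 m²): draw until cumulative area
  ≥ 650 m²; accept only if ≤ 670 m², otherwise discard the whole attempt
  and redraw. Rejection-resampling is the simplest scheme consistent with a
  hard window; overshoot-truncation alternatives would change image
  inclusion probabilities. 1000 consecutive rejections abort with advice to
  widen the window.

A re-drawn image contributes its specimens *and* its area again: densities
use multiplicity in numerator and denominator alike.

Replicate statistics are summarized by the mean (median for biovolume,
which is strongly right-skewed) and a simple percentile CI using order
statistics at ranks ⌊(B+1)α⌋ and ⌈(B+1)(1−α)⌉ (ranks 25 and 976 at
B = 1000, level 0.95), clamped to [1, B].

Randomness: one root seed; each (group, class, rule) gets an independent
`numpy.random.SeedSequence` child stream, so any class can be recomputed
alone, bit-identically, and replicate order is exchangeable.

## Metrics

Hill numbers of order 0, 1, 2 are reported as effective numbers of
morphospecies: S_N (richness), exp H′ with the natural log (required for
the effective-number exponentiation), and 1/D. They obey
S_N ≥ exp H′ ≥ 1/D ≥ 1 with equality only at perfect evenness. Diversity
is computed on metazoans only; xenophyophores — whose live/dead status is
not determinable from images — contribute standing stocks only
(configurable). Morphospecies density S_A is the bare count of distinct
focal morphospecies in an area-controlled sample; requesting it from a
count-controlled sample is a contract error. Biovolume uses the ellipsoid
proxy V = (π/6)·L·(aspect·L)², with cm³ ≡ mL ≈ g fresh wet weight.
Functional-group densities (NA/FM life habit, feeding groups, higher taxa
from the morphospecies-name prefix) are additive partitions of the matching
total density.

## Ordination

Per-replicate densities are √-transformed and compared with Bray–Curtis
dissimilarity (a pair of all-zero rows gets d = 0 by convention, with a
warning). The 2-D nMDS minimizes Kruskal stress-1 over monotone disparities
(primary approach to ties: tied dissimilarities may take different
disparities). The engine is SMACOF majorization (scikit-learn,
`metric=False`) run from a classical-scaling start plus random restarts
(default 16, max_iter 300, tol 1e-6); the reported stress-1 is recomputed
from the final configuration via isotonic regression. Coordinates are
centered and rotated to principal axes; dimension 1 is sign-fixed to
correlate positively with class mean cover and dimension 2 so its
largest-magnitude coordinate is positive, making plots reproducible across
runs. Class ellipses scale the 2×2 replicate covariance by the χ²(2) 0.95
quantile (5.991).

The default ordination uses a 100-replicate-per-class subsample (1000
points) rather than all 10 × 1000 replicates: the dissimilarity matrix and
the per-iteration isotonic fits are O(n²), and the class structure is
already stable at a few tens of replicates per class (the examples and the
acceptance script use 25–50 per class for the same reason). The full size
remains available through `ord_subsample`.

## Trend tests

Two assessments per ecological parameter, always on the k per-class summary
centers against the k class mean covers (never on raw replicates):

* **class-1 distinctness**: one joint criterion — the minimal class's CI
  upper bound below the minimum CI lower bound of all other classes (or the
  mirror for responses elevated in class 1). No pairwise testing, no
  multiple-testing correction; the joint criterion is deliberately
  conservative (under a flat null it fires in ≲ 5% of simulated surveys,
  under the saturating default in ≳ 95%).
* **Spearman rank correlation** with tie-corrected ranks. The headline
  p-value is the Student-t transform t = r_s√((k−2)/(1−r_s²)) on k−2 df,
  which reproduces published per-class worked values at k = 10 (0.891 →
  0.001, 0.760 → 0.011, −0.600 → 0.067); at |r_s| = 1 the transform
  degenerates and the exact minimum 2/k! is reported. For k ≤ 10 an exact
  two-sided permutation p, Pr(|r_perm| ≥ |r_obs|) by full enumeration (not
  a doubled one-tail), is computed alongside; the permutation dot-product
  distribution is cached per rank configuration so the k = 10 enumeration
  (10! permutations) is paid once per table.

## Synthetic survey generator

The generator defines the survey regime the analysis is tested under.

* **Cover field**: per-landscape stationary log-scale AR(1) (median,
  log-sd 0.8, ρ = 0.7 between consecutive images ⇒ meter-scale patchiness),
  exponentiated, capped at 37%, with independent zero-inflation for truly
  nodule-free images. Defaults calibrate the pooled field to mean cover
  ~6–7%, max 37%.
* **Species responses**: five forms — flat d₀; saturating d₀+dmax·c/(c+h);
  declining d₀e^(−bc); unimodal A·exp(−(c−μ)²/2σ²); increasing a·c^γ.
  Counts per image are Poisson(area × density). The default pool (~20
  metazoan + 5 xenophyophore morphospecies) spans all forms, with a
  numerically dominant declining sponge at minimal cover, and is scaled so
  pooled post-QC densities are ~0.42 (metazoan) and ~2.5 (xenophyophore)
  ind m⁻².
* **Body size / biovolume**: log-normal lengths per species; biovolume from
  the ellipsoid proxy above.
* **Nodules**: per-image log-normal areas with median s₀ + s₁·cover,
  rescaled so their sum matches the image's cover exactly; nodule size
  therefore rises with cover (Spearman r_s ≈ 0.9 at default calibration).

Presets: `full_survey` (full calibration, ~10⁴ post-QC images, class-1 mean
cover ≈ 1%); `saturating_stock`, `null_flat`, `turnover_gradient`
(desk-scale, ~2600 post-QC images, ~200 focal specimens per class, higher
zero-inflation so the minimal class sits on the low plateau of the
responses). In `saturating_stock` the pooled metazoan response doubles from
the nodule-free plateau to saturation (class-1 density ≈ half the plateau,
measured ratio ≈ 0.50), while a large-bodied declining sponge compensates
in biovolume so biomass density stays level along the gradient — standing
stock is distinct in class 1, biomass is not.

What the generator does **not** emulate: 2-D spatial fields (transects are
independent 1-D series), vehicle dynamics, image rendering,
observation/annotation error, species interactions, or environmental
covariates beyond cover and the landscape label. Passing recovery tests
therefore shows the *pipeline* correctly recovers structure of this
statistical form from count data at realistic sizes — not that real
assemblages follow these response forms.

## Degenerate inputs and numerical conventions

* Empty abundance vectors: Hill numbers are undefined (error), S_A of an
  empty sample is 0.
* Constant summary vectors: Spearman r_s is undefined (error status; the
  trend table records NaN for that parameter).
* Zero-area samples and images: rejected at validation.
* All-zero Bray–Curtis pairs: d = 0 with a warning collected in the run.
* nMDS non-convergence: result returned with `converged=False` and a
  warning, never an exception.
* Report tables are written with a fixed `%.10g` float format; with the
  same seed and configuration two runs produce byte-identical bundles (the
  resolved-config echo omits the output directory itself).

## Known limitations

* The area-rule acceptance mechanics (discard-and-redraw) are one of
  several defensible schemes for a windowed stopping rule.
* The exact permutation test is limited to k ≤ 10 by design (k! growth).
* Full-size ordination (10 × 1000 samples) is supported but quadratic in
  memory and time; the desk-scale default is the subsample described above.
* The greedy binning is not an optimal equal-count partition; the exact
  DP minimizer exists only as a test oracle.
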