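# Methods

## Problem setting

`mgpmap` estimates process-level genotype–phenotype (GP) maps in an
eight-founder multiparental population. Genotypes are founder-origin
probabilities: at every marker each specimen carries an 8-vector on the
probability simplex giving the estimated diplotype contribution of each
founder strain. Phenotypes are 3-D landmark configurations (the
reference case is a 54-landmark bilaterally symmetric cranium, K is
configurable). The estimand is the first paired axis of covariation
between a *gene-set-restricted* genotype block and shape — a hypothesis-
driven alternative to marker-by-marker scans.

## Pipeline

1. **Gene-set resolution** (`annotations`). Ontology terms are matched
   by case-insensitive substring; `|` unions alternatives. Annotated
   genes are deduplicated by symbol and matched to catalog intervals
   (1-based, inclusive; longest transcript per gene, ties to the
   smallest start). Only direct annotations are used — no GO-graph
   closure.
2. **Genotype block** (`genotypes`). Per gene, the two markers closest
   to the interval midpoint (largest position ≤ center; smallest >
   center; clamped at chromosome ends) are averaged elementwise into an
   n × 8 block; blocks are concatenated in gene order. Each gene's 8
   columns sum to 1 per specimen.
3. **Shape preprocessing** (`geometry`). Generalized Procrustes
   Analysis with proper rotations, unit centroid size, convergence at
   1e-10 mean change or 200 iterations. Object symmetry follows the
   reflection–relabeling construction: each configuration is joined
   with its mirrored, left/right-relabeled copy and the doubled sample
   superimposed; the symmetric component is the average of the two
   aligned copies, the asymmetric component the remainder. Directional
   asymmetry is tested by Procrustes ANOVA. Generation and sex are
   regressed out coordinate-wise (dummy coding) and the grand mean
   restored. No tangent-space projection is applied; analyses operate
   on aligned coordinates.
4. **Regularized PLS** (`spls_core`). Standardize both blocks,
   soft-threshold the cross-correlation matrix at λ, take the leading
   singular triple. λ is therefore on the correlation scale; values in
   the 0.04–0.08 range are typical and 0.06 is the default. Only the
   first component is estimated — no deflation.
5. **Inference** (`inference`, `mutants`). Permutation null, vector
   correlations, gene drops, pairwise process clustering, mutant
   contrasts and morphospace projection, described below.

## Numerical and statistical conventions

- **GPA frame.** After convergence the consensus is rotated into its
  principal-axes frame (axes ordered by landmark variance, signs fixed
  by the largest-|projection| landmark, right-handed). This makes GPA
  output invariant to specimen order and to arbitrary rigid
  pre-transformations of the input (verified to 1e-8). Near-spherical
  consensus shapes make this frame ill-conditioned; no remedy is
  attempted.
- **Symmetry frame.** The doubled-sample consensus is canonicalized so
  its symmetry plane is exactly x = 0 (the plane normal is recovered
  from the rotation aligning the reflected consensus to itself); the
  consensus is re-symmetrized elementwise every iteration, which makes
  the reflected copy of every aligned shape itself optimally aligned —
  the doubled GPA then reduces to aligning originals only.
- **Asymmetry F-test.** SS_DA = n‖mean asymmetry‖² on df₁ = empirical
  rank of the asymmetric component matrix; SS_FA = within-sample
  deviation on df₂ = (n − 1)·df₁. Under isotropic landmark noise and a
  symmetric mean, the asymmetric subspace inherits isotropy (the
  nuisance directions removed by alignment are reflection eigenvectors,
  so the projections commute) and F is calibrated; the test suite
  verifies uniform p-values over 500 null replicates. The rank-based
  df requires n to exceed the asymmetric-subspace dimension
  (3·pairs + midline − 3); with fewer specimens the df are
  underestimated and the test is only approximate.
- **Registration absorbs rigid components of planted asymmetries.** A
  perturbation confined to one landmark pair loses its overlap with
  the rotation tangents during superimposition, so its asymmetric
  field equals the *projected* perturbation (first-order exact,
  verified to rel. error 5e-6 at offset 0.01), not the raw one; for a
  generic pair shift only ~75–91% of the planted energy stays on the
  pair. Symmetrize-twice is likewise idempotent only to second order
  in the asymmetry magnitude (rescaling and consensus re-estimation
  are O(ε²)); it is a numerical fixed point (< 1e-8) on
  asymmetry-free samples.
- **Sign conventions.** The largest-|entry| of the phenotypic loading
  vector v is positive (u flips with it); principal components use the
  same rule. All vector-correlation *matrices* use |r|; individual
  comparisons report signed r with t = r√(df/(1 − r²)), df = entries − 2,
  two-sided p. (Some published analyses report t-values inconsistent
  with this standard formula; we implement the standard one.)
- **R² estimator.** tr cov(Ŷ)/tr cov(Y) with Ŷ = t·b′ + column means.
  Because u is chosen adaptively, the estimator is optimistically
  biased in proportion to the genotype-block width relative to n —
  which is exactly why R² is referred to a permutation null rather
  than interpreted absolutely.
- **Cross-validation.** Specimen-level folds from a seeded shuffle;
  standardization re-estimated per training fold; error is mean squared
  held-out deviation on the original coordinate scale; ties between
  penalties resolve to the larger (sparser, more interpretable) λ.
- **Permutation null.** Replicates draw |gene set| catalog genes
  without replacement — gene-level resampling automatically reproduces
  the two-flanking-marker averaging and much of the LD structure of
  real marker sets. Draws are additionally matched on mean within-set
  LD (gene-level LD = max over founders of the squared correlation of
  the founder-probability tracks; tolerance 0.05, best of 51 attempts
  accepted otherwise). p uses the add-one estimator, so it is never 0.
  The permutation path refits from per-gene precomputed slices; a test
  asserts exact agreement with the reference implementation.
- **Gene drops.** Importance = Euclidean norm of a gene's 8 founder
  loadings in the full fit; genes are removed cumulatively in
  full-model order and the model refit at the same λ. Caveat: if a
  retained gene is in LD with a removed one it keeps carrying the
  signal — distinguishing "one dominant gene" from "one dominant locus"
  requires the retained set to be unlinked to the removed gene, which
  the dominant-architecture study enforces by drawing its decoys from
  other chromosomes.
- **Clustering.** Distances 1 − |r|, complete linkage by default
  (single/average available); cophenetic correlation over the
  strictly-lower-triangle pairs with df = pairs − 2.
- **Mutant contrasts.** Mutants are registered jointly with the
  reference sample (size removed; symmetrized when a pairing is given —
  the default) and the contrast is the mutant-minus-reference mean
  difference per coordinate, i.e. the group-coded multivariate
  regression coefficient, used as a direction only. The morphospace
  ellipse is the normal-theory 95% data ellipse (χ² quantile, 2 df).
  Effect-vector tips are reported as displacements from the
  reference-mean score, scaled by the magnification factor (default 4).

## Synthetic data generator

The generator emulates the statistical structure the method assumes,
not mouse anatomy.

- **Founder mosaics.** Two independent founder-state Markov chains per
  chromosome (uniform start; switch to a uniformly random other founder
  with probability 0.02 per marker interval), averaged into diplotype
  probabilities with the characteristic {0, ½, 1} values, then mixed
  with the uniform simplex (softening 0.05) to mimic reconstruction
  uncertainty. Markers are evenly spaced (1 Mb).
- **Genome scale.** 20 chromosomes × 50 markers and a 600-gene catalog
  of non-overlapping intervals. The catalog is deliberately large
  relative to the causal footprint so that random gene sets rarely tag
  the causal loci, as a genome-wide pool would behave; with a small
  catalog the permutation null degenerates because most draws contain
  the causal genes themselves.
- **Shapes.** A deterministic bilaterally symmetric template on an
  ellipsoid (paired landmarks mirrored across x = 0, midline in-plane),
  plus a rank-1 additive genetic effect: each causal gene contributes a
  zero-sum founder-coefficient vector (effects are contrasts among
  founders) through its averaged probability block, all causal genes
  pushing along one shared symmetric unit direction w. Per-gene scores
  are standardized, so causal genes contribute equal analytic variance
  shares by design. The amplitude is calibrated on the realized sample
  so the genetic share of total coordinate variance equals the
  configured target exactly (default 5%); isotropic Gaussian noise
  (SD 0.05 on a unit-scale template) supplies the rest. With zero
  noise the share is 1 by construction and a unit amplitude is used.
  The target share is defined on raw coordinates; the full pipeline
  analyses the *symmetric* component, where removing the asymmetric
  half of the isotropic noise roughly doubles the genetic share (a 5%
  raw-coordinate architecture yields R² near 9% after symmetrization).
- **Defaults as study conditions.** n = 800 specimens; a 20-gene causal
  ontology term carrying 2 causal genes inside the 600-gene catalog;
  covariates (generation, sex) drawn without shape effect. The
  permutation calibration and power studies use a 5-gene term
  (2 causal + 3 decoys) at n = 300 and n = 800 respectively; the
  recovery study uses the 20-gene term at n = 800.

**What passing tests do and do not show.** The generator's noise is
isotropic and its GP map is rank-1 with linkage only through the
founder mosaic; real craniofacial data have strongly anisotropic,
integrated covariance, multi-axis genetic architecture, measurement
error correlated across landmarks, and kinship structure. Calibration
and recovery results under the generator therefore validate the
implementation and the statistical logic at desk scale, not
field performance on real morphometric data.

## Problem sizes used by the test suite

Chosen so the full suite runs comfortably on one CPU: oracle checks at
n = 40–60 with p, q ≤ 30; recovery at n = 800 over 20 seeds;
permutation calibration over 200 datasets × 199 permutations at
n = 300 and power over 100 replicates × 99 permutations at n = 800;
asymmetry calibration over 500 replicates of 30 specimens × 12
landmarks. The morphometrics tests use a 12-landmark template — the
geometry is dimension-agnostic and the smaller configuration keeps the
500-replicate calibration fast.

## Known limitations

- Only the first PLS component is estimated; architectures with
  several comparable orthogonal axes are summarized by one axis.
- The LD summary (max founder-track r²) is one reasonable choice among
  several; no consensus definition exists for founder-probability data.
- Coordinates-level standardization inside the PLS means v is a
  *standardized-scale* direction; on noise-free data its raw-scale
  counterpart is b (the shape regression), which the recovery tests use
  where the distinction matters.
- The asymmetry test df convention (empirical rank) is declared, not
  universal; published Procrustes ANOVA tables may use different df.
- Gene identity is keyed on symbol; catalogs with duplicated symbols on
  different chromosomes are rejected rather than disambiguated.
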