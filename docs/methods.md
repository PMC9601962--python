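# Methods

## The bias model

`mockbias` works entirely in compositional coordinates.  A sample's counts
are closed to relative abundances and mapped by the centered log-ratio
(clr), `clr(p)_j = log p_j − (1/J) Σ_j' log p_j'`.  The measurement model
says the observed composition is the true one reweighted by
`exp(γ_j)` with `γ = X β`; taking clr of both sides gives a linear model for
the clr discrepancy `clr(obs) − clr(truth)` with design `X` and coefficient
matrix `β̃` (the row-centered version of `β` — an additive constant per
sample cancels in the softmax, so only centered rows are identifiable).
We use the standard mean-centered clr throughout; the package never works
with an uncentered log-sum convention, since effect sizes and distances are
only reproducible under mean-centering.

With one indicator column per protocol the least-squares estimate is the
per-protocol mean of clr discrepancies; this closed form is used as the test
oracle for the general `lstsq` path.  Zeros are outside the clr domain: the
default pipeline refuses zero counts rather than silently altering data
(`pseudocount=0` raises), and the supported zero-avoidance route for
unknown-truth sample sets is the detection filter — keep exactly the taxa
with positive counts in *every* sample of at least one grouping level
(product).  A user-set positive pseudocount is available but never implied.

## Permutation inference

Hypotheses are linear restrictions on rows of `β̃`: a protocol row is zero
(no bias), all rows zero, two rows equal, all rows equal — plus cross-set
versions on a stacked set × protocol cell design.  The statistic is
`F = (RSS₀ − RSS₁)/RSS₁`.  The default resampling scheme is Freedman–Lane:
fit the null-restricted model, permute its residual rows across samples
(keeping each sample's taxon vector intact, which preserves the strong
between-taxon covariance of clr data), add back the null fitted values and
recompute `F`.  A plain label-permutation scheme (`scheme="labels"`) is
provided for sensitivity checks; it is exact under full exchangeability but
invalid when nuisance protocols are themselves biased.

Empirical p-values default to `(1 + #{F* ≥ F})/(n_perm + 1)`, which can
never be zero; a literal mode `#{F* > F}/n_perm` is available.  Every
result object records `n_perm`, the seed and the p-value mode.

Known behaviour at very small designs: for partial nulls (single-protocol
or pairwise restrictions) on a saturated 4 × 4 one-way layout, the
Freedman–Lane null distribution is conservative in its bulk — permutations
that place one group's centered residuals into the tested slot collapse the
statistic toward zero — while the upper tail, and hence rejection at
conventional levels, remains close to nominal (measured ≈ 0.05–0.06 at
α = 0.05 in the test suite).  The overall no-bias test has an empty
restricted design, where the scheme reduces to permuting raw rows and is
exact; the calibration tests use it for the distribution-level uniformity
check.

For the paired relative-bias model, the permutation unit is the underlying
sample: protocol labels are shuffled within each pairing group, pairs and
the difference design are rebuilt, and `F` recomputed.  This preserves the
dependence among overlapping pairs that the observed statistic carries, so
no degrees-of-freedom correction is needed.

## Relative bias from pairs

With unknown truth, all unordered distinct-protocol pairs within each
pairing group are formed (maximal information; the permutation makes the
induced dependence ignorable), the clr difference of each pair regressed on
the indicator difference with the reference protocol's column removed, and
the reference row reported as zeros.  With exhaustive pairs and balanced
replication this reproduces the direct fit's row differences exactly, which
the test suite asserts to 1e-10.  Only row differences are interpreted;
column-centering `β̂` is offered as a reporting transform that leaves
differences, pairwise effect sizes and distances unchanged and makes the
Gower-centered squared-distance matrix equal `β̂ β̂ᵀ` exactly.

## Distance comparison and the GRV test

The protocol distance matrix is `D_kk' = ‖β̂_k· − β̂_k'·‖₂`, equal to the
Aitchison distance between protocol-mean observed compositions.  For
reporting, matrices are divided by their full-matrix Frobenius norm (both
triangles and the zero diagonal); the GRV statistic is invariant to this
scaling, so it affects presentation only.  Association between two sample
sets' matrices is measured by
`GRV = tr(G₁G₂)/√(tr(G₁²) tr(G₂²))` on Gower-centered matrices
`G = −½ C D² C`, or by the Mantel correlation of strict upper triangles
(undefined, and reported as such, for equidistant geometries).

The null distribution combines two layers per iteration: (a) replicates are
resampled with replacement independently within every protocol (and product)
stratum of each sample set and `β̂` and `D` recomputed, propagating sampling
variability; (b) one uniformly random simultaneous row/column permutation
(identity allowed — with K = 4 there are only 24, and the bootstrap layer
supplies continuous variability) is applied to the second matrix.  The
observed statistic uses the full data with no bootstrap.  Bootstrap and
permutation draws are paired one-to-one within an iteration.  The resulting
test measured slightly conservative (type-I ≈ 0.036 at α = 0.05 over 500
null runs), consistent with the +1 p-value convention and the extra
bootstrap variability in the null draws.

## Synthetic data

The generator emulates the study design the analysis assumes: a known-truth
mock layout (default 4 protocols × 4 replicates on the 8-taxon Zymo
theoretical composition: Staphylococcus 13.3%, Bacillus 15.7%,
Lactobacillus 18.8%, Listeria 15.9%, Enterococcus 10.4%, Salmonella 11.3%,
Escherichia/Shigella 10.0%, Pseudomonas 4.6%) and a paired unknown-truth
layout (default 6 products × 4 protocols × 3 replicates, 10 taxa) in which
each product draws an independent truth as a log-normal clr perturbation
(σ = 1.0) of a uniform base, guaranteeing distinct product compositions.

Counts are Dirichlet-multinomial: the per-sample composition is drawn from
`Dirichlet(α · biased_expectation)` for finite concentration `α` (pure
multinomial in the `α = ∞` default), then counts from a multinomial with
library size Poisson-jittered around `depth` (default 5 × 10⁴, a typical
16S library scale that keeps runs in seconds).  No distributional form for
the replicate error is implied by the model itself; Dirichlet-multinomial is
the field-standard overdispersed choice and approximates mean-zero clr
error.  What the generator does *not* emulate: read-level artefacts,
chimeras, contamination events, taxonomic misassignment, or realistic
between-replicate extraction variance (no published variance information
exists to calibrate `α`, so it is a knob, not an estimate).  Passing
calibration and recovery tests on these simulations therefore validates the
statistical machinery under the model's own assumptions, not robustness to
real-data pathologies.

## Numerical choices and problem sizes

- Fitting uses `numpy.linalg.lstsq`; rank-deficient designs raise rather
  than silently pseudo-inverting, except that reference-dropped paired
  designs are full-rank by construction.
- Exact-fit residuals (`RSS₁` at rounding-noise level, ≤ 1e-12 of the
  response scale) report `F = +∞` with the p-value still taken from the
  permutation counts.
- Restrictions that do not reduce the design's column space (e.g. an
  equality constraint on a single row) are rejected as ill-posed.
- Composition validation tolerances: sum-to-one 1e-12, clr zero-sum 1e-10,
  identity checks (Gower/Gram, Aitchison/row-distance) 1e-10.
- Test-suite problem sizes are chosen for desk-scale runs: calibration uses
  1000 null simulations at 200 permutations for the F-test and 500 runs at
  1000 permutations for the GRV test; recovery uses depth 1e5.  Production
  defaults are 10,000 permutations for model tests and 500,000 for GRV,
  both overridable.
- All stochastic operations take explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces every
  output bit-for-bit.

## Known limitations

- Permutation p-values depend on the resampling scheme; schemes other than
  the two implemented (Freedman–Lane, label permutation) may give different
  mid-range p-values on small designs, so published p-values from other
  implementations should be compared qualitatively, not digit-for-digit.
- The "overall" effect size is defined as the mean of its constituent
  single-protocol or pairwise effect sizes; other codings of the overall
  contrast exist and give different (non-comparable) numbers.
- The GRV test assumes the taxon sets of the two sample sets are not
  confounded with bias-driving covariates (e.g. Gram status); weighted
  distances to balance such confounders are out of scope.
- BIOM-format input is not supported; count tables are TSV/CSV.
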