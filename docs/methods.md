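# Methods

This note documents the models, defaults and numerical choices behind
`modulon`, and what validation on synthetic compendia does and does not show.

## Preprocessing

Raw counts are turned into the matrix ICA consumes in four steps.

1. **Gene filtering.** Keep genes with ORF length strictly greater than
   100 nt *and* maximum raw count across all samples strictly greater
   than 10.  Both thresholds are strict inequalities.  Filtering runs on raw
   counts, before TPM, so that removing genes rescales the remaining genes'
   TPM consistently.
2. **TPM and log transform.** Per sample, `TPM_g = 10⁶·(c_g/L_g)/Σ(c/L)`;
   column sums are 10⁶ by construction.  Expression is `log₂(TPM + 1)`; the
   pseudocount keeps zero counts at exactly 0 and avoids −∞.
3. **Replicate QC.** Within each replicate group, samples are dropped —
   worst first, by mean pairwise Pearson r — until all remaining pairs
   satisfy r > 0.95 (strict).  Groups reduced below two samples are removed
   entirely, since an unreplicated sample cannot demonstrate the required
   correlation.  A group in which every pair already exceeds the threshold
   is never touched.
4. **Reference centering.** Each gene's mean over the reference-condition
   replicates (≥ 3 required) is subtracted from all samples, so expression is
   log₂ fold change relative to the baseline growth condition.

## Consensus ICA

`RobustICA` (a scikit-learn style estimator: `fit`, `transform`,
`get_params`, fitted attributes `gene_weights_`, `activities_`,
`cluster_sizes_`) decomposes X (genes × samples) as follows.

- **Restarts.** FastICA (parallel fixed-point, log-cosh contrast, whitening
  to `n_components` dimensions, tolerance 1e-7, `max_iter` 1000) is run
  `n_runs` times with seeds drawn from `random_state`.  The defaults
  (100 runs, DBSCAN ε 0.1, minimum cluster size 50) are the established
  settings for compendium-scale iModulon mining; desk-scale analyses may
  reduce `n_runs`, in which case the DBSCAN core size scales as
  `max(2, ceil(n_runs/2))`.
- **Non-convergent runs stay in the pool.**  Above the true signal rank,
  FastICA wanders on near-Gaussian directions and rarely meets the
  tolerance, yet the same runs' signal-subspace components are fine.  The
  consensus clustering — not the convergence flag — separates reproducible
  components from wanderers.  Convergence is still tracked (`n_converged_`).
- **Double centering.**  Before whitening, per-gene and per-sample means are
  removed, and activities are fit against the same double-centered matrix.
  Both mean directions are nuisance: reference centering leaves a per-gene
  constant (the reference-mean estimation noise, shared by every sample)
  which across thousands of genes forms a rank-one direction strong enough
  to displace the weakest genuine component from the whitened subspace; TPM
  renormalization leaves per-sample compositional offsets that would
  otherwise smear a constant into every gene's weight and inflate
  memberships.  Explained variance is defined about the same double-centered
  matrix, i.e. variance excludes these offsets.
- **Consensus.** All pooled components are clustered by DBSCAN on the
  precomputed distance `1 − |ρ|` (full pool² matrix in memory — fine at desk
  scale, the documented limit is pool sizes of a few tens of thousands).
  Cluster centroids are computed by aligning each member's sign to the
  cluster's first member, averaging, renormalizing to unit L2, and
  canonicalizing the sign so the largest-magnitude weight is positive.
  Components are ordered by descending cluster size.  Activities are re-fit
  by least squares, `A = argmin ‖X − M·A‖_F`, because centroids are not any
  single run's columns.
- **Orientation/scale convention.** Weight columns have unit L2 norm;
  activities carry all scale; the sign convention above makes outputs
  reproducible.

## Dimensionality selection

The decomposition is repeated over a strictly increasing grid of dimensions
(the compendium-scale convention starts at 20 with step 20; desk-scale grids
are smaller).  At each dimension the scan records the number of robust
components, the number whose thresholded membership is a single gene, and
the number conserved — greedy one-to-one matching by descending |ρ| (ties:
lower index), counting pairs with |ρ| > 0.7 — against the components at the
largest scanned dimension.  The selected dimension is the smallest one where
`n_robust − n_single_gene == n_conserved`; if none qualifies, the largest
grid point is returned with a warning flag.

*Known limitation.*  When the smallest scanned dimension is about half the
true module count, an under-decomposed component is typically a mixture of
two modules; if one module carries more than ~50% of the mixture's energy
its correlation with the pure component exceeds √0.5 ≈ 0.707, i.e. it sits
right at the 0.7 conservation threshold, and the selection rule can
terminate early.  The rule is best behaved when low dimensions mix many
modules of comparable strength (correlations then fall well below 0.7),
which is how the validation experiments are constructed.

## Membership and explained variance

- **Membership.** K-means with k = 3 on the absolute gene weights of a
  component (10 seeded restarts, best inertia); the union of the two
  clusters with the larger centers is the member set, making membership
  invariant to the global sign and scale of the weights.  The iModulon's
  `threshold` is the smallest member |weight|.  Weight vectors with fewer
  than three distinct absolute values cannot be 3-clustered; the builder
  falls back to nonzero-weight membership with a warning.  Components with
  no members are dropped.  An exact dynamic-programming 1-D k-means oracle
  validates the 10-restart solution in the test suite.
- **Explained variance.** `EV(S) = 1 − ‖X − M_S·A*_S‖²_F/‖X‖²_F` with A*
  re-fit by least squares for the subset (X double-centered as above).
  Subset refit — rather than slicing a shared A — guarantees EV(∅) = 0,
  monotonicity over nested subsets, and a well-defined category-level EV.
  Since components are not orthogonal, single-component EVs do not sum to
  the combined EV.

## Activity analysis

- **Clustering of activities** uses average linkage on `1 − ρ` (not
  `1 − |ρ|`): anti-correlated programs (e.g. opposing nutrient regimes)
  should separate, not merge.  Constant activity rows are an error naming
  the offending component.
- **Differential activity** between two disjoint sample groups is the
  difference of means with a two-sided label-permutation p-value (add-one
  corrected, seeded).  A permutation test was chosen because it is
  assumption-free at the small group sizes typical of condition contrasts.
- **Regulon reconstitution.** Overlap of an iModulon's members with each
  known regulon is scored by precision, recall, F1 and a hypergeometric
  upper-tail p-value over the filtered gene universe, BH-adjusted across
  regulators.  A regulator is assigned to an iModulon as the best-F1 hit
  with q < 0.01 (thresholds configurable).  The putative transcriptional
  regulatory network is the union of known regulator→gene edges and
  regulator→member edges from assigned iModulons, provenance-tagged; edges
  are co-membership-based putative regulation, not causal claims.

## BGC boundary refinement

A predicted BGC region (gene-order interval plus designated core
biosynthetic genes) is matched to the iModulon containing most of its core
genes (ties: larger overlap with the whole region, then lower iModulon id).
The cluster is redefined as the maximal genome-order run of member genes
containing the cores, bridging at most `gap_tol` consecutive non-members
(default 1 — operonic genes occasionally fall below the membership
threshold); the run starts and ends on members.  Member genes outside the
run — distal regulators or transporters genuinely co-regulated with the
cluster — are reported as *associated genes*, not cluster genes.  Refinement
reasons in gene order, not base pairs, and is monotone in `gap_tol`.

## Synthetic compendium generator

The generator emulates the statistical structure the decomposition assumes:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes in the compendium |
| `k_true` | 12 | planted modules |
| `module_size_range` | (8, 40) | members per module |
| `weight_scale`, `weight_spread` | 1.0, (0.5, 2.0) | member \|weights\| ~ scale·U(spread), one sign per module |
| `sparsity_overlap` | 0.05 | fraction of members shared with one other module (≤ 2 modules per gene) |
| activity scale | 2.0 | per-condition activities ~ N(0, 2²) log₂ units, zero at reference |
| activity correlation cap | 0.35 | redraw rows until pairwise \|ρ\| ≤ 0.35 |
| `noise_sd` | 0.25 | per-entry Gaussian noise, log₂ units (replicate jitter) |
| design | 20 conditions × 3 replicates | condition 0 is the reference triplicate |
| baseline | U(2, 10) | per-gene baseline log₂ expression |
| genome layout | 900 nt ORFs, 100 nt gaps | consecutive non-overlapping 1-based intervals |
| library size | 5×10⁶ | counts back-computed per sample |

Choices that matter and why:

- **Member weight spread (0.5–2.0).**  Real regulon effect sizes vary
  several-fold across members (promoter strength, operon position, mRNA
  stability).  This spread is also what makes the 3-means membership rule
  well-posed: if member weights were nearly identical, the optimal 1-D
  3-clustering would split the noise floor instead of the member cluster
  and memberships would balloon.  A tight spread (e.g. (1.0, 1.2)) is
  available for constructing exact-recovery fixtures.
- **Dense Gaussian activities with a correlation cap.**  With only ~20
  conditions, independently drawn activity rows can be collinear by chance,
  and planted modules with near-collinear activities are unidentifiable by
  *any* decomposition; the redraw guard (|ρ| ≤ 0.35) enforces the
  independence the planted model asserts.  Amplitudes of ±2 log₂ units
  (tails ±5) reflect strong perturbations such as carbon-source shifts or
  sigma-factor overexpression.
- **Counts back-computation.**  `TPM-like = 2^y − 1` (clipped at 0), scaled
  per sample to a 5×10⁶ library over the gene lengths and rounded.  Because
  TPM renormalizes every sample to 10⁶, re-running the counts through
  TPM+log₂ reproduces the generated log-expression only up to a per-sample
  compositional offset (and, below ~TPM 1, pseudocount curvature); the
  round-trip test verifies exactness on well-expressed genes after removing
  that offset.  The decomposition itself is insensitive to the offset by the
  double-centering above.

What the generator does **not** emulate: count overdispersion beyond
log-normal noise, operon structure within modules (members are placed
uniformly except BGC blocks), batch effects between projects, condition-
dependent library composition, or gene-length variation.  Passing the
validation suite therefore demonstrates correctness of the algorithms under
the planted model, not performance on any real compendium; on real data the
practical limits are the ones documented above (membership ballooning for
marginal components, border-line dimension selection).

## Validation problem sizes

The test suite and the acceptance script run the full pipeline at
2000 genes × 60 samples with 12 planted modules (20 FastICA restarts,
D = 12), a four-point dimension scan on a 10-module compendium with
10 restarts per dimension, 20-seed replicate-QC and BGC-refinement
batteries, and exact-enumeration oracles for the hypergeometric and
permutation statistics.  These sizes keep a full validation run in the
minutes range on a single CPU while leaving every code path exercised.

## Known limitations

- Membership calling can balloon for components recovered at |ρ| ≲ 0.92:
  near the noise floor the 3-means objective may prefer splitting the floor.
  Downstream consumers (regulator assignment, BGC matching) should treat
  very large iModulons with suspicion; the best-F1 assignment rule will
  still label them if the hypergeometric q-value is small.
- The DBSCAN consensus holds the full pool distance matrix in memory.
- Dimension-scan behaviour at grid points near half the true rank is
  borderline by construction (see above).
- The generator's activities are zero at the reference condition; analyses
  of absolute (uncentered) activity levels are out of scope.
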