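# Methods

## The analysis model

`metaborf` targets the two-class, small-n / large-p regime of untargeted
serum metabolomics: n ≈ 30 subjects (two balanced groups), p ≈ 10²–10³
metabolites measured as raw chromatographic area counts (positive,
right-skewed, arbitrary units) with value-dependent missingness. The
pipeline makes three modelling commitments:

* **Missingness is left-censoring.** A value is absent because it fell
  below the platform's effective detection limit, so the least-biased
  single imputation is the metabolite's minimum observed level. The
  imputation stage records a provenance mask so downstream consumers can
  distinguish measured from imputed cells.
* **Classification is by bagged Gini trees.** Each tree is grown to
  purity on a bootstrap sample of size n (drawn with replacement,
  unstratified); at each node ⌊√p⌋ candidate features are examined by
  default. Forests are insensitive to monotone feature scaling, so the
  classifier consumes raw imputed abundances; no normalisation is applied
  before the forest.
* **Importance is permutation-based (MDA).** For each tree with at least
  one out-of-bag subject, each feature *used by that tree* has its OOB
  values permuted and the accuracy drop recorded; features unused by a
  tree contribute zero for that tree. The reported MDA is the raw mean
  over trees (accuracy-fraction units). A z-score variant
  (mean / (SD/√T)) is kept alongside but the selection rule uses the raw
  mean throughout.

The refinement procedure is deliberately two-round: replicate forests on
the qualified profile vote on feature importance; the top ⌈0.05·p⌉
features of the lowest-OOB-error replicate form the refined profile; a
smaller forest refit on that profile yields the reported confusion
matrix. Selecting features and evaluating on the same subjects is
optimistic, so the pipeline also computes a nested-CV accuracy in which
selection is repeated inside each training fold; both numbers appear in
the run report so the optimism is a measured quantity, not a footnote.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `presence_min` | 0.80 | fraction per group | sparse metabolites carry little classifier signal |
| `rsd_min` | 0.15 | s/x̄, unitless | removes near-constant features; sample SD (n−1), pooled across groups, on imputed values (the matrix the classifier sees) |
| `top_fraction` | 0.05 | fraction of qualified p | refined-profile size ⌈0.05·p⌉ (ceiling, so 594 → 30) |
| `qualified_trees` | 10⁶ | trees | full-scale stability of the MDA ranking |
| `refined_trees` | 10³ | trees | the refit forest; OOB error is converged here for p ≈ 30 |
| `replicates` | 10 | forests | quantifies profile stability across seeds |
| `folds` | 5 | — | stratified (3 + 3 held out per fold at n = 30) |
| tuning grid | 10⁰…10⁶, half-magnitude | trees | 13 sizes, round(10^e): 1, 3, 10, 32, …, 10⁶ |
| `data_matrix_threshold` | 0.73 | linkage height | flat-cluster cut on the Spearman/average-linkage metabolite dendrogram |
| `correlation_matrix_threshold` | 0.60 | linkage height | cut on the correlation-matrix dendrogram |
| `features_per_split` | ⌊√p⌋ | features | the standard classification default |

Forest-size choice: among grid sizes whose mean replicate CV accuracy is
within a tolerance of the maximum, take the one with minimal SD, then the
smallest size. The default tolerance is one standard error of the best
size's replicate accuracies — small enough to respect real accuracy
differences, large enough that sampling noise does not force the largest
forest.

## The synthetic generator

`synthetic_data` draws log abundances from a multivariate normal with
block-diagonal correlation: `n_blocks` blocks of `block_size` metabolites
share pairwise correlation `block_rho` (pathway structure); all other
metabolites are independent. Defaults emulate the target regime: 759
metabolites, 15 + 15 subjects, `base_log_mean` 13 (area counts ~4×10⁵),
`base_log_sd` 1.0 (log-normal RSD ≈ 130%, typical of untargeted area
counts), 10 blocks of 15, ρ = 0.6, 10% left-censoring, 30 discriminative
metabolites at 1 log₂ unit.

Discriminative metabolites differ by `log2_fold_change · ln 2` between
groups on the log scale, placed symmetrically (cases +half, controls
−half) with alternating signs (half elevated, half reduced in cases).
Both choices mirror real panels — discriminative metabolites go in both
directions, and each group carries its own signature relative to the
cohort mean. They also matter technically: a one-directional, case-only
shift adds a constant to a case's whole profile, which leaves its
within-profile ranks unchanged and is therefore invisible to the
rank-correlation subject distance used by the heatmap clustering.
`effect_direction="up"` restores one-directional effects for experiments
that want them.

Censoring is per metabolite: observed values strictly below the
`missing_quantile` empirical quantile become missing, so the missing
fraction tracks the quantile and the minimum-observed imputation rule is
meaningful by construction. Randomness is organised as one seed
substream per block and per loose metabolite (derived via
`SeedSequence([seed, stream, index])`), so outputs are independent of
generation order; blocks are the substream unit because their members
need joint draws.

What the generator does **not** emulate: batch effects, retention-index
drift, QC-sample structure, heteroscedastic platform noise, missingness
that is not detection-limit censoring, and correlation between the
planted effect and the block structure (informative metabolites sit
outside blocks by default). Passing recovery tests therefore demonstrate
correctness of the machinery under the stated model, not performance on
any particular real cohort.

## Numerical and degenerate-case choices

* **Determinism.** Every stochastic stage takes one integer seed; child
  seeds derive from `SeedSequence([base, stream])`. Forest results are
  bit-reproducible for a given seed; PCA signs are fixed by making each
  component's largest-magnitude loading positive.
* **Tie-breaks.** OOB and held-out vote ties go to the first class label
  (first appearance order by default). Best-replicate ties on OOB error
  go to the lowest replicate index. MDA ties at the profile cut go to the
  lower original feature index. Leaf-class ties go to the first label.
* **Never-OOB subjects.** At forest sizes 1–3 some subjects are in every
  bootstrap sample; they are reported as `never-oob` and excluded from
  the OOB-error denominator, keeping the error defined across the whole
  tuning grid.
* **Zeros and constants.** Zero abundances are valid observations but
  block the log transform unless an explicit offset is passed — silent
  pseudo-counts hide a data problem. Constant metabolites fail the RSD
  filter; if one still reaches PCA or a Spearman distance it is an error
  naming the metabolite (detected with a relative tolerance, since a
  constant column's floating-point SD is O(ε) rather than exactly zero).
* **Scree elbow.** Automated selection takes the interior eigenvalue
  index with maximal second difference and retains the components before
  it; `k_override` reproduces a by-eye scree reading. Flat curves fall
  back to one component with a warning.
* **UPGMA.** Linkage, cophenetic heights and threshold cuts are scipy's;
  agreement with a brute-force UPGMA that re-averages original distances
  at every merge is asserted in the tests on matrices with distinct
  entries (merge ties are measure-zero on continuous data, and scipy's
  internal tie order is accepted as the package's deterministic
  convention). Newick exports halve height differences so leaf-to-leaf
  path length equals the cophenetic height.
* **Correlation-matrix clustering.** "Correlation distance on the
  correlation matrix" admits two readings; the default clusters the rows
  of the metabolite correlation matrix with 1 − Pearson of the rows
  (correlation of correlation profiles), and `mode="direct"` uses
  1 − r_ij itself. Both are exposed because the two conventions coexist in
  practice and differ only by one flag.
* **Cluster counts.** A threshold cut reports both the total number of
  flat clusters and the number with ≥ 2 members, since singletons are
  conventionally not lettered on heatmap dendrograms.

## Desk-scale problem sizes

The full-scale settings (10 replicates × 10⁶ trees, tuning grid to 10⁶)
are batch runs. The test suite and the acceptance script run the same
code paths at sizes where the relevant quantities are already converged:
qualified-stage forests of 4×10³–10⁴ trees (the OOB error of a 30-subject
forest stabilises well below this — the suite asserts
|err(10⁴) − err(10⁵)| ≤ 0.5/n), refit forests of 10³ trees as at full
scale, and tuning grids truncated at 10³–10⁴ trees, which is where the
Hamming-distance and CV-spread curves have flattened.

## Known limitations

* **OOB pessimism at small balanced n.** With an unstratified bootstrap,
  a subject's OOB trees were trained on samples containing on average
  (n/2 − 1) of its own class versus n/2 of the other, so OOB majority
  votes lean against the subject's class. On no-signal cohorts at n = 30
  this depresses mean OOB accuracy several points below 0.5 (the R
  randomForest reference shows the same value). OOB accuracy is therefore
  conservative, never optimistic; the cross-validated accuracy is the
  calibrated chance-level diagnostic.
* **Joint recovery of weak panels is cohort-limited.** With 5 planted
  metabolites at 2 log₂ units over unit log-SD noise (d ≈ 1.4) among 200,
  the weakest planted metabolite's *realized* effect falls outside the
  top-10 ranking of even an oracle |t| ranker in roughly a third of
  cohorts; no selector can recover the full panel every time in this
  regime, and the forest's joint recovery rate (~0.8 per cohort) slightly
  exceeds the oracle's.
* **The two-round accuracy is optimistic by design**; use the nested-CV
  number for an unbiased performance estimate.
* **Convention ambiguities** (pooled vs per-group RSD, correlation-matrix
  distance reading, ceiling vs floor at the 5% cut) are resolved by
  documented defaults with the alternative behind a flag, so either
  convention is one argument away.
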