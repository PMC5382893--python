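# Methods

## Model

The package treats a bipartite interaction matrix Y (n×m, non-negative) as a
noisy, undersampled observation of an underlying link structure. Nonzero
entries are *positive* (observed) interactions, zeros *negative*
(unobserved) ones — statistical terminology, independent of whether the
ecological interaction benefits either partner. There is deliberately no
missing-value sentinel: the premise of the method is precisely that zeros
conflate true negatives and false negatives, and the task is to rank the
zeros by their plausibility as false negatives.

The linear filter re-estimates each entry as

F_ij = α₁ Y_ij + α₂ mean(column j) + α₃ mean(row i) + α₄ mean(Y).

The column/row means act as promiscuity (generalism) scores of the two
species; the global mean captures network density. The convention is fixed:
α₂ weighs the mean over the n entries of column j, α₃ the mean over the m
entries of row i (with the default equal weights the assignment is
symmetric, but it matters for asymmetric weights and is documented here
once).

The leave-one-out imputation β at (i, j) is *defined* by the fixed point:
substitute β for Y_ij, apply the filter at (i, j), require the result to
equal β. Because the filter is affine in Y_ij, the equation is scalar-linear
and solves to

β = [(α₂/n) C′ + (α₃/m) R′ + (α₄/nm) T′] / D,  D = 1 − α₁ − α₂/n − α₃/m − α₄/nm,

with C′, R′, T′ the column/row/total sums excluding the cell. The printed
closed form is re-derived from the fixed-point definition and is validated
in the test suite against an oracle that never uses it (see below); this
derivation is the module's central contract. β is independent of Y_ij by
construction, which is what makes ranking zero cells by β a false-negative
detector rather than a self-fulfilling one. The global-average term shifts
all zero-cell scores by a common constant (T′ = T for every zero cell), so
it never changes the *ranking* of negatives — only imputed values.

## Parameters

* α₁..α₄ (unitless, ≥ 0; default 0.25 each). Equal weights reduce the filter
  to a plain average of the four terms; ranking by AUC is insensitive to the
  exact values, so no tuning machinery is provided (tuning by
  cross-validated squared loss is a documented non-goal). Weights need not
  sum to one — a warning, not an error, because only the weighted-average
  interpretation is lost. At least one of α₂..α₄ must be positive, and the
  LOO denominator D must be positive (it fails only when α₁ is close to 1
  for the given n, m; the error names D).
* SVD variance-retention threshold (default 0.75): the baseline truncates at
  the smallest rank whose leading squared singular values retain at least
  this fraction of the total squared singular mass. "Variance" is
  interpreted as uncentered Frobenius mass of Y itself, because the baseline
  is motivated as the best mean-squared-error approximation of Y; no column
  centering is applied. Unlike the LOO filter, the SVD re-estimate at a cell
  *does* use that cell's observed value — the asymmetry is intentional and
  mirrors how the two methods are compared in the experiments.
* Robustness sweep defaults: planted-false-negative fractions
  {0.05, 0.1, 0.2, 0.5, 0.9} of the positives, 100 repetitions. The test
  suite and the acceptance script use 20 repetitions on 20×20 networks; at
  that size the per-fraction standard errors are already a few times smaller
  than the effects being asserted, and the seeds are recorded in every
  report.

## Numerical choices

* `loo_impute_entry` computes C′, R′, T′ on a copy with the cell zeroed, so
  the observed value never enters the arithmetic and the independence
  property holds bit-for-bit even for overwrites like 1e6 (subtracting from
  a precomputed sum would lose ~1e-10 to cancellation). The vectorized
  `loo_impute_all` uses the O(nm) subtract-from-sums form; cellwise
  agreement between the two is a test.
* `loo_impute_oracle` solves the defining fixed-point equation numerically,
  treating the filter as a black box: it evaluates the filter at the cell
  for β = 0 and β = 1 and solves the (affine) scalar equation, or optionally
  iterates β ← g(β), which contracts because |g′| = α₁ + α₂/n + α₃/m +
  α₄/nm = 1 − D < 1 whenever D > 0. It exists purely as an independent
  check on the closed form.
* AUC uses the Heaviside pair count with H(0) = ½. The ½ tie convention is
  chosen because it makes the statistic equal to Mann–Whitney U/(|P||N|),
  keeps auc(x, x) = 0.5 and preserves the probabilistic reading. Pair
  enumeration is the reference path; above 10⁶ pairs the rank form is used,
  and the two are exactly equal (asserted on tied integer scores).
* ROC curves sweep thresholds over distinct score values descending; tied
  scores advance TPR and FPR jointly (diagonal segments). precision@k breaks
  score ties by flat row-major position, making ranked output deterministic,
  as does the (row, col) tie-break in `rank_negatives`.
* `select_rank` compares the cumulative squared-mass fraction against the
  threshold with a 1e-12 slack so that a spectrum retaining exactly the
  threshold (e.g. equal singular values) is accepted at the smaller rank.
* Degenerate inputs: 1×k matrices are rejected (row/column means would
  coincide with the cell); all-zero rows/columns are allowed — their LOO
  scores are driven by the remaining terms, as in real sparse networks;
  an all-zero matrix has an undefined SVD rank and is an error there.

## Experiments

* *Imputation*: LOO-score every cell, AUC of positive vs negative cells,
  plus ROC and precision@k for k ∈ {10, 20, 50, 100} clipped to the matrix.
* *Flip-one recovery*: every positive is zeroed in turn; all zero cells of
  the variant are re-scored (the flip shifts row/column/total sums, so all
  scores move — the closed form keeps this O(nm) per flip). The per-flip
  AUC compares the flipped cell's score with the original true negatives
  (strictly-below fraction plus half credit per tie); the dataset recovery
  AUC is the mean of per-flip AUCs. A pooled AUC across flips is reported
  alongside, since either aggregation is defensible; the per-flip mean is
  the default because each variant is its own ranking problem.
* *Robustness*: per fraction × repetition, remove round(f·#positives) ≥ 1
  positives uniformly; score the degraded matrix's zeros with the filter
  and with SVD at the re-selected rank; AUC separates planted false
  negatives from the *original* zeros. Repetition seeds are shared across
  fractions and removal sets are nested, so fraction curves are paired.
* *Forbidden links*: with a known true-negative mask, three AUCs (positives
  vs all negatives / vs forbidden only / vs potential false negatives only)
  plus score histograms on a common binning. An empty mask degrades to a
  warning, not an error.
* *Catalogue summary*: mean AUC stratified by density bins
  [0, 0.1), [0.1, 0.25), [0.25, 1] and positive-count bins [0, 50),
  [50, 100), [100, 1000), [1000, 10000), [10000, ∞). The bins are half-open
  on the right (last bin closed) — a convention this package fixes because
  printed bin labels in the literature overlap at the edges.

## Synthetic generator

`synthetic.generate` emulates the structural motifs of real interaction
networks: *nested* (perfect staircase: cells ranked by (i+½)/n + (j+½)/m,
the round(ρ·n·m) shallowest taken, giving rows in containment order),
*modular* (positives confined to block-diagonal modules) and *random*
(uniform placement). Positive-count placement is exact — exactly
round(ρ·n·m) positives — rather than i.i.d. Bernoulli, so the achieved
density is always within half a cell of the target and downstream
experiments are not confounded by density jitter. Interaction strengths are
optionally drawn lognormal(0, σ); a heavy-tailed multiplicative noise is a
stand-in for local-condition variability in visit counts, not an ecological
claim. All randomness flows from one `SeedSequence`.

What the generator does *not* emulate: degree distributions fitted to real
catalogues, phylogenetic or trait correlations, sampling-effort gradients,
or partially nested/modular mixtures. Passing tests therefore show that the
method behaves as designed on cleanly structured sparse networks — nested
structure recoverable, unstructured networks at chance — not that any
particular field dataset will reach the same AUCs.

## Limitations

* The filter uses only row/column/total counts; it cannot separate two zero
  cells in the same row and column-degree class, and it carries no side
  information (traits, phylogeny).
* The SVD baseline re-estimates with the observed value included, so its
  comparison with the LOO filter is a protocol choice, not a like-for-like
  estimator comparison.
* AUC-based evaluation is ranking-only; imputed β values are not calibrated
  interaction probabilities or strengths (for that, the weights would need
  tuning, which is out of scope).
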