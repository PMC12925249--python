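# Methods

## Model

Each cell is scored independently. Within one cell, all G genes of the
matrix are ranked by descending expression value; the n genes of a signature
set receive ranks r₁,…,rₙ and the score is

    score = 1 − U/U_max,  U = Σ rᵢ − n(n+1)/2,  U_max = n·r_max − n(n+1)/2,

with every rank first capped at r_max. U is the Mann–Whitney rank-sum
statistic comparing the signature genes against the rest of the
transcriptome of that cell, so the score is the per-cell probability-like
quantity "how close to the top of this cell's expression profile does the
signature sit", normalized to [0, 1]. Because the statistic depends only on
within-cell ordering, the score is invariant to any strictly increasing
per-cell transform — raw counts, CPM scaling and log1p normalization give
identical results (asserted bitwise in the tests).

A *legacy* normalization U_max = n·r_max is retained behind the
`legacy_norm` flag for comparison with early implementations of this
statistic. It overestimates the true maximum of U, hence produces scores
greater than or equal to the corrected ones; the test suite asserts that
dominance direction.

### Tie handling and capping order

Tied expression values (overwhelmingly the zero tail in sparse data)
receive their midrank — the mean of the positions they span — which is the
standard Mann–Whitney convention and makes scores independent of the gene
order in the input file. Capping is applied to the final midrank value, so
capped ties are deterministic. In a cell with d detected genes among G, the
whole zero tail shares midrank (d+1+G)/2, which the cap collapses to r_max
whenever that midrank exceeds it.

### Positive and negative sets

The two sets are scored as independent components and combined as
max(0, score⁺ − w·score⁻), clipped into [0, 1]. A signature with no
scorable positive component (none defined, or all its genes missing under
the skip policy) is *undefined*, reported as NaN / empty output field —
never as 0, which would be indistinguishable from "no signal". If only the
negative set vanishes under the skip policy, the combined score falls back
to the positive component with a warning.

### Missing genes

`impute_zero` treats a missing gene exactly as if an all-zero row had been
appended to the matrix for it. All of a signature's missing genes are
appended to the *same* conceptual augmented matrix, which fixes the induced
rank shifts: measured genes with negative values shift by the number of
appended rows m, measured zeros shift by m/2 (they tie with the appended
zeros), and each appended gene takes the augmented zero-tail midrank
pos_count + (zero_count + m + 1)/2 — all before capping. The implementation
computes these shifts in closed form rather than materializing the augmented
matrix; equality with literal augmentation is asserted in the tests,
including for matrices containing negative values. `skip` simply drops
missing genes and shrinks the effective n.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `r_max` | 1500 | rank cap; set ≈ median detected genes per cell. 1500 suits 10x whole-transcriptome data; targeted panels and ADT need far smaller values. Use one value across samples being compared. |
| `neg_weight` (w) | 1.0 | weight of the negative component |
| `policy` | `impute_zero` | missing-gene handling (see above); use `skip` for targeted panels |
| `chunk_size` | 500 | cells per mini-batch; memory knob only, results are chunk-invariant |
| `legacy_norm` | off | historical U_max = n·r_max normalization |
| smoothing `k` | 10 | neighbors in the kNN graph |
| smoothing `λ` | 0.1 | decay of neighbor weights (1−λ)ⁱ; λ=1 disables smoothing, λ=0 is a plain mean |
| embedding `n_components` | 20 | PCA dimensions for the internal embedding |
| embedding `target_sum` | 10 000 | per-cell count scaling before log1p |

The smoothing defaults (k = 10, λ = 0.1, 20 components, target sum 10⁴)
follow common single-cell practice; all are configurable.

## Chunked evaluation

Rank matrices are dense, so the full matrix is processed in mini-batches of
`chunk_size` cells: each chunk is densified, ranked once (shared across all
signatures), scored, and discarded. Chunks are independent, so they may be
evaluated by parallel workers; results are concatenated in input order and
are bitwise identical for every chunk size and worker count — a contract
the acceptance tests assert, not an accident of implementation.

## Degenerate inputs and numerical choices

- Scores are clamped into [0, 1] against floating-point drift; the clamp is
  mathematically inactive.
- `r_max < n`, or a set where U_max ≤ 0 (e.g. n = 1 with r_max = 1), has no
  meaningful normalization: the score is undefined (NaN) rather than
  guessed.
- Undefined neighbor scores are dropped from both numerator and denominator
  of the smoothing average; a cell whose every contributor is undefined
  stays undefined.
- kNN search is exact (brute-force Euclidean distances); ties in distance
  resolve toward the lower cell index, making the graph deterministic.
- PCA uses the full (deterministic) SVD solver with a sign convention that
  makes each component's largest-magnitude gene loading positive.

## Smoothing: self-inclusion

The smoothing average runs over the ordered sequence
[self, neighbor₁, …, neighbor_k] with weight (1−λ)ⁱ for the i-th element,
the cell itself included at i = 0 with weight 1. Summing over neighbors
only would make every weight vanish at λ = 1 and leave the score undefined;
self-inclusion instead reproduces the intended limits exactly: λ = 1
returns the original score unchanged and λ = 0 averages self and neighbors
equally. Smoothing touches only score tables; the expression matrix is
never modified (unlike gene-level imputation methods).

## Synthetic data generator

The generator emulates droplet scRNA-seq sparse counts: per-gene relative
rates are log-normal (σ = 1), per-cell depth factors log-normal (σ = 0.3),
and counts are gamma-Poisson (negative binomial, dispersion shape 2.0). A
global rate multiplier is calibrated by root-finding so that the *expected*
zero fraction of the matrix equals the requested sparsity target (default
90%, 10x-like). Planted populations multiply the rates of their signature's
positive genes by a fold factor and divide negative-gene rates by the same
factor. The standard benchmark is 2000 genes × 1000 cells with one planted
population covering 30% of cells at fold 8, marked by 15 elevated and 5
suppressed genes, cells spread over 4 samples — sizes chosen so the whole
pipeline runs in seconds on a laptop while leaving enough cells per group
for stable rank-sum separation estimates.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond the planted signal, spatial structure.
Passing the planted-signal benchmark therefore shows that the scoring
pipeline recovers a known enrichment under realistic sparsity and
overdispersion; it does not certify performance on artifacts the simulation
lacks.

## Known limitations

- Gene matching is exact and case-sensitive; no alias or identifier
  conversion (curate signatures to the matrix's namespace first).
- A gene may not appear in both the positive and the negative set; this is
  rejected as a curation error rather than resolved by precedence.
- Negative-only signatures are reported undefined: without a positive
  component the combined score would be identically zero and meaningless.
- Between-group hypothesis testing is out of scope; the per-sample mean
  table is the intended input to the user's own testing framework, and
  signatures derived from a dataset should not be tested on that same
  dataset (circularity).
- Approximate nearest-neighbor search is not implemented; the exact search
  is quadratic in cells and intended for desk-scale data.
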