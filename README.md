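# usig — rank-based gene signature scoring for single cells

`usig` quantifies the activity of gene signatures (marker panels, pathway
gene sets, data-driven modules) in individual cells of a genes-by-cells
expression matrix. It is aimed at single-cell transcriptomics practitioners
who need a robust per-cell score for annotating clusters, quantifying
activation programs, or comparing conditions — on raw counts or normalized
data, from 10x-style sparse matrices, dense tables, or `.h5ad` files.

## The score

For a cell *j* and a signature **s** of *n* genes, let
r₁,…,rₙ be the **descending ranks** of the signature genes within the
cell's full expression profile (rank 1 = most expressed; ties get midranks),
capped at a ceiling r_max:

    rᵢ ← min(rᵢ, r_max)

The score is one minus the normalized Mann–Whitney U statistic:

    score = 1 − U / U_max,   U = Σᵢ rᵢ − n(n+1)/2,   U_max = n·r_max − n(n+1)/2

so a signature occupying the top *n* ranks scores exactly 1 and a fully
undetected (capped) signature scores exactly 0. The cap keeps the huge tail
of zero counts typical of sparse single-cell data from swamping the
statistic; set it near the median number of detected genes per cell (the
default, 1500, suits 10x Chromium whole-transcriptome data).

Signatures may carry **positive and negative gene sets**, written with
`+`/`-` suffixes (`CD8A+`, `CD4-`). The sets are scored separately and
combined as

    score = max(0, score⁺ − w·score⁻)        (w = 1 by default)

Genes absent from the matrix are either **imputed as zero counts** (default;
right for filtered whole-transcriptome matrices) or **skipped** (right for
targeted panels such as Xenium/CosMx). Scores can optionally be **smoothed**
over each cell's k nearest neighbors in PCA space with decay weights
(1−λ)ⁱ, and **aggregated per sample** — the recommended unit for statistical
tests, since treating cells as replicates inflates significance.

## Worked example

```python
import numpy as np
from usig import (ExpressionMatrix, ScoringParams, aggregate_scores,
                  parse_signature, score_signatures)

m = ExpressionMatrix(
    gene_ids=["CD8A", "GZMB", "CD4", "SELL", "ACTB"],
    cell_ids=["cell1", "cell2", "cell3"],
    values=np.array([
        [9.0, 0.0, 1.0],
        [7.0, 0.0, 0.0],
        [0.0, 8.0, 2.0],
        [0.0, 5.0, 0.0],
        [4.0, 6.0, 3.0],
    ]),
)
sig = parse_signature("CD8_T", ["CD8A+", "GZMB+", "CD4-"])
table = score_signatures(m, [sig], ScoringParams(r_max=4))
print(table.to_frame())
```

prints

```
         CD8_T_UCell
cell_id
cell1            1.0
cell2            0.0
cell3            0.0
```

`cell1` expresses CD8A and GZMB above everything else and has no CD4, so the
positive set sits at ranks 1–2 (score⁺ = 1) while the negative set is fully
capped (score⁻ = 0): combined score 1. `cell2` is the mirror image. `cell3`
expresses a little CD8A but more CD4, so its weak positive component
(score⁺ = 0.2) is cancelled by the negative component and clips to 0.
Per-sample means for downstream testing:

```python
print(aggregate_scores(table, {"cell1": "sampleA", "cell2": "sampleA", "cell3": "sampleB"}))
#      group signature  mean_score  n_defined  n_cells
# 0  sampleA     CD8_T         0.5          2        2
# 1  sampleB     CD8_T         0.0          1        1
```

The same pipeline is available from the shell:

```sh
usig --input counts_dir/ --signatures "CD8_T=CD8A+,GZMB+,CD4-" \
     --rmax 1500 --smooth --k 10 --lambda 0.1 --output scores.tsv
```

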