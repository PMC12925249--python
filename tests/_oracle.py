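"""Naive reference implementation used as an independent oracle in tests.

Deliberately simple and slow: explicit per-cell sorting with hand-rolled
midrank assignment, literal appending of zero rows for imputed missing
genes, and direct evaluation of the score formulas. Shares no code path
with the package's chunked/vectorized implementation.
"""

from __future__ import annotations

import numpy as np


def naive_desc_midranks(values) -> list[float]:
    """Descending ranks (1 = largest) with midranks for ties, by explicit sort."""
    vals = [float(v) for v in values]
    n = len(vals)
    order = sorted(range(n), key=lambda i: -vals[i])
    ranks = [0.0] * n
    i, pos = 0, 1
    while i < n:
        j = i
        while j < n and vals[order[j]] == vals[order[i]]:
            j += 1
        mid = (pos + pos + (j - i) - 1) / 2.0
        for t in range(i, j):
            ranks[order[t]] = mid
        pos += j - i
        i = j
    return ranks


def _component(ranks: list[float], r_max: int, legacy: bool) -> float:
    n = len(ranks)
    if r_max < n:
        return float("nan")
    umax = n * r_max if legacy else n * r_max - n * (n + 1) / 2.0
    if umax <= 0:
        return float("nan")
    u = sum(min(r, r_max) for r in ranks) - n * (n + 1) / 2.0
    return min(1.0, max(0.0, 1.0 - u / umax))


def naive_scores(
    X: np.ndarray,
    genes: list[str],
    signature,
    r_max: int,
    w: float = 1.0,
    policy: str = "impute_zero",
    legacy: bool = False,
) -> np.ndarray:
    """Score one signature on a dense genes-by-cells array, cell by cell."""
    present = set(genes)
    missing = [s for s in (*signature.positive, *signature.negative) if s not in present]
    if policy == "impute_zero":
        work_genes = list(genes) + missing
        Xw = np.vstack([X] + [np.zeros((1, X.shape[1]))] * len(missing)) if missing else X
        pos_syms = list(signature.positive)
        neg_syms = list(signature.negative)
    else:
        work_genes = list(genes)
        Xw = X
        pos_syms = [s for s in signature.positive if s in present]
        neg_syms = [s for s in signature.negative if s in present]
    idx = {g: i for i, g in enumerate(work_genes)}
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        ranks = naive_desc_midranks(Xw[:, j])
        s_pos = _component([ranks[idx[s]] for s in pos_syms], r_max, legacy) if pos_syms else None
        if s_pos is None:
            out[j] = np.nan
            continue
        if signature.negative:
            if not neg_syms:
                out[j] = s_pos
            else:
                s_neg = _component([ranks[idx[s]] for s in neg_syms], r_max, legacy)
                out[j] = min(1.0, max(0.0, s_pos - w * s_neg))
        else:
            out[j] = s_pos
    return out
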