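"""Independent oracles used across the test suite.

These implementations deliberately share no code path with the package: the
Fisher oracle enumerates the full hypergeometric support with exact integer
binomials, and the naive classifier is a double loop over genes and samples.
"""

from math import comb

import numpy as np


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher exact p by full enumeration (point-probability rule).

    Sums, over every table compatible with the observed margins, the
    hypergeometric probability of those no more probable than the observed
    table (relative tolerance 1e-7 on the comparison).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))
    return min(total, 1.0)


def naive_mes_calls(values, thresholds):
    """Double-loop threshold classifier: values genes x samples, thresholds
    per gene. Returns (scores, is_mes) with the strict-exceed tie rule."""
    n_genes, n_samples = values.shape
    scores = np.zeros(n_samples)
    for j in range(n_samples):
        count = 0
        for i in range(n_genes):
            if values[i, j] > thresholds[i]:
                count += 1
        scores[j] = count / n_genes
    return scores, scores == 1.0


def loop_signature_score(z_values, gene_index, signature_genes):
    """Per-sample mean of signature-gene z-values by explicit loops."""
    rows = [gene_index.index(g) for g in signature_genes]
    n_samples = z_values.shape[1]
    out = np.zeros(n_samples)
    for j in range(n_samples):
        out[j] = sum(z_values[i, j] for i in rows) / len(rows)
    return out
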