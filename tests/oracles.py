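"""Deliberately naive, loop-based reference implementations.

These stay free of numpy vectorization so they remain structurally
independent of the package code they are used to check.
"""

import math
import statistics


def rle_factors_oracle(rows):
    """Median-ratio scale factors for a genes x samples list-of-lists.

    Reference per gene = geometric mean across samples (0 if any count is
    0); raw factor per sample = median(count/reference) / library size;
    factors rescaled to geometric mean 1.
    """
    n_genes = len(rows)
    n_samples = len(rows[0])
    refs = []
    for g in range(n_genes):
        if all(c > 0 for c in rows[g]):
            refs.append(math.exp(sum(math.log(c) for c in rows[g]) / n_samples))
        else:
            refs.append(0.0)
    raw = []
    for j in range(n_samples):
        ratios = [rows[g][j] / refs[g] for g in range(n_genes) if refs[g] > 0]
        lib = sum(rows[g][j] for g in range(n_genes))
        raw.append(statistics.median(ratios) / lib)
    gm = math.exp(sum(math.log(f) for f in raw) / n_samples)
    return [f / gm for f in raw]


def bh_stepup_oracle(pvalues):
    """Benjamini-Hochberg adjusted p-values by direct suffix minimization."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    out = [0.0] * m
    for pos in range(m):
        suffix = [pvalues[order[k]] * m / (k + 1) for k in range(pos, m)]
        out[order[pos]] = min(1.0, min(suffix))
    return out


def composite_score_oracle(expr_rows, gene_index, members, sample):
    """Mean of (x - mean)/sd over member genes for one sample (sd: n-1)."""
    zs = []
    for gene in members:
        row = expr_rows[gene_index[gene]]
        mu = sum(row) / len(row)
        sd = statistics.stdev(row)
        zs.append((row[sample] - mu) / sd)
    return sum(zs) / len(zs)
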