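"""Independent brute-force oracles shared by the test modules."""

import numpy as np
from scipy import stats


def naive_resampler(panel, causal, tag, case_counts, control_counts, observed_p, b, seed):
    """Slow per-individual re-implementation of the constrained resampling null.

    Draws each individual's two haplotypes one by one (conditional on the
    causal allele the assigned genotype implies) and scores the allele 2x2
    table with scipy's contingency test; returns frac_less_significant.
    """
    rng = np.random.default_rng(seed)
    c = panel.column(causal)
    t = panel.column(tag)
    pool0 = t[c == 0]
    pool1 = t[c == 1]
    worse = 0
    for _ in range(b):
        rows = []
        for (n0, n1, n2) in (case_counts, control_counts):
            alleles = 0
            for _i in range(n2):
                alleles += pool1[rng.integers(pool1.size)] + pool1[rng.integers(pool1.size)]
            for _i in range(n1):
                alleles += pool1[rng.integers(pool1.size)] + pool0[rng.integers(pool0.size)]
            for _i in range(n0):
                alleles += pool0[rng.integers(pool0.size)] + pool0[rng.integers(pool0.size)]
            rows.append((alleles, 2 * (n0 + n1 + n2) - alleles))
        table = np.array(rows, dtype=float)
        if (table.sum(axis=0) == 0).any():
            p = 1.0
        else:
            p = stats.chi2_contingency(table, correction=False)[1]
        worse += p > observed_p
    return worse / b
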