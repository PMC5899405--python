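"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the Fisher oracle
enumerates the hypergeometric distribution directly, and the caller oracle
is a straight-line re-evaluation of the filtering thresholds.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided(a: int, b: int, c: int, d: int,
                     rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Conditions on the margins of [[a, b], [c, d]] and sums the
    probabilities of all tables no more likely than the observed one
    (minimum-likelihood convention, with a relative tolerance on the
    probability comparison).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    rv = hypergeom(n, r1, c1)
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())


def caller_oracle(column, min_cov=5, min_mean_mapq=15.0, min_maf=0.1):
    """Direct threshold evaluation of one pileup column.

    Returns the dict of passing alternate alleles, or None when the column
    yields no call.
    """
    if column.ref_base not in "ACGT":
        return None
    if column.depth < min_cov:
        return None
    if column.mean_mapq <= min_mean_mapq:
        return None
    alts = {}
    for base, count in column.base_counts.items():
        if base == column.ref_base or base not in "ACGT":
            continue
        alts[base] = count / column.depth
    if not alts:
        return None
    if max(alts.values()) <= min_maf:
        return None
    return alts
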