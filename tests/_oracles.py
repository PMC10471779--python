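"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_bh(p):
    """Step-up FDR adjustment written from the definition: sort, scale
    each p by m/rank, enforce monotonicity from the largest rank down."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
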