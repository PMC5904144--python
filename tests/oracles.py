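"""Independent brute-force oracles shared across test modules."""

import numpy as np

from knotfactory.freeenergy import f1


def z_multi_oracle(L_list, state, params):
    """Brute-force enumeration over all ordered, non-overlapping placements.

    Independent of the recursive/geometric implementation: every excitation
    tuple (d_1..d_m) is enumerated explicitly and weighted by exp(-sum f1).
    """
    L = np.atleast_1d(np.asarray(L_list, float))
    w = 2.0 * params.g_k(L) / state.r_o
    slack = state.R_c - w.sum()
    if slack < 0:
        return 0.0
    total = 0.0

    def rec(j, prev_end, remaining, fsum):
        nonlocal total
        if j == len(L):
            total += np.exp(-fsum)
            return
        d = 0
        while d * w[j] <= remaining + 1e-12:
            a = prev_end + d * w[j]
            rec(j + 1, a + w[j], remaining - d * w[j],
                fsum + float(f1(L[j], a, state, params)))
            d += 1

    rec(0, 0.0, slack, 0.0)
    return total
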