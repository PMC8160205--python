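"""Independent brute-force oracles shared by the test modules."""

import numpy as np
from scipy import stats as sps


def brute_force_nk_pairs(groups, alpha=0.05):
    """All-pairs studentized-range decisions at each pair's rank span.

    Independent re-derivation of the stepwise procedure's decisions for
    instances without containment ambiguity (well-separated or fully null
    groups): a pair is significant when its range statistic exceeds the
    studentized-range critical value at the span the ordered means place
    between them.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    ns = [len(g) for g in groups]
    means = [g.mean() for g in groups]
    df_e = sum(ns) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_e
    order = np.argsort(means)
    rank = {g: r for r, g in enumerate(order)}
    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            span = abs(rank[i] - rank[j]) + 1
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            if q >= sps.studentized_range.ppf(1 - alpha, span, df_e):
                sig.add((i, j))
    return sig
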