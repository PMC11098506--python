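"""Independent brute-force oracle for the two-sided Mann-Whitney test.

Enumerates every assignment of the pooled observations to the two groups
and accumulates the permutation distribution of U directly; completely
independent of the implementation under test.
"""

from itertools import combinations

import numpy as np


def u_statistic(xs, ys) -> float:
    """U of xs over ys by direct pair counting, with half credit for ties."""
    u = 0.0
    for a in xs:
        for b in ys:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def exact_two_sided_p(x, y) -> float:
    """Two-sided exact p: both permutation tails at and beyond the observed U."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = u_statistic(x, y)
    us = []
    indices = range(n + m)
    for chosen in combinations(indices, n):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in indices if i not in chosen_set]
        us.append(u_statistic(xs, ys))
    us = np.asarray(us)
    lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
    return min(1.0, float(((us <= lo).sum() + (us >= hi).sum()) / len(us)))
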