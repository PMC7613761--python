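"""Independent brute-force oracles used by unit and acceptance tests."""

import math
import statistics

from scipy import stats


def brute_force_esd(values, k_max, alpha=0.05):
    """Straightforward generalized ESD loop, independent of the library path.

    Recomputes mean/sd with the statistics module at every step and keeps
    explicit Python lists. Returns (n_outliers, flagged_indices).
    """
    xs = list(map(float, values))
    n = len(xs)
    remaining = list(enumerate(xs))
    results = []
    removed = []
    for i in range(1, k_max + 1):
        m = len(remaining)
        p = 1.0 - alpha / (2.0 * m)
        df = m - 2
        t = stats.t.ppf(p, df)
        lam = (m - 1) * t / math.sqrt((df + t * t) * m)
        vals = [v for _, v in remaining]
        mu = statistics.fmean(vals)
        sd = statistics.stdev(vals)
        if sd <= 0:
            results.append((0.0, lam))
            continue
        devs = [abs(v - mu) for v in vals]
        best = devs.index(max(devs))
        r = devs[best] / sd
        results.append((r, lam))
        removed.append(remaining[best][0])
        del remaining[best]
    n_outliers = 0
    for i, (r, lam) in enumerate(results, start=1):
        if r > lam:
            n_outliers = i
    return n_outliers, set(removed[:n_outliers])


def bh_stepup(pvalues, alpha):
    """Benjamini-Hochberg step-up rejection set, by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank / m * alpha:
            k_star = rank
    return set(order[:k_star])
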