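"""Independent oracles used by the test suite.

Deliberately naive implementations — explicit loops and exhaustive
enumeration — kept separate from the library code paths they check.
"""

import numpy as np


def naive_fold_q(x, period_bins: int) -> float:
    """Chi-squared periodogram statistic by explicit fold-and-score loops."""
    x = np.asarray(x, dtype=float)
    K = len(x) // period_bins
    used = x[: K * period_bins]
    grand = used.mean()
    col_means = []
    for h in range(period_bins):
        col = [used[c * period_bins + h] for c in range(K)]
        col_means.append(np.mean(col))
    num = K * sum((m - grand) ** 2 for m in col_means)
    var = sum((v - grand) ** 2 for v in used) / len(used)
    return num / var


def exhaustive_best_path_logprob(spec, obs) -> float:
    """Maximum joint log-probability over all n_states**L state paths.

    Enumerates every path (chunked, vectorized) — tractable for L <= 12
    with 4 states.
    """
    obs = np.asarray(obs, dtype=int)
    L = len(obs)
    S = spec.n_states
    with np.errstate(divide="ignore"):
        logA = np.log(spec.transmat)
        logB = np.log(spec.emissionprob)
        logpi = np.log(spec.startprob)
    total = S ** L
    chunk = min(total, 4 ** 8)
    best = -np.inf
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        # digits of idx base S give the path, most significant = t0
        paths = np.empty((len(idx), L), dtype=np.int64)
        rem = idx.copy()
        for t in range(L - 1, -1, -1):
            paths[:, t] = rem % S
            rem //= S
        lp = logpi[paths[:, 0]] + logB[paths[:, 0], obs[0]]
        for t in range(1, L):
            lp = lp + logA[paths[:, t - 1], paths[:, t]]
            lp = lp + logB[paths[:, t], obs[t]]
        m = lp.max()
        if m > best:
            best = m
    return float(best)
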