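"""Independent brute-force oracles shared across test modules."""

import numpy as np


def exhaustive_step_fit(biomarker, response, pp):
    """Scan every proper split of the sorted cohort, recompute the two-level
    step fit and its SSE from scratch, minimize, then apply the
    above-fraction constraint to the winning split."""
    x = np.asarray(biomarker, dtype=float)
    y = np.asarray(response, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    best = None
    for k in range(1, n):
        if x[k] == x[k - 1]:
            continue
        below, above = y[:k], y[k:]
        fitted = np.concatenate((np.full(k, below.mean()), np.full(n - k, above.mean())))
        sse = float(np.sum((y - fitted) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, 0.5 * (x[k - 1] + x[k]), k)
    if best is None:
        return None
    sse, cutoff, k = best
    if (n - k) / n < pp:
        return None
    return {
        "sse": sse,
        "cutoff": cutoff,
        "n_plus": n - k,
        "r_plus": int(y[k:].sum()),
        "n_minus": k,
        "r_minus": int(y[:k].sum()),
    }
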