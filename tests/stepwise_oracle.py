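"""Naive reference stepwise regression used as an independent oracle.

Recomputes every residual sum of squares from scratch with lstsq on the
raw design matrices (no Gram-matrix shortcuts), mirroring the textbook
procedure: add the smallest-p entrant below the entry threshold, else
remove the largest-p incumbent above the removal threshold, else stop;
min-p fallback if nothing was ever selected.
"""

import numpy as np
from scipy import stats


def naive_stepwise(X, y, p_enter=0.05, p_remove=0.1, max_steps=100):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape

    def rss(cols):
        Z = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        return float(resid @ resid)

    def pval(r_red, r_full, k_full):
        dfden = n - k_full - 1
        if dfden <= 0 or r_full <= 0:
            return 1.0 if r_red <= r_full else 0.0
        f = max((r_red - r_full) / (r_full / dfden), 0.0)
        return float(stats.f.sf(f, 1, dfden))

    selected, first_step = [], None
    for _ in range(max_steps):
        cur = rss(selected)
        entry = {j: pval(cur, rss(selected + [j]), len(selected) + 1)
                 for j in range(m) if j not in selected}
        if first_step is None:
            first_step = dict(entry)
        if entry:
            j = min(entry, key=lambda j: (entry[j], j))
            if entry[j] < p_enter:
                selected.append(j)
                continue
        removal = {j: pval(rss([k for k in selected if k != j]), cur,
                           len(selected)) for j in selected}
        if removal:
            j = max(selected, key=lambda j: (removal[j], -j))
            if removal[j] > p_remove:
                selected.remove(j)
                continue
        break
    if not selected:
        selected = [min(first_step, key=lambda j: (first_step[j], j))]
    return selected
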