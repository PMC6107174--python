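"""Independent brute-force multifractal estimator used as a test oracle.

Deliberately naive: plain Python loops, direct powers (so only moderate
|q| is safe), and scipy.stats.linregress per q.  It shares no code with
the package implementation.
"""

import numpy as np
from scipy import stats


def naive_slopes(u, scales, q_values):
    """Return (alpha, f, r_alpha, r_f) arrays via direct evaluation."""
    u = np.asarray(u, dtype=float)
    alphas, fs, r_as, r_fs = [], [], [], []
    for q in q_values:
        ys_f, ys_a, xs = [], [], []
        for L in scales:
            n_bins = len(u) // L
            sums = [u[i * L : (i + 1) * L].sum() for i in range(n_bins)]
            total = sum(sums)
            P = [s / total for s in sums]
            Ppos = [p for p in P if p > 0]
            if len(Ppos) < len(P) and q <= 0:
                continue
            Z = sum(p**q for p in Ppos)
            mu = [p**q / Z for p in Ppos]
            ys_f.append(sum(m * np.log(m) for m in mu))
            ys_a.append(sum(m * np.log(p) for m, p in zip(mu, Ppos)))
            xs.append(np.log(L))
        if len(xs) < 3:
            alphas.append(np.nan); fs.append(np.nan)
            r_as.append(0.0); r_fs.append(0.0)
            continue
        reg_f = stats.linregress(xs, ys_f)
        reg_a = stats.linregress(xs, ys_a)
        fs.append(reg_f.slope)
        alphas.append(reg_a.slope)
        r_fs.append(reg_f.rvalue)
        r_as.append(reg_a.rvalue)
    return (np.array(alphas), np.array(fs), np.array(r_as), np.array(r_fs))
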