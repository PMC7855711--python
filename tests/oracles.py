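"""Independent brute-force oracles for the statistical primitives.

Deliberately coded from the textbook formulas, separate from the
implementation paths in cernax.stats, so that agreement between the two
routes is meaningful.
"""

import math

import numpy as np
from scipy.stats import t as t_dist


def pearson_oracle(x, y):
    """Direct covariance/variance evaluation + t-transform p-value."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * t_dist.sf(abs(t), df=n - 2)
    return r, p


def bh_oracle(pvalues):
    """Literal step-up formula q_i = min_{j>=i}(m p_(j) / j) over sorted p."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q


def pooled_t_oracle(a, b):
    """Two-sample pooled-variance Student t with its two-sided p."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), df=df)
    return t, p


def paired_t_oracle(a, b):
    """One-sample t on within-pair differences."""
    d = [float(x) - float(y) for x, y in zip(a, b)]
    n = len(d)
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return t, p


def anova_two_group_oracle(a, b):
    """One-way ANOVA F from between/within sums of squares (two groups)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grand = np.concatenate([a, b]).mean()
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    dfb = 1
    dfw = a.size + b.size - 2
    return (ssb / dfb) / (ssw / dfw)
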