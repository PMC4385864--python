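"""Independent brute-force reference implementations used only by tests.

Each oracle is built directly from the defining formula (rank sorting,
pair enumeration, hypergeometric event tables, Newton-Raphson on the
partial likelihood) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def average_ranks(x):
    """Average ranks computed by explicit sorting and tie grouping."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # mean of positions i..j, 1-based
        i = j + 1
    return ranks


def pearson_bf(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def spearman_bf(x, y):
    """Pearson correlation of average ranks."""
    return pearson_bf(average_ranks(x), average_ranks(y))


def kendall_taub_bf(x, y):
    """Tau-b by explicit enumeration of all pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tie_x = tie_y = tie_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tie_both += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    n1 = tie_x + tie_both
    n2 = tie_y + tie_both
    return float((conc - disc) / np.sqrt((n0 - n1) * (n0 - n2)))


def logrank_two_group_bf(time, event, group):
    """Two-group log-rank statistic from per-event-time 2x2 tables.

    At each distinct event time t: a hypergeometric table with n1 at risk
    in group 1 of n total and d events; O-E and variance accumulate over
    tables.  Returns the chi-square statistic.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    g1 = group == labels[0]
    oe = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(oe**2 / var)


def cox_univariate_nr(time, event, x, n_iter=30):
    """Univariate Cox fit by Newton-Raphson on the partial likelihood.

    Breslow handling of ties (equals Efron on tie-free data).  Returns
    (beta, se).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    t, e, xv = time[order], event[order], x[order]
    beta = 0.0
    for _ in range(n_iter):
        w = np.exp(beta * xv)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xv)
        s2 = np.cumsum(w * xv * xv)
        # risk set of an event at t_i = all with time >= t_i: last index with that time
        idx = np.searchsorted(-t, -t, side="right") - 1
        ev = e == 1
        r0, r1, r2 = s0[idx][ev], s1[idx][ev], s2[idx][ev]
        score = (xv[ev] - r1 / r0).sum()
        info = (r2 / r0 - (r1 / r0) ** 2).sum()
        step = score / info
        beta += step
        if abs(step) < 1e-12:
            break
    w = np.exp(beta * xv)
    s0, s1, s2 = np.cumsum(w), np.cumsum(w * xv), np.cumsum(w * xv * xv)
    idx = np.searchsorted(-t, -t, side="right") - 1
    ev = e == 1
    r0, r1, r2 = s0[idx][ev], s1[idx][ev], s2[idx][ev]
    info = (r2 / r0 - (r1 / r0) ** 2).sum()
    return float(beta), float(1.0 / np.sqrt(info))


def km_product_limit_bf(time, event):
    """Kaplan-Meier by the textbook product over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = {}
    s = 1.0
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out[float(t)] = s
    return out
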