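"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions directly, without reusing
any package internals, so agreement with the package is a genuine
two-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Classification (straight from the defining formulas)
# ---------------------------------------------------------------------------

def present_mean_oracle(series) -> float:
    s = list(series)
    n_present = sum(1 for v in s if v > 0)
    return sum(s) / n_present


def cv_oracle(series) -> float:
    s = list(series)
    m = present_mean_oracle(s)
    sq = sum((v - m) ** 2 for v in s)
    return math.sqrt(sq / (len(s) - 1)) / m


def classify_taxon_oracle(row, before_idx, during_idx, after_idx, alpha=0.05,
                          ha=0.01, la=0.001):
    """All four labels for one taxon, by direct evaluation of the rules."""
    row = list(row)
    b = [row[i] for i in before_idx]
    d = [row[i] for i in during_idx]
    a = [row[i] for i in after_idx]

    mean_all = sum(row) / len(row)
    if mean_all > ha:
        abundance = "HA"
    elif mean_all >= la:
        abundance = "LA"
    else:
        abundance = "RA"

    presence = "Core" if all(v > 0 for v in row) else "Ncore"

    if not any(v > 0 for v in b) or not any(v > 0 for v in a):
        stability = "NC"
    else:
        var_b = float(np.var(b, ddof=1))
        var_a = float(np.var(a, ddof=1))
        if var_b == 0 and var_a == 0:
            stability = "NC"
        elif var_b == 0 or var_a == 0:
            stability = "BS" if cv_oracle(b) >= cv_oracle(a) else "BV"
        else:
            f = var_b / var_a
            dist = stats.f(len(b) - 1, len(a) - 1)
            p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
            if p > alpha:
                stability = "NC"
            else:
                stability = "BS" if cv_oracle(b) >= cv_oracle(a) else "BV"

    if (
        not d
        or not any(v > 0 for v in b)
        or not any(v > 0 for v in d)
        or not any(v > 0 for v in a)
    ):
        response = "neither"
    else:
        mb, md, ma = (present_mean_oracle(w) for w in (b, d, a))
        if md > mb and md > ma:
            response = "induced"
        elif md < mb and md < ma:
            response = "repressed"
        else:
            response = "neither"
    return abundance, presence, stability, response


# ---------------------------------------------------------------------------
# Graph centralities
# ---------------------------------------------------------------------------

def betweenness_oracle(nodes, edges):
    """Unnormalized directed betweenness by exhaustive simple-path search.

    For every ordered pair (s, t) all simple paths are enumerated, the
    shortest length found, and each intermediate node of each shortest
    path credited with 1/sigma_st.
    """
    nodes = list(nodes)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        # enumerate all simple paths s -> t
        paths = []
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                paths.append(path)
                continue
            for w in adj[u]:
                if w not in path:
                    stack.append((w, path + [w]))
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


# ---------------------------------------------------------------------------
# Two-phase test (direct distribution formulas)
# ---------------------------------------------------------------------------

def two_phase_oracle(before, after, alpha=0.05, direction="greater"):
    """F-then-t p-values computed from the raw statistic formulas."""
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    nb, na = len(b), len(a)
    vb, va = b.var(ddof=1), a.var(ddof=1)
    fdist = stats.f(nb - 1, na - 1)
    f = vb / va
    f_p = min(1.0, 2.0 * min(fdist.cdf(f), fdist.sf(f)))
    diff = a.mean() - b.mean()
    if f_p > alpha:
        sp2 = ((nb - 1) * vb + (na - 1) * va) / (nb + na - 2)
        se = math.sqrt(sp2 * (1 / nb + 1 / na))
        df = nb + na - 2
    else:
        se = math.sqrt(vb / nb + va / na)
        df = (vb / nb + va / na) ** 2 / (
            (vb / nb) ** 2 / (nb - 1) + (va / na) ** 2 / (na - 1)
        )
    t = diff / se
    if direction == "greater":
        t_p = stats.t.sf(t, df)
    else:
        t_p = stats.t.cdf(t, df)
    return float(f_p), float(t_p)
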