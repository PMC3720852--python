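"""Independent reference implementations used only to cross-check the
package.  These deliberately avoid the library's own code paths: the
promoter oracle enumerates every placement naively, the alignment oracle is
a plain Needleman-Wunsch matrix, the Mann-Whitney oracle enumerates rank
arrangements, and the Kruskal-Wallis oracle computes mid-ranks by hand."""

from itertools import combinations

import numpy as np

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _mismatches(consensus, observed):
    strong = weak = 0
    for c, o in zip(consensus, observed.upper()):
        if o not in _IUPAC[c.upper()]:
            if c.isupper():
                strong += 1
            else:
                weak += 1
    return strong, weak


def brute_scan(upstream, motifs, policy):
    """Every (-35, -10) placement passing the policy, as a set of tuples
    (sigma, minus35, minus10, spacing, dist_to_start, source)."""
    up = upstream.upper()
    found = set()
    for m in motifs:
        n35, n10 = len(m.minus35), len(m.minus10)
        for i35 in range(len(up) - n35 + 1):
            for i10 in range(len(up) - n10 + 1):
                spacing = i10 - (i35 + n35)
                if not (policy.spacing_min <= spacing <= policy.spacing_max):
                    continue
                o35 = up[i35:i35 + n35]
                o10 = up[i10:i10 + n10]
                s35, w35 = _mismatches(m.minus35, o35)
                s10, w10 = _mismatches(m.minus10, o10)
                if (s35 <= policy.max_strong_mismatch
                        and w35 <= policy.max_weak_mismatch
                        and s10 <= policy.max_strong_mismatch
                        and w10 <= policy.max_weak_mismatch):
                    found.add((m.sigma_label, o35.lower(), o10.lower(),
                               spacing, len(up) - (i10 + n10), m.source))
    return found


def best_window(seq, consensus):
    """Exhaustive best-identity ungapped window (ties -> smallest offset)."""
    k = len(consensus)
    scores = [
        (sum(a == b for a, b in zip(seq[off:off + k], consensus)), -off)
        for off in range(len(seq) - k + 1)
    ]
    score, negoff = max(scores)
    return -negoff, score


def nw_score(a, b, match=1, mismatch=0, gap=-1):
    """Optimal global alignment score by a plain DP matrix."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = gap * np.arange(n + 1)
    dp[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = dp[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            dp[i, j] = max(diag, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return float(dp[n, m])


def mwu_exact_p(x, y, alternative):
    """Exact one-tailed Mann-Whitney p by enumerating all rank arrangements.
    Assumes no ties."""
    x, y = list(x), list(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    nx, n = len(x), len(x) + len(y)
    us = []
    for idx in combinations(range(n), nx):
        chosen = set(idx)
        us.append(sum(1 for i in idx for j in range(n)
                      if j not in chosen and i > j))
    if alternative == "less":
        count = sum(1 for u in us if u <= u_obs)
    elif alternative == "greater":
        count = sum(1 for u in us if u >= u_obs)
    else:
        raise ValueError(alternative)
    return count / len(us)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def kruskal_h(groups):
    """Kruskal-Wallis H with tie correction, from first principles."""
    pooled = [v for g in groups for v in g]
    ranks = _midranks(pooled)
    n = len(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        rsum = sum(ranks[pos:pos + len(g)])
        h += rsum ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1 - sum(t ** 3 - t for t in counts.values()) / (n ** 3 - n)
    return h / correction
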