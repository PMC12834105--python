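"""Independent brute-force oracles used to cross-check the implementations.

Everything here is deliberately written in plain loops, straight from the
published definitions, and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def wc_fst_brute(d1, d2):
    """Two-population Weir & Cockerham (1984) theta, coded with explicit loops.

    ``d1``/``d2`` are (individuals x loci) diploid dosage arrays without
    missing data. Loci monomorphic in the pooled sample are skipped.
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    r = 2
    num = 0.0
    den = 0.0
    for locus in range(d1.shape[1]):
        g1 = list(d1[:, locus])
        g2 = list(d2[:, locus])
        pooled = g1 + g2
        if sum(pooled) in (0, 2 * len(pooled)):
            continue  # monomorphic in the pooled pair
        n1, n2 = len(g1), len(g2)
        p1 = sum(g1) / (2 * n1)
        p2 = sum(g2) / (2 * n2)
        h1 = sum(1 for g in g1 if g == 1) / n1
        h2 = sum(1 for g in g2 if g == 1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            ssq - (pbar * (1 - pbar) - ssq * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ssq * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    if den == 0:
        raise ValueError("no usable loci")
    return num / den


def bh_brute(pvals):
    """Benjamini-Hochberg step-up q-values by the textbook recipe."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


def _pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def mantel_exhaustive_brute(X, Y, alternative="greater"):
    """Exact Mantel p by enumerating every simultaneous row/column relabeling."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i)]
    yv = [Y[i][j] for i, j in pairs]
    r_obs = _pearson([X[i][j] for i, j in pairs], yv)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        xp = [X[perm[i]][perm[j]] for i, j in pairs]
        r = _pearson(xp, yv)
        if alternative == "greater":
            hits += r >= r_obs - 1e-12
        else:
            hits += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return r_obs, hits / total


def heterozygosity_brute(dosages):
    """Per-individual het fraction by explicit counting (missing = -1)."""
    out = []
    for row in np.asarray(dosages):
        het = sum(1 for g in row if g == 1)
        called = sum(1 for g in row if g in (0, 1, 2))
        out.append(het / called if called else float("nan"))
    return out


def load_brute(dosages, vclasses, ancestral_is_alt, dfreq, include_lof=False):
    """Per-individual load metrics by explicit scanning.

    ``dosages``: (individuals x sites), -1 missing; ``ancestral_is_alt``:
    per-site bool (ancestral allele is the alt allele); ``dfreq``: per-site
    population derived frequency, NaN = unpolarized.
    """
    res = []
    for row in np.asarray(dosages):
        Pn = Ps = 0
        fn = []
        fs = []
        lof = 0.0
        for j, g in enumerate(row):
            if math.isnan(dfreq[j]) or g == -1:
                continue
            dd = 2 - g if ancestral_is_alt[j] else g
            cls = vclasses[j]
            carrier = dd >= 1
            if cls == "SYN" and carrier:
                Ps += 1
                fs.append(dfreq[j])
            nonsyn = cls == "NONSYN" or (include_lof and cls == "LOF")
            if nonsyn and carrier:
                Pn += 1
                fn.append(dfreq[j])
            if cls == "LOF":
                lof += dd
        fn_bar = sum(fn) / len(fn) if fn else float("nan")
        fs_bar = sum(fs) / len(fs) if fs else float("nan")
        ratio = Pn / (Pn + Ps) if Pn + Ps else float("nan")
        freq_ratio = (
            (Pn * fn_bar) / (Ps * fs_bar) if Ps and fs and fs_bar > 0 else float("nan")
        )
        res.append((Pn, Ps, fn_bar, fs_bar, ratio, freq_ratio, lof))
    return res
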