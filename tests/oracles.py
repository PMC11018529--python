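"""Independent brute-force oracles used by the tests.

Everything here is written as plain scalar loops, deliberately sharing no
code path with the package implementations it checks.
"""

import math

import numpy as np


def naive_classify(vector, points):
    """Scalar-loop nearest-ideal-point scan (first minimum wins)."""
    best_cat, best_d = None, None
    for cat, p in points.items():
        d = 0.0
        for a, b in zip(vector, p):
            d += (a - b) ** 2
        d = math.sqrt(d)
        if best_d is None or d < best_d - 1e-12:
            best_cat, best_d = cat, d
    return best_cat, best_d


def naive_bicor(x, y, max_p_outliers=0.05):
    """Scalar-loop biweight midcorrelation with the per-tail outlier cap."""

    def transform(v):
        med = float(np.median(v))
        mad = float(np.median([abs(a - med) for a in v]))
        u = [(a - med) / (9.0 * mad) for a in v]
        if 0 < max_p_outliers < 0.5:
            q_lo = float(np.quantile(v, max_p_outliers))
            q_hi = float(np.quantile(v, 1.0 - max_p_outliers))
            u_lo = (q_lo - med) / (9.0 * mad)
            u_hi = (q_hi - med) / (9.0 * mad)
            if u_lo < -1.0:
                u = [ui / abs(u_lo) if ui < 0 else ui for ui in u]
            if u_hi > 1.0:
                u = [ui / u_hi if ui > 0 else ui for ui in u]
        out = []
        for a, ui in zip(v, u):
            w = (1.0 - ui * ui) ** 2 if abs(ui) < 1.0 else 0.0
            out.append((a - med) * w)
        return out

    xt = transform(list(x))
    yt = transform(list(y))
    num = sum(a * b for a, b in zip(xt, yt))
    den = math.sqrt(sum(a * a for a in xt) * sum(b * b for b in yt))
    return num / den


def naive_tom(adjacency):
    """Triple-loop unsigned topological overlap."""
    a = np.asarray(adjacency, dtype=float).copy()
    n = a.shape[0]
    for i in range(n):
        a[i, i] = 0.0
    k = [sum(a[i, u] for u in range(n)) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def naive_scale_free_choice(corr, powers, target_fit, n_bins=10):
    """Re-derive the soft-power rule with its own binning and OLS loops.

    Returns the chosen power (first to reach target; else argmax of fit).
    """

    def fit_index(k):
        k = [v for v in k if v > 0]
        if len(k) < 3 or max(k) == min(k):
            return None
        lo, hi = min(k), max(k)
        width = (hi - lo) / n_bins
        sums = [0.0] * n_bins
        cnts = [0] * n_bins
        for v in k:
            b = min(int((v - lo) / width), n_bins - 1) if width > 0 else 0
            sums[b] += v
            cnts[b] += 1
        xs, ys = [], []
        for b in range(n_bins):
            if cnts[b] == 0:
                continue
            xs.append(math.log10(sums[b] / cnts[b]))
            ys.append(math.log10(cnts[b] / len(k)))
        if len(xs) < 3:
            return None
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        sxx = sum((x - mx) ** 2 for x in xs)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        syy = sum((y - my) ** 2 for y in ys)
        if sxx == 0 or syy == 0:
            return None
        slope = sxy / sxx
        r2 = sxy * sxy / (sxx * syy)
        return r2 if slope < 0 else -r2

    c = np.asarray(corr, dtype=float)
    n = c.shape[0]
    fits = {}
    for p in powers:
        k = []
        for i in range(n):
            s = 0.0
            for j in range(n):
                if i != j and c[i, j] > 0:
                    s += c[i, j] ** p
            k.append(s)
        f = fit_index(k)
        if f is not None:
            fits[p] = f
            if f >= target_fit:
                return p
    return max(fits, key=fits.get)


def rand_index(a, b):
    """Plain Rand index between two label vectors."""
    a, b = list(a), list(b)
    n = len(a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    return agree / total
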