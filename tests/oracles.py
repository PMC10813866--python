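"""Independent brute-force oracles, written straight from definitions.

Everything here is deliberately naive — plain Python loops and dicts,
no shared code with the package — so that agreement with the vectorized
implementations is meaningful.
"""

import math


def cooccurrence_bruteforce(levels, offset, n_gray):
    """Symmetric normalized GLCM by explicit pair enumeration."""
    h = len(levels)
    w = len(levels[0])
    dr, dc = offset
    mat = [[0.0] * n_gray for _ in range(n_gray)]
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = levels[r][c], levels[r2][c2]
                mat[a][b] += 1
                mat[b][a] += 1
                total += 2
    for i in range(n_gray):
        for j in range(n_gray):
            mat[i][j] /= total
    return mat


def haralick_bruteforce(p):
    """The 13 classic GLCM statistics via explicit loops (log base 2)."""
    ng = len(p)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j] = p_sum.get(i + j, 0.0) + p[i][j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i][j]

    def ent(values):
        return -sum(v * math.log2(v) for v in values if v > 0)

    out = {}
    out["energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    out["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = (
            sum(i * j * p[i][j] for i in range(ng) for j in range(ng)) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    out["inverse_difference_moment"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    sa = sum(k * v for k, v in p_sum.items())
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["sum_entropy"] = ent(p_sum.values())
    hxy = ent([p[i][j] for i in range(ng) for j in range(ng)])
    out["entropy"] = hxy
    md = sum(k * v for k, v in p_diff.items())
    out["difference_variance"] = sum((k - md) ** 2 * v for k, v in p_diff.items())
    out["difference_entropy"] = ent(p_diff.values())
    hx = ent(px)
    hy = ent(py)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if px[i] * py[j] > 0)
    out["IMC1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["IMC2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


def ks_statistic_bruteforce(a, b):
    """Two-sample KS D by sweeping the ECDF over every sample point."""
    pts = sorted(set(a) | set(b))
    d = 0.0
    for x in pts:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def bh_qvalues_bruteforce(pvals):
    """Benjamini-Hochberg step-up q-values, by the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def spearman_bruteforce(x, y):
    """Spearman rho = Pearson correlation of average ranks."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
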