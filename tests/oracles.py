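"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as naive loops over the defining
formulas, sharing no code path with the package.
"""

import numpy as np


def unfold_loops(x, mode):
    """Mode-n unfolding by walking indices: lower-numbered remaining mode fastest."""
    n1, n2, n3 = x.shape
    dims = [n1, n2, n3]
    rest = [m for m in range(3) if m != mode - 1]
    out = np.zeros((dims[mode - 1], dims[rest[0]] * dims[rest[1]]))
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                idx = [i, j, k]
                r = idx[mode - 1]
                c = idx[rest[0]] + dims[rest[0]] * idx[rest[1]]
                out[r, c] = x[i, j, k]
    return out


def tucker_sum_loops(core, u1, u2, u3):
    """Direct evaluation of the Tucker sum x_ijk = sum G(l1,l2,l3) u1 u2 u3."""
    n, m, k = u1.shape[0], u2.shape[0], u3.shape[0]
    r1, r2, r3 = core.shape
    x = np.zeros((n, m, k))
    for i in range(n):
        for j in range(m):
            for kk in range(k):
                acc = 0.0
                for l1 in range(r1):
                    for l2 in range(r2):
                        for l3 in range(r3):
                            acc += core[l1, l2, l3] * u1[i, l1] * u2[j, l2] * u3[kk, l3]
                x[i, j, kk] = acc
    return x


def bh_stepup(p):
    """Benjamini-Hochberg step-up: adjusted_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        # adjusted can never fall below the raw P; guards fp rounding of p*m/m
        adjusted_sorted[rank - 1] = max(running, p[order[rank - 1]])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def gram_loops(layers):
    """Eq-style triple loop: x[j, j', k] = sum_i layer_k[i, j] * layer_k[i, j']."""
    m = layers[0].shape[1]
    out = np.zeros((m, m, len(layers)))
    for k, x in enumerate(layers):
        for j in range(m):
            for jp in range(m):
                acc = 0.0
                for i in range(x.shape[0]):
                    acc += x[i, j] * x[i, jp]
                out[j, jp, k] = acc
    return out


def project_loops(layer, u):
    """Back-projection double loop: score_i = sum_j u_j * x[i, j]."""
    n, m = layer.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            out[i] += u[j] * layer[i, j]
    return out


def spearman_abs(v, levels):
    """Absolute Spearman correlation via explicit average ranks + Pearson."""
    def ranks(a):
        a = np.asarray(a, dtype=float)
        order = np.argsort(a, kind="stable")
        r = np.empty(a.size)
        i = 0
        while i < a.size:
            j = i
            while j + 1 < a.size and a[order[j + 1]] == a[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rv, rl = ranks(v), ranks(levels)
    rv = rv - rv.mean()
    rl = rl - rl.mean()
    denom = np.sqrt((rv**2).sum() * (rl**2).sum())
    if denom == 0:
        return 0.0
    return abs(float((rv * rl).sum() / denom))


def f1_score(predicted, truth):
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)
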