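"""Independent brute-force oracles for the agreement statistics.

Each function implements the defining formula directly with plain Python
loops, deliberately sharing no code path with the package implementations.
"""

import math


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _midranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(_midranks(list(x)), _midranks(list(y)))


def rmse_oracle(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / len(x))


def weighted_kappa_oracle(a, b, k):
    """Direct double summation of kappa = 1 - sum(w O)/sum(w E)."""
    n = len(a)
    obs = [[0.0] * k for _ in range(k)]
    for i, j in zip(a, b):
        obs[i][j] += 1.0 / n
    row = [sum(obs[i][j] for j in range(k)) for i in range(k)]
    col = [sum(obs[i][j] for i in range(k)) for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / (k - 1) ** 2
            num += w * obs[i][j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


def bland_altman_oracle(x, y):
    n = len(x)
    d = [a - b for a, b in zip(x, y)]
    bias = sum(d) / n
    var = sum((v - bias) ** 2 for v in d) / (n - 1)
    sd = math.sqrt(var)
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def flood_fill_count(mask, connectivity=8):
    """Count connected components by explicit BFS flood fill."""
    h, w = mask.shape
    seen = [[False] * w for _ in range(h)]
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r][c] and not seen[r][c]:
                count += 1
                stack = [(r, c)]
                seen[r][c] = True
                while stack:
                    cr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr][nc] and not seen[nr][nc]:
                            seen[nr][nc] = True
                            stack.append((nr, nc))
    return count
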