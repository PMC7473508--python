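"""Independent brute-force oracles used by the tests.

Everything here is written as literal formula transcriptions with plain
Python loops over dense matrices — deliberately slow and unrelated to the
vectorized implementations under test.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def entropy_bits(ps) -> float:
    return -sum(p * math.log2(p) for p in ps if p > 0)


# ---------------------------------------------------------------- first order

def first_order_oracle(levels: np.ndarray, L: int) -> dict[str, float]:
    x = [float(v) for v in levels.ravel()]
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1)) if n > 1 else 0.0
    hist = [0] * L
    for v in levels.ravel():
        hist[int(v)] += 1
    entropy = entropy_bits([h / n for h in hist])
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    pairs = [(float(levels[i, j]), float(levels[i, j + 1]))
             for i in range(levels.shape[0])
             for j in range(levels.shape[1] - 1)]
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    sa = math.sqrt(sum((v - ma) ** 2 for v in a))
    sb = math.sqrt(sum((v - mb) ** 2 for v in b))
    if sa == 0 or sb == 0:
        corr = 0.0
    else:
        corr = sum((u - ma) * (v - mb) for u, v in pairs) / (sa * sb)
    return {"Mean": mean, "Std": std, "Entropy": entropy, "Kurtosis": kurt,
            "Skewness": skew, "Correlation": corr}


# ----------------------------------------------------------------------- GLCM

def glcm_counts_oracle(levels: np.ndarray, L: int, direction: int,
                       distance: int = 1, symmetric: bool = True) -> np.ndarray:
    dr, dc = OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    h, w = levels.shape
    counts = np.zeros((L, L), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def glcm_features_oracle(counts: np.ndarray) -> dict[str, float]:
    L = counts.shape[0]
    total = counts.sum()
    p = counts / total
    px = [p[i, :].sum() for i in range(L)]
    py = [p[:, j].sum() for j in range(L)]

    mu_x = sum((i + 1) * px[i] for i in range(L))
    mu_y = sum((j + 1) * py[j] for j in range(L))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(L))

    entropy = entropy_bits(p.ravel())
    if var_x > 0:
        skew = sum((i + 1 - mu_x) ** 3 * px[i] for i in range(L)) / var_x**1.5
        kurt = sum((i + 1 - mu_x) ** 4 * px[i] for i in range(L)) / var_x**2
    else:
        skew, kurt = 0.0, 0.0

    autocorr = sum((i + 1) * (j + 1) * p[i, j]
                   for i in range(L) for j in range(L))
    if var_x > 0 and var_y > 0:
        corr = (autocorr - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        corr = 0.0

    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    dissim = sum(abs(i - j) * p[i, j] for i in range(L) for j in range(L))
    homog = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    inv_diff = sum(p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    idn = sum(p[i, j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L))
    idmn = sum(p[i, j] / (1 + (i - j) ** 2 / L**2)
               for i in range(L) for j in range(L))
    variance = sum((i + 1 - mu_x) ** 2 * p[i, j]
                   for i in range(L) for j in range(L))
    shade = sum((i + j + 2 - mu_x - mu_y) ** 3 * p[i, j]
                for i in range(L) for j in range(L))
    prom = sum((i + j + 2 - mu_x - mu_y) ** 4 * p[i, j]
               for i in range(L) for j in range(L))
    max_prob = p.max()

    p_sum = {}
    p_diff = {}
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i, j]
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    sum_ent = entropy_bits(p_sum.values())
    mu_d = sum(k * v for k, v in p_diff.items())
    diff_var = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    diff_ent = entropy_bits(p_diff.values())

    hx = entropy_bits(px)
    hy = entropy_bits(py)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(L) for j in range(L) if p[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - entropy))
    imc2 = math.sqrt(min(max(arg, 0.0), 1.0))

    return {
        "Entropy": entropy, "Kurtosis": kurt, "Skewness": skew,
        "Correlation": corr, "Contrast": contrast, "Variance": variance,
        "SumAverage": sum_avg, "SumVariance": sum_var, "SumEntropy": sum_ent,
        "DifferenceVariance": diff_var, "DifferenceEntropy": diff_ent,
        "IMC1": imc1, "IMC2": imc2, "Autocorrelation": autocorr,
        "Dissimilarity": dissim, "Homogeneity": homog,
        "ClusterProminence": prom, "ClusterShade": shade,
        "MaximumProbability": max_prob, "InverseDifference": inv_diff,
        "InverseDifferenceNormalized": idn,
        "InverseDifferenceMomentNormalized": idmn,
    }


# ----------------------------------------------------------------------- GLRL

def glrl_lines_oracle(levels: np.ndarray, direction: int) -> list[list[int]]:
    h, w = levels.shape
    lines = []
    if direction == 0:
        lines = [[int(levels[r, c]) for c in range(w)] for r in range(h)]
    elif direction == 90:
        lines = [[int(levels[r, c]) for r in range(h)] for c in range(w)]
    elif direction == 45:
        for s in range(h + w - 1):          # r + c = s, r descending
            lines.append([int(levels[r, s - r])
                          for r in range(h - 1, -1, -1) if 0 <= s - r < w])
    elif direction == 135:
        for d in range(-(h - 1), w):        # c - r = d
            lines.append([int(levels[r, r + d])
                          for r in range(h) if 0 <= r + d < w])
    return [ln for ln in lines if ln]


def glrl_features_oracle(levels: np.ndarray, L: int,
                         direction: int) -> dict[str, float]:
    runs = []  # (level, length)
    for line in glrl_lines_oracle(levels, direction):
        cur, length = line[0], 1
        for v in line[1:]:
            if v == cur:
                length += 1
            else:
                runs.append((cur, length))
                cur, length = v, 1
        runs.append((cur, length))
    n_r = len(runs)
    n_p = levels.size
    assert sum(l for _, l in runs) == n_p
    runs_per_level = {}
    runs_per_length = {}
    for g, l in runs:
        runs_per_level[g] = runs_per_level.get(g, 0) + 1
        runs_per_length[l] = runs_per_length.get(l, 0) + 1
    return {
        "SRE": sum(c / l**2 for l, c in runs_per_length.items()) / n_r,
        "LRE": sum(c * l**2 for l, c in runs_per_length.items()) / n_r,
        "GLN": sum(c**2 for c in runs_per_level.values()) / n_r,
        "RP": n_r / n_p,
        "RLN": sum(c**2 for c in runs_per_length.values()) / n_r,
        "LGRE": sum(c / (g + 1) ** 2 for g, c in runs_per_level.items()) / n_r,
        "HGRE": sum(c * (g + 1) ** 2 for g, c in runs_per_level.items()) / n_r,
    }


# ------------------------------------------------------------------------ AUC

def auc_mann_whitney(y_true, scores, positive) -> float:
    pos = [s for y, s in zip(y_true, scores) if y == positive]
    neg = [s for y, s in zip(y_true, scores) if y != positive]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
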