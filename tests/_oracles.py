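"""Independent brute-force oracles for the co-occurrence-family statistics.

Everything here is written as explicit pixel-pair enumeration with plain
Python loops, deliberately sharing no code with the vectorized
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_oracle(gray, mask, levels, offset):
    """(contrast, correlation, energy, homogeneity) by direct pair counting."""
    H, W = gray.shape
    dy, dx = offset
    C = [[0.0] * levels for _ in range(levels)]
    total = 0
    for y in range(H):
        for x in range(W):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < H and 0 <= x2 < W and mask[y, x] and mask[y2, x2]:
                i, j = int(gray[y, x]), int(gray[y2, x2])
                C[i][j] += 1.0
                C[j][i] += 1.0  # symmetric accumulation
                total += 2
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    P = [[c / total for c in row] for row in C]
    contrast = sum(P[i][j] * (i - j) ** 2 for i in range(levels) for j in range(levels))
    energy = sum(P[i][j] ** 2 for i in range(levels) for j in range(levels))
    homog = sum(
        P[i][j] / (1 + abs(i - j)) for i in range(levels) for j in range(levels)
    )
    pi = [sum(P[i][j] for j in range(levels)) for i in range(levels)]
    mu = sum(i * pi[i] for i in range(levels))
    var = sum((i - mu) ** 2 * pi[i] for i in range(levels))
    if var > 0:
        corr = (
            sum(
                (i - mu) * (j - mu) * P[i][j]
                for i in range(levels)
                for j in range(levels)
            )
            / var
        )
    else:
        corr = 0.0
    return contrast, corr, energy, homog


def gldm_oracle(gray, mask, levels, displacement):
    """(mean, contrast, ASM, entropy) of the absolute-difference histogram."""
    H, W = gray.shape
    dy, dx = displacement
    hist = [0.0] * levels
    total = 0
    for y in range(H):
        for x in range(W):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < H and 0 <= x2 < W and mask[y, x] and mask[y2, x2]:
                hist[abs(int(gray[y, x]) - int(gray[y2, x2]))] += 1.0
                total += 1
    if total == 0:
        raise ValueError("no pairs")
    P = [h / total for h in hist]
    mean = sum(d * P[d] for d in range(levels))
    contrast = sum(d * d * P[d] for d in range(levels))
    asm = sum(p * p for p in P)
    entropy = -sum(p * math.log(p) for p in P if p > 0)
    return mean, contrast, asm, entropy


def _sobel_at(gray, y, x):
    """3x3 Sobel magnitude at (y, x) with nearest-edge padding."""
    H, W = gray.shape
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]

    def px(yy, xx):
        return float(gray[min(max(yy, 0), H - 1), min(max(xx, 0), W - 1)])

    gx = sum(kx[r][c] * px(y + r - 1, x + c - 1) for r in range(3) for c in range(3))
    gy = sum(kx[c][r] * px(y + r - 1, x + c - 1) for r in range(3) for c in range(3))
    return math.sqrt(gx * gx + gy * gy)


def ggcm_oracle(gray, mask, levels, gradient_levels=None):
    """The 15 gray-gradient co-occurrence statistics by direct enumeration.

    Order matches ginkgohsi.image_features._GGCM_NAMES.
    """
    H, W = gray.shape
    Lg = gradient_levels or levels
    # interior pixels: 3x3 window fully in foreground
    valid = []
    for y in range(H):
        for x in range(W):
            ok = True
            for r in (-1, 0, 1):
                for c in (-1, 0, 1):
                    yy, xx = y + r, x + c
                    if not (0 <= yy < H and 0 <= xx < W and mask[yy, xx]):
                        ok = False
            if ok:
                valid.append((y, x))
    if not valid:
        raise ValueError("no interior pixels")
    mags = {pos: _sobel_at(gray, *pos) for pos in valid}
    hi = max(mags.values())
    Hm = [[0.0] * Lg for _ in range(levels)]
    for (y, x), mg in mags.items():
        q = min(int(mg / hi * Lg), Lg - 1) if hi > 0 else 0
        Hm[int(gray[y, x])][q] += 1.0
    total = sum(sum(row) for row in Hm)
    p = [[v / total for v in row] for row in Hm]
    p_gray = [sum(row) for row in p]
    p_grad = [sum(p[i][j] for i in range(levels)) for j in range(Lg)]
    mu_g = sum(i * p_gray[i] for i in range(levels))
    mu_d = sum(j * p_grad[j] for j in range(Lg))
    var_g = sum((i - mu_g) ** 2 * p_gray[i] for i in range(levels))
    var_d = sum((j - mu_d) ** 2 * p_grad[j] for j in range(Lg))
    if var_g > 0 and var_d > 0:
        corr = sum(
            (i - mu_g) * (j - mu_d) * p[i][j]
            for i in range(levels)
            for j in range(Lg)
        ) / math.sqrt(var_g * var_d)
    else:
        corr = 0.0

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    return np.array(
        [
            sum(p[i][j] / (j + 1) ** 2 for i in range(levels) for j in range(Lg)),
            sum(p[i][j] * j * j for i in range(levels) for j in range(Lg)),
            sum(v * v for v in p_gray),
            sum(v * v for v in p_grad),
            sum(v * v for row in p for v in row),
            mu_g,
            mu_d,
            math.sqrt(var_g),
            math.sqrt(var_d),
            corr,
            ent(p_gray),
            ent(p_grad),
            ent([v for row in p for v in row]),
            sum(p[i][j] * (i - j) ** 2 for i in range(levels) for j in range(Lg)),
            sum(p[i][j] / (1 + (i - j) ** 2) for i in range(levels) for j in range(Lg)),
        ]
    )
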