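"""Independent brute-force oracles used by the feature tests."""

import numpy as np


def glcm_oracle(img, levels, distance, angles, mask=None):
    """Double-loop symmetric co-occurrence features (reference path)."""
    q = (img.astype(np.int64) * levels) // 256
    H, W = img.shape
    offs = {0.0: (0, distance), 45.0: (-distance, distance),
            90.0: (-distance, 0), 135.0: (-distance, -distance)}
    P = np.zeros((levels, levels))
    for ang in angles:
        dr, dc = offs[ang]
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < H and 0 <= c2 < W):
                    continue
                if mask is not None and not (mask[r, c] and mask[r2, c2]):
                    continue
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    P /= P.sum()
    feats = {"asm": 0.0, "contrast": 0.0, "idm": 0.0, "entropy": 0.0}
    mu_i = sum(i * P[i, j] for i in range(levels) for j in range(levels))
    mu_j = sum(j * P[i, j] for i in range(levels) for j in range(levels))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(levels) for j in range(levels))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(levels) for j in range(levels))
    cov = 0.0
    for i in range(levels):
        for j in range(levels):
            p = P[i, j]
            feats["asm"] += p * p
            feats["contrast"] += (i - j) ** 2 * p
            feats["idm"] += p / (1 + (i - j) ** 2)
            if p > 0:
                feats["entropy"] -= p * np.log(p)
            cov += (i - mu_i) * (j - mu_j) * p
    feats["correlation"] = cov / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else np.nan
    return feats


def gliding_box_oracle(mask, r):
    """Exhaustive gliding-box lambda(r) = var(M)/mean(M)^2."""
    H, W = mask.shape
    masses = [
        mask[y:y + r, x:x + r].sum()
        for y in range(H - r + 1)
        for x in range(W - r + 1)
    ]
    m = np.asarray(masses, dtype=float)
    return m.var() / m.mean() ** 2
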