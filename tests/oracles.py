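"""Independent brute-force reference implementations used only by tests.

Each oracle is written as plain double loops straight from the defining
formulas, sharing no code with the package implementation.
"""

import numpy as np

EPS = 1e-6


def vote_mask_oracle(masks):
    """Per-voxel >= 50% vote, evaluated voxel by voxel."""
    out = np.zeros(masks[0].shape, bool)
    for idx in np.ndindex(masks[0].shape):
        votes = sum(int(m[idx]) for m in masks)
        out[idx] = votes / len(masks) >= 0.5
    return out


def ngtdm_oracle(img, mask, d, levels):
    """Neighbourhood gray-tone difference textures by explicit loops."""
    img = np.asarray(img, float)
    mask = np.asarray(mask, bool)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    h, w = img.shape
    q = np.zeros((h, w), int)
    for x in range(h):
        for y in range(w):
            if mask[x, y]:
                if hi > lo:
                    level = int((img[x, y] - lo) / (hi - lo) * levels)
                    level = min(level, levels - 1)
                else:
                    level = 0
                q[x, y] = level + 1

    s = {}
    count = {}
    n = 0
    for x in range(h):
        for y in range(w):
            if not mask[x, y]:
                continue
            ok = True
            total = 0.0
            k = 0
            for dx in range(-d, d + 1):
                for dy in range(-d, d + 1):
                    xi, yi = x + dx, y + dy
                    if not (0 <= xi < h and 0 <= yi < w and mask[xi, yi]):
                        ok = False
                        break
                    if (dx, dy) != (0, 0):
                        total += q[xi, yi]
                        k += 1
                if not ok:
                    break
            if not ok:
                continue
            n += 1
            i = q[x, y]
            s[i] = s.get(i, 0.0) + abs(i - total / k)
            count[i] = count.get(i, 0) + 1

    zeros = dict(coarseness=0.0, contrast=0.0, busyness=0.0,
                 complexity=0.0, strength=0.0)
    if n == 0:
        return zeros
    tones = sorted(count)
    p = {i: count[i] / n for i in tones}
    n_p = len(tones)

    coarseness = min(1.0 / (EPS + sum(p[i] * s[i] for i in tones)), 1.0 / EPS)
    if n_p < 2:
        return dict(zeros, coarseness=coarseness)
    contrast = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in tones for j in tones)
        / (n_p * (n_p - 1))
    ) * (sum(s[i] for i in tones) / n)
    denom = sum(abs(i * p[i] - j * p[j]) for i in tones for j in tones)
    busyness = (
        sum(p[i] * s[i] for i in tones) / denom if denom > EPS else 0.0
    )
    complexity = sum(
        abs(i - j) / (n * (p[i] + p[j])) * (p[i] * s[i] + p[j] * s[j])
        for i in tones
        for j in tones
    )
    strength = sum(
        (p[i] + p[j]) * (i - j) ** 2 for i in tones for j in tones
    ) / (EPS + sum(s[i] for i in tones))
    return dict(coarseness=coarseness, contrast=contrast, busyness=busyness,
                complexity=complexity, strength=strength)


def lacunarity_oracle(mask, box_sizes):
    """Gliding-box lacunarity by explicit window enumeration."""
    mask = np.asarray(mask, bool)
    xs, ys = np.nonzero(mask)
    box = mask[xs.min():xs.max() + 1, ys.min():ys.max() + 1]
    h, w = box.shape
    out = []
    for s in box_sizes:
        if s > h or s > w:
            out.append(1.0)
            continue
        counts = []
        for x in range(h - s + 1):
            for y in range(w - s + 1):
                counts.append(int(box[x:x + s, y:y + s].sum()))
        counts = np.asarray(counts, float)
        mean = counts.mean()
        out.append(float(counts.var() / mean**2 + 1.0) if mean > 0 else 1.0)
    return np.asarray(out)


def pair_count_auc_oracle(scores, labels):
    """AUC as the fraction of correctly ordered (pos, neg) pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


def moments_oracle(values):
    """Population mean/sd/variance/skewness/kurtosis by direct summation."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    if m2 == 0:
        return mean, 0.0, 0.0, 0.0, 0.0
    return mean, m2**0.5, m2, m3 / m2**1.5, m4 / m2**2


def box_count_oracle(mask):
    """Box-counting dimension via explicit grid scans over dyadic sizes."""
    mask = np.asarray(mask, bool)
    xs, ys = np.nonzero(mask)
    box = mask[xs.min():xs.max() + 1, ys.min():ys.max() + 1]
    h, w = box.shape
    sizes, counts = [], []
    s = 2
    while s <= max(h, w):
        n = 0
        for x0 in range(0, h, s):
            for y0 in range(0, w, s):
                if box[x0:x0 + s, y0:y0 + s].any():
                    n += 1
        sizes.append(s)
        counts.append(n)
        s *= 2
    if len(sizes) < 3:
        return None
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return -slope
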