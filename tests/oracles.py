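"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested loops / direct enumeration so
that it shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_com_matrix(levels, mask, dx, dy, n_levels):
    """Co-occurrence probabilities by explicit ordered-pair enumeration."""
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                counts[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def brute_com_features(p):
    """Haralick statistics by direct summation over matrix cells."""
    n = p.shape[0]
    feats = {}
    feats["AngScMom"] = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    feats["Contrast"] = sum(
        p[i, j] * (i - j) ** 2 for i in range(n) for j in range(n)
    )
    px = p.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(n))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))
    if var > 0:
        feats["Correlat"] = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n))
            - mu * mu
        ) / var
    else:
        feats["Correlat"] = 0.0
    feats["SumOfSqs"] = sum(
        (i + 1 - mu) ** 2 * p[i, j] for i in range(n) for j in range(n)
    )
    feats["InvDfMom"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
    )
    psum = {}
    pdif = {}
    for i in range(n):
        for j in range(n):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdif[abs(i - j)] = pdif.get(abs(i - j), 0.0) + p[i, j]
    sa = sum(k * v for k, v in psum.items())
    feats["SumAverg"] = sa
    feats["SumVarnc"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    feats["SumEntrp"] = -sum(v * np.log(v) for v in psum.values() if v > 0)
    feats["Entropy"] = -sum(
        p[i, j] * np.log(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
    )
    md = sum(k * v for k, v in pdif.items())
    feats["DifVarnc"] = sum((k - md) ** 2 * v for k, v in pdif.items())
    feats["DifEntrp"] = -sum(v * np.log(v) for v in pdif.values() if v > 0)
    return feats


def brute_runs(levels, mask, step):
    """Maximal constant-level runs along one direction by walking lines."""
    h, w = levels.shape
    dy, dx = step
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dy, c - dx
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs = {}
    traversed = 0
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append((levels[r, c], mask[r, c]))
            r, c = r + dy, c + dx
        i = 0
        while i < len(line):
            g, inside = line[i]
            if not inside:
                i += 1
                continue
            traversed += 1
            length = 1
            while i + length < len(line) and line[i + length][1] and line[i + length][0] == g:
                length += 1
                traversed += 1
            runs[(int(g), length)] = runs.get((int(g), length), 0) + 1
            i += length
    return runs, traversed


def brute_rlm_features(runs, traversed):
    total = sum(runs.values())
    if total == 0:
        return dict.fromkeys(
            ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction"), 0.0
        )
    by_g, by_l = {}, {}
    for (g, l), r in runs.items():
        by_g[g] = by_g.get(g, 0) + r
        by_l[l] = by_l.get(l, 0) + r
    return {
        "ShrtREmp": sum(r / l**2 for (_, l), r in runs.items()) / total,
        "LngREmph": sum(r * l**2 for (_, l), r in runs.items()) / total,
        "GLevNonU": sum(v**2 for v in by_g.values()) / total,
        "RLNonUni": sum(v**2 for v in by_l.values()) / total,
        "Fraction": total / traversed,
    }


def brute_quantize(values, mu, sigma, n_levels):
    """Per-value binning by explicit bin-edge enumeration."""
    lo, hi = mu - 3 * sigma, mu + 3 * sigma
    edges = [lo + (hi - lo) * k / n_levels for k in range(n_levels + 1)]
    out = []
    for v in values:
        v = min(max(v, lo), hi)
        level = n_levels
        for k in range(n_levels):
            if v < edges[k + 1]:
                level = k + 1
                break
        out.append(level)
    return out
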