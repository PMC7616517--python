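"""Independent brute-force oracles, deliberately kept free of the package's
vectorized code paths: plain-Python arithmetic and full sorts only."""

from __future__ import annotations

import math


def cosine_scalar(u, v) -> float:
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return max(-1.0, min(1.0, dot / (nu * nv)))


def sneigh_bruteforce(target, target_vec, words, vectors, k):
    """Mean cosine of the k nearest neighbors by exhaustive enumeration and sort."""
    sims = []
    for w, v in zip(words, vectors):
        if w == target:
            continue
        sims.append((w, cosine_scalar(target_vec, v)))
    sims.sort(key=lambda t: (-t[1], t[0]))
    top = sims[:k]
    return sum(c for _, c in top) / k, top


def loo_high_outliers(rates: dict, threshold_sd: float = 2.5) -> list:
    """Leave-one-out mean + t*SD screening (sample SD), one-sided high."""
    out = []
    for name, r in rates.items():
        others = [v for n, v in rates.items() if n != name]
        mu = sum(others) / len(others)
        var = sum((v - mu) ** 2 for v in others) / (len(others) - 1)
        if r > mu + threshold_sd * math.sqrt(var):
            out.append(name)
    return out
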