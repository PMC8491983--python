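"""Independent plain-loop reference implementations of the three
published thresholding criteria, used to cross-check the package's
vectorized versions.  Deliberately written as direct transcriptions of
the criteria (exhaustive evaluation over all 256 candidate thresholds),
sharing no code with the implementation.
"""

import math

import numpy as np


def triangle_oracle(counts) -> int:
    """Zack's geometric construction, evaluated bin by bin."""
    counts = [float(c) for c in counts]
    nonzero = [i for i, c in enumerate(counts) if c > 0]
    if len(nonzero) == 1:
        return nonzero[0]
    peak = max(range(256), key=lambda i: (counts[i], -i))
    lo, hi = nonzero[0], nonzero[-1]
    end = lo if (peak - lo) > (hi - peak) else hi
    x0, y0, x1, y1 = float(peak), counts[peak], float(end), counts[end]
    length = math.hypot(x1 - x0, y1 - y0)
    best_t, best_d = None, -1.0
    for i in range(min(peak, end), max(peak, end) + 1):
        d = abs((y1 - y0) * (i - x0) - (x1 - x0) * (counts[i] - y0)) / length
        if d > best_d + 1e-12:
            best_d, best_t = d, i
    return best_t


def maxentropy_oracle(counts) -> int:
    """Kapur-Sahoo-Wong: exhaustive search maximizing the class entropies."""
    counts = [float(c) for c in counts]
    total = sum(counts)
    p = [c / total for c in counts]
    best_t, best_val = None, -math.inf
    for t in range(256):
        low = p[: t + 1]
        high = p[t + 1 :]
        w_low, w_high = sum(low), sum(high)
        if w_low <= 0 or w_high <= 0:
            continue
        h_low = -sum(q / w_low * math.log(q / w_low) for q in low if q > 0)
        h_high = -sum(q / w_high * math.log(q / w_high) for q in high if q > 0)
        val = h_low + h_high
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return best_t


def moments_oracle(counts) -> int:
    """Tsai's moment preservation via an independent algebraic route.

    The representative gray levels z0 < z1 of the moment-preserving
    binary image are the roots of z^2 + c1 z + c0 = 0 where (c0, c1)
    solve the linear system [[1, m1], [m1, m2]] @ (c0, c1) = (-m2, -m3).
    The below-threshold fraction is p = (z1 - m1) / (z1 - z0); the
    threshold is then found by exhaustive scan of the cumulative
    distribution.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    prob = counts / total
    bins = np.arange(256, dtype=float)
    m1 = float(prob @ bins)
    m2 = float(prob @ bins**2)
    m3 = float(prob @ bins**3)
    c0, c1 = np.linalg.solve([[1.0, m1], [m1, m2]], [-m2, -m3])
    roots = np.roots([1.0, c1, c0])
    z0, z1 = sorted(roots.real)
    p_below = (z1 - m1) / (z1 - z0)
    cum = 0.0
    for t in range(256):
        cum += prob[t]
        if cum >= p_below - 1e-12:
            return t
    return 255


def random_histograms(n: int, seed: int) -> list[np.ndarray]:
    """A seeded mix of histogram shapes: dense uniform, sparse, bimodal."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        kind = len(out) % 3
        if kind == 0:
            h = rng.integers(0, 1000, 256)
        elif kind == 1:
            h = np.zeros(256, dtype=np.int64)
            idx = rng.choice(256, size=rng.integers(2, 20), replace=False)
            h[idx] = rng.integers(1, 5000, idx.size)
        else:
            h = np.zeros(256, dtype=np.int64)
            for mu, sd, mass in (
                (rng.integers(10, 90), rng.uniform(2, 15), rng.integers(500, 5000)),
                (rng.integers(120, 250), rng.uniform(2, 25), rng.integers(100, 5000)),
            ):
                vals = np.clip(np.round(rng.normal(mu, sd, mass)), 0, 255).astype(int)
                h += np.bincount(vals, minlength=256)
        if np.count_nonzero(h) >= 2:  # preconditions of all three methods
            out.append(h.astype(np.int64))
    return out
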