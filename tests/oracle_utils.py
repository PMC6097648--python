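"""Independent brute-force oracles used by the tests.

Everything here is written as plain Python loops straight from the
definitions, deliberately avoiding the vectorized code paths of the package
so that agreement is meaningful.
"""

import math


# --- rank filters ----------------------------------------------------------

def oracle_disc(radius):
    """Disc membership offsets; radius 1 is the full 3x3 square."""
    if radius == 1:
        return [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    out = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                out.append((dy, dx))
    return out


def oracle_rank_2d(img, radius, mode):
    """Per-pixel neighborhood min/max with edge replication."""
    ny, nx = len(img), len(img[0])
    offsets = oracle_disc(radius)
    pick = min if mode == "min" else max
    out = [[0] * nx for _ in range(ny)]
    for y in range(ny):
        for x in range(nx):
            vals = []
            for dy, dx in offsets:
                yy = min(max(y + dy, 0), ny - 1)
                xx = min(max(x + dx, 0), nx - 1)
                vals.append(img[yy][xx])
            out[y][x] = pick(vals)
    return out


# --- thresholds ------------------------------------------------------------

def _smooth3(h):
    padded = [h[1]] + list(h) + [h[-2]]  # reflect ends
    return [(padded[i] + padded[i + 1] + padded[i + 2]) / 3.0 for i in range(len(h))]


def _peaks(h):
    padded = [h[1]] + list(h) + [h[-2]]
    return [
        i
        for i in range(len(h))
        if padded[i] < padded[i + 1] and padded[i + 1] > padded[i + 2]
    ]


def oracle_intermodes(counts, cap=10_000):
    h = [float(c) for c in counts]
    for _ in range(cap + 1):
        peaks = _peaks(h)
        if len(peaks) == 2:
            return (peaks[0] + peaks[1]) // 2
        h = _smooth3(h)
    raise ValueError("not bimodalizable")


def oracle_isodata(counts, cap=1_000):
    c = [float(x) for x in counts]
    c[0] = 0.0
    c[255] = 0.0
    nz = [i for i, x in enumerate(c) if x > 0]
    if not nz:
        raise ValueError("empty")
    lo, hi = nz[0], nz[-1]
    if lo == hi:
        return lo
    t = (lo + hi) // 2
    seen = {t}
    for _ in range(cap):
        s0 = sum(c[i] for i in range(t + 1))
        s1 = sum(c[i] for i in range(t + 1, 256))
        m0 = sum(i * c[i] for i in range(t + 1)) / s0 if s0 else lo
        m1 = sum(i * c[i] for i in range(t + 1, 256)) / s1 if s1 else hi
        t_new = int(math.floor((m0 + m1) / 2.0 + 0.5))
        t_new = min(max(t_new, lo), hi - 1)
        if t_new == t:
            return t
        if t_new in seen:
            return t_new
        seen.add(t_new)
        t = t_new
    return t


def oracle_renyi_candidate(counts, alpha):
    """Exhaustive-split argmax of summed background/foreground Renyi entropy."""
    total = float(sum(counts))
    p = [c / total for c in counts]
    best_t, best = -1, -float("inf")
    for t in range(256):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        if w0 <= 0.0 or w1 <= 0.0:
            continue
        b = [x / w0 for x in p[: t + 1] if x > 0]
        f = [x / w1 for x in p[t + 1 :] if x > 0]
        if not b or not f:
            continue
        if abs(alpha - 1.0) < 1e-12:
            val = -sum(x * math.log(x) for x in b) - sum(x * math.log(x) for x in f)
        else:
            val = (
                math.log(sum(x**alpha for x in b)) + math.log(sum(x**alpha for x in f))
            ) / (1.0 - alpha)
        if val > best + 1e-12:
            best, best_t = val, t
    return best_t


def oracle_renyi(counts):
    """Candidates from the exhaustive oracle, combined with the pinned
    spread-weighting rule (1-2-1 / 3-1-0 by candidate agreement within 5)."""
    t1, t2, t3 = sorted(
        oracle_renyi_candidate(counts, a) for a in (0.5, 1.0, 2.0)
    )
    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    total = float(sum(counts))
    p = [c / total for c in counts]
    P1 = []
    acc = 0.0
    for x in p:
        acc += x
        P1.append(acc)
    omega = P1[t3] - P1[t1]
    return int(
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (1.0 - P1[t3] + 0.25 * omega * beta[2])
    )


# --- random histogram factories --------------------------------------------

def bimodal_histogram(rng):
    """Integer histogram from a two-Gaussian mixture plus a sparse floor."""
    counts = [0] * 256
    m1 = int(rng.integers(20, 90))
    m2 = int(rng.integers(130, 230))
    s1 = float(rng.uniform(4, 15))
    s2 = float(rng.uniform(4, 15))
    n1 = int(rng.integers(2_000, 20_000))
    n2 = int(rng.integers(2_000, 20_000))
    for m, s, n in ((m1, s1, n1), (m2, s2, n2)):
        for v in rng.normal(m, s, size=n):
            b = int(round(v))
            if 0 <= b <= 255:
                counts[b] += 1
    return counts


def rough_histogram(rng):
    """Arbitrary nonnegative integer histogram with random support."""
    counts = [0] * 256
    lo = int(rng.integers(0, 100))
    hi = int(rng.integers(lo + 20, 256))
    for i in range(lo, hi):
        counts[i] = int(rng.integers(0, 500))
    return counts
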