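"""Pooled stack histograms and histogram auto-threshold algorithms.

Three classic 8-bit histogram thresholds are provided, one per channel type
of the analysis:

* **Intermodes** (Prewitt & Mendelsohn): repeatedly smooth the histogram
  with a 3-bin running mean until exactly two local maxima remain, then
  threshold midway between them.  Used for the active-zone (Brp) channel.
* **Default/IsoData** (iterated intermeans, Ridler & Calvard lineage): the
  fixed point of ``t <- round((mean below + mean above) / 2)``, after
  trimming the two extreme bins (0 and 255) so erased/saturated areas do
  not bias the class means.  Used for the dye-fill (DA488) and Neurobiotin
  channels.
* **Rényi entropy** (Sahoo, Wilkins & Yeager 1997): maximize the summed
  background/foreground Rényi entropies at orders α→1 (Shannon), α=1/2 and
  α=2, then combine the three candidate levels with the published
  spread-dependent 1-2-1 / 3-1-0 weighting rule.  Used for the ShakB
  (gap-junction plaque) channel.

All thresholds operate on one histogram pooled over the whole stack, with
bin 255 optionally excluded ("ignore white").  Binarization uses the strict
convention: a voxel is foreground iff its intensity is greater than the
level.  Argmax ties break to the lowest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import BinaryMask, VoxelStack

__all__ = [
    "IntensityHistogram",
    "ThresholdResult",
    "stack_histogram",
    "threshold_intermodes",
    "threshold_default_isodata",
    "threshold_renyi_entropy",
    "threshold",
    "binarize",
    "METHODS",
]

INTERMODES_ITERATION_CAP = 10_000
_ISODATA_ITERATION_CAP = 1_000


@dataclass
class IntensityHistogram:
    """256-bin pooled stack histogram.

    ``counts[255]`` is zeroed when ``ignore_white`` is set; the number of
    excluded white voxels is kept so that
    ``counts.sum() + excluded_white == source_voxels``.
    """

    counts: np.ndarray
    ignore_white: bool = True
    source_voxels: int = 0
    excluded_white: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ValueError(f"histogram must have 256 bins, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ThresholdResult:
    level: int
    method: str
    iterations: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.level <= 255:
            raise ValueError(f"threshold level {self.level} outside [0, 255]")


def stack_histogram(stack: VoxelStack, ignore_white: bool = True) -> IntensityHistogram:
    """Pool one 256-bin histogram over every slice of the stack."""
    counts = np.bincount(stack.intensities.ravel(), minlength=256).astype(np.int64)
    source = int(counts.sum())
    excluded = 0
    if ignore_white:
        excluded = int(counts[255])
        counts[255] = 0
    return IntensityHistogram(counts, ignore_white, source, excluded)


# ---------------------------------------------------------------------------
# Intermodes
# ---------------------------------------------------------------------------

def _smooth3_reflect(h: np.ndarray) -> np.ndarray:
    padded = np.pad(h, 1, mode="reflect")
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _strict_peaks(h: np.ndarray) -> np.ndarray:
    padded = np.pad(h, 1, mode="reflect")
    inner = padded[1:-1]
    return np.flatnonzero((padded[:-2] < inner) & (inner > padded[2:]))


def threshold_intermodes(hist: IntensityHistogram) -> ThresholdResult:
    """Iterative 3-bin mean smoothing until bimodal; level = floor((j+k)/2).

    Raises if the histogram cannot be reduced to exactly two strict local
    maxima within the iteration cap (e.g. a single spike).
    """
    h = hist.counts.astype(np.float64)
    if h.sum() == 0:
        raise ValueError("empty histogram")
    iterations = 0
    peaks = _strict_peaks(h)
    while len(peaks) != 2:
        if iterations >= INTERMODES_ITERATION_CAP:
            raise ValueError("histogram cannot be bimodalized")
        h = _smooth3_reflect(h)
        iterations += 1
        peaks = _strict_peaks(h)
    j, k = int(peaks[0]), int(peaks[1])
    return ThresholdResult((j + k) // 2, "intermodes", iterations, {"modes": (j, k)})


# ---------------------------------------------------------------------------
# Default / IsoData (iterated intermeans)
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_default_isodata(hist: IntensityHistogram) -> ThresholdResult:
    """Iterated-intermeans fixed point after trimming bins 0 and 255.

    Starting at the midpoint of the trimmed histogram's nonzero support,
    iterate ``t <- round((mean of counts <= t + mean of counts > t) / 2)``
    until stable.  If all mass sits in one interior bin, that bin is the
    (degenerate) fixed point.
    """
    c = hist.counts.astype(np.float64).copy()
    c[0] = 0.0
    c[255] = 0.0
    if c.sum() == 0:
        raise ValueError("empty histogram (after trimming extreme bins)")
    nz = np.flatnonzero(c)
    lo, hi = int(nz[0]), int(nz[-1])
    if lo == hi:
        return ThresholdResult(lo, "default_isodata", 0, {"degenerate": True})
    bins = np.arange(256, dtype=np.float64)
    t = (lo + hi) // 2
    seen = {t}
    iterations = 0
    while True:
        below = c[: t + 1]
        above = c[t + 1 :]
        m0 = float(bins[: t + 1] @ below / below.sum()) if below.sum() else float(lo)
        m1 = float(bins[t + 1 :] @ above / above.sum()) if above.sum() else float(hi)
        t_new = _round_half_up((m0 + m1) / 2.0)
        t_new = min(max(t_new, lo), hi - 1)
        iterations += 1
        if t_new == t or iterations >= _ISODATA_ITERATION_CAP or (t_new in seen and t_new != t):
            t = t_new
            break
        seen.add(t_new)
        t = t_new
    return ThresholdResult(t, "default_isodata", iterations)


# ---------------------------------------------------------------------------
# Rényi entropy
# ---------------------------------------------------------------------------

def _renyi_candidate(p: np.ndarray, alpha: float) -> int:
    """Level maximizing summed background/foreground Rényi entropy of order
    ``alpha`` over all valid splits; ties go to the lowest level.

    The background class is bins ``<= t``, foreground ``> t``; only splits
    with positive mass on both sides are candidates.
    """
    P1 = np.cumsum(p)
    best_t, best_val = -1, -np.inf
    for t in range(256):
        w0 = P1[t]
        w1 = 1.0 - w0
        if w0 <= 0.0 or w1 <= 0.0:
            continue
        b = p[: t + 1][p[: t + 1] > 0] / w0
        f = p[t + 1 :][p[t + 1 :] > 0] / w1
        if b.size == 0 or f.size == 0:  # mass vanished in float round-off
            continue
        if abs(alpha - 1.0) < 1e-12:
            val = -(b @ np.log(b)) - (f @ np.log(f))
        else:
            val = (np.log((b**alpha).sum()) + np.log((f**alpha).sum())) / (1.0 - alpha)
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return best_t


def threshold_renyi_entropy(hist: IntensityHistogram) -> ThresholdResult:
    """Three-order Rényi entropy threshold with the spread-weighted merge.

    Candidates ``t*`` are computed at α=1/2, α→1 and α=2 and sorted; the
    published rule then weights them 1-2-1 when all three agree to within 5
    levels, 3-1-0 / 0-1-3 when only one pair agrees, and combines them
    through the cumulative mass around the extreme candidates:

    ``level = t1·(P(t1) + ω·β1/4) + t2·ω·β2/4 + t3·(1 − P(t3) + ω·β3/4)``

    with ``ω = P(t3) − P(t1)`` (truncated to an integer level).
    """
    c = hist.counts.astype(np.float64)
    if np.count_nonzero(c) < 2:
        raise ValueError("Rényi entropy threshold requires at least 2 nonzero bins")
    p = c / c.sum()
    t_half = _renyi_candidate(p, 0.5)
    t_one = _renyi_candidate(p, 1.0)
    t_two = _renyi_candidate(p, 2.0)
    t1, t2, t3 = sorted((t_half, t_one, t_two))

    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)

    P1 = np.cumsum(p)
    omega = P1[t3] - P1[t1]
    level = int(
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (1.0 - P1[t3] + 0.25 * omega * beta[2])
    )
    return ThresholdResult(
        level,
        "renyi_entropy",
        0,
        {"candidates": {"alpha=0.5": t_half, "alpha=1": t_one, "alpha=2": t_two}, "beta": beta},
    )


METHODS = {
    "intermodes": threshold_intermodes,
    "default": threshold_default_isodata,
    "default_isodata": threshold_default_isodata,
    "renyi": threshold_renyi_entropy,
    "renyi_entropy": threshold_renyi_entropy,
}


def threshold(hist: IntensityHistogram, method: str) -> ThresholdResult:
    """Dispatch to one of the supported methods by name."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}; supported: {sorted(METHODS)}")
    return fn(hist)


def binarize(stack: VoxelStack, level: int) -> BinaryMask:
    """Foreground = intensity strictly greater than ``level``."""
    level = int(level)
    if not 0 <= level <= 255:
        raise ValueError(f"threshold level {level} outside [0, 255]")
    return BinaryMask(stack.intensities > level, stack.geometry)
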