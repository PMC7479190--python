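"""Dynamic Complexity and Permutation Entropy, windowed over a series.

Dynamic Complexity (DC) was designed for short, coarse-grained rating-scale
data: it is the product ``F * D`` of a fluctuation measure (sensitive to the
amplitude and rate of direction reversals) and a distribution measure (how
evenly the window's values fill the available scale range).  High DC flags
critical fluctuations, the classic early-warning signal preceding a
transition.

Permutation Entropy (PE) is the Shannon entropy of ordinal-pattern ("word")
frequencies inside the window, normalized by ``ln(n!)`` to [0, 1].  Being
rank-based it is invariant to monotone distortions of the measurement scale
and tolerant to observational noise.

Both indicators use trailing windows (default width 7, matching daily-rating
practice of one window per week).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .series import DerivedSeries, TimeSeries


@dataclass(frozen=True)
class ScaleRange:
    """Theoretical or observed bounds of the measurement scale."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("scale range requires hi > lo")

    @property
    def span(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class DcConfig:
    window: int = 7
    range: Optional[ScaleRange] = None  # None -> observed global min/max

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("DC window must be >= 3")


@dataclass(frozen=True)
class PeConfig:
    window: int = 7
    order: int = 3

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("word length must be >= 2")
        if self.window <= self.order:
            raise ValueError("window must exceed word length")


def fluctuation_measure(window_values: Sequence[float], rng: ScaleRange) -> float:
    """Normalized fluctuation intensity of one window, in [0, 1].

    The window is partitioned into maximal monotone runs (plateaus extend the
    current run); each run contributes its absolute value change divided by
    its duration.  The sum is normalized by the steepest realizable
    alternation, ``(hi - lo) * (m - 1)``, so a full-range zig-zag scores 1 and
    a constant window 0.
    """
    x = np.clip(np.asarray(window_values, dtype=float), rng.lo, rng.hi)
    m = x.size
    if m < 2:
        raise ValueError("fluctuation measure needs at least 2 points")
    d = np.diff(x)
    signs = np.sign(d)
    total = 0.0
    start = 0
    direction = 0.0
    for i, s in enumerate(signs):
        if s != 0 and direction != 0 and s != direction:
            total += abs(x[i] - x[start]) / (i - start)
            start = i
            direction = s
        elif s != 0 and direction == 0:
            direction = s
    total += abs(x[m - 1] - x[start]) / max(m - 1 - start, 1)
    return float(total / (rng.span * (m - 1)))


def distribution_measure(window_values: Sequence[float], rng: ScaleRange) -> float:
    """Evenness of the window's spread over the scale range, in [0, 1].

    The sorted values are compared against the ideal uniform grid over
    ``[lo, hi]``; the summed deviation is scaled by its value for a fully
    degenerate window (all mass at one end), ``m * (hi - lo) / 2``.
    """
    x = np.clip(np.asarray(window_values, dtype=float), rng.lo, rng.hi)
    m = x.size
    if m < 2:
        raise ValueError("distribution measure needs at least 2 points")
    y = np.sort(x)
    grid = rng.lo + np.arange(m) * (rng.span / (m - 1))
    dev = float(np.abs(y - grid).sum())
    return max(0.0, 1.0 - dev / (m * rng.span / 2.0))


def dynamic_complexity(s: TimeSeries, cfg: DcConfig = DcConfig()) -> DerivedSeries:
    """Windowed dynamic complexity ``F * D`` as a trailing-window series.

    With no explicit scale range the observed global min/max of the series is
    used; a constant series therefore yields all zeros (no fluctuation).
    """
    w = cfg.window
    if len(s) < w:
        raise ValueError(f"series of length {len(s)} shorter than DC window {w}")
    rng = cfg.range
    if rng is None:
        lo, hi = float(np.min(s.values)), float(np.max(s.values))
        if hi <= lo:  # constant series: no fluctuation, complexity zero
            return DerivedSeries(np.zeros(len(s) - w + 1), window=w,
                                 offset=s.t0 + w - 1)
        rng = ScaleRange(lo, hi)
    wins = np.lib.stride_tricks.sliding_window_view(s.values, w)
    vals = np.array([
        fluctuation_measure(win, rng) * distribution_measure(win, rng)
        for win in wins
    ])
    return DerivedSeries(vals, window=w, offset=s.t0 + w - 1)


def ordinal_pattern(word: Sequence[float]) -> tuple[int, ...]:
    """Rank pattern of a word; ties are broken by order of occurrence.

    Each value is recoded to its rank ``0..n-1``; among equal values the
    earlier index receives the lower rank (relevant for coarse rating data
    with many ties).
    """
    w = np.asarray(word, dtype=float)
    order = np.argsort(w, kind="stable")
    ranks = np.empty(w.size, dtype=int)
    ranks[order] = np.arange(w.size)
    return tuple(int(r) for r in ranks)


def _window_entropy(patterns: Sequence[tuple[int, ...]], order: int) -> float:
    counts = np.array(list(Counter(patterns).values()), dtype=float)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(order)))


def permutation_entropy(s: TimeSeries, cfg: PeConfig = PeConfig()) -> DerivedSeries:
    """Normalized permutation entropy per trailing window, in [0, 1].

    Every window of width ``w`` contains ``w - n + 1`` consecutive words of
    length ``n``; their ordinal-pattern frequencies define the entropy,
    normalized by ``ln(n!)``.
    """
    w, n = cfg.window, cfg.order
    if len(s) < w:
        raise ValueError(f"series of length {len(s)} shorter than PE window {w}")
    words = np.lib.stride_tricks.sliding_window_view(s.values, n)
    patterns = [ordinal_pattern(word) for word in words]
    per_window = w - n + 1
    vals = np.array([
        _window_entropy(patterns[i:i + per_window], n)
        for i in range(len(s) - w + 1)
    ])
    return DerivedSeries(vals, window=w, offset=s.t0 + w - 1)
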