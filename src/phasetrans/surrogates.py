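"""Dispersion tests of detected change points against uniform-random surrogates.

If a battery of detectors converges on one transition, the pooled change
points cluster; if the detections were artifacts, they should scatter like
points drawn uniformly over the series.  The null model therefore draws
``n_sets`` (default 100) sets of as many integers as there are real change
points, uniformly (with replacement) on ``{1..N}``, and compares two
dispersion statistics of the real pool against the percentile confidence
interval of the surrogate distribution:

* ``iqr_pct``  — interquartile range as a percentage of series length;
* ``sigma_pct`` — standard deviation of a fitted normal (the sample SD) as a
  percentage of series length.

For uniform draws these approach 50% and 100/sqrt(12) ~ 28.87% respectively;
a real pool far below the interval's lower bound indicates clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np


@dataclass(frozen=True)
class SurrogateConfig:
    n_sets: int = 100
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_sets < 2:
            raise ValueError("need at least 2 surrogate sets")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class DispersionTest:
    """One dispersion statistic of the real pool versus the surrogate null."""

    statistic: Literal["iqr_pct", "sigma_pct"]
    real_value: float
    surrogate_mean: float
    ci: tuple[float, float]
    outside_ci: bool


def draw_random_sets(
    n_points: int, series_length: int, cfg: SurrogateConfig = SurrogateConfig()
) -> np.ndarray:
    """``n_sets`` independent sets of ``n_points`` uniform integers on {1..N}."""
    if n_points < 2:
        raise ValueError("dispersion undefined for fewer than 2 points")
    if series_length < 2:
        raise ValueError("series length must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    return rng.integers(1, series_length + 1,
                        size=(cfg.n_sets, n_points))


def iqr_pct(points: Sequence[int], series_length: int) -> float:
    """Interquartile range of the points as % of series length.

    Quartiles by linear interpolation of the order statistics.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size < 2:
        raise ValueError("IQR needs at least 2 points")
    q1, q3 = np.percentile(pts, [25.0, 75.0], method="linear")
    return float((q3 - q1) / series_length * 100.0)


def sigma_pct(points: Sequence[int], series_length: int) -> float:
    """Fitted-normal sigma (sample SD, ddof=1) as % of series length."""
    pts = np.asarray(points, dtype=float)
    if pts.size < 2:
        raise ValueError("sigma needs at least 2 points")
    return float(np.std(pts, ddof=1) / series_length * 100.0)


def run_tests(
    real_points: Sequence[int],
    series_length: int,
    cfg: SurrogateConfig = SurrogateConfig(),
) -> tuple[DispersionTest, DispersionTest]:
    """Compare the real pool's dispersion against the uniform surrogate null.

    Returns the IQR test and the sigma test; ``outside_ci`` is True when the
    real statistic falls outside the two-sided percentile interval of the
    surrogate values (clustered pools fall below its lower bound).
    """
    real = np.asarray(real_points, dtype=float)
    if real.size < 2:
        raise ValueError("need at least 2 real change points")
    sets = draw_random_sets(real.size, series_length, cfg)
    alpha = (1.0 - cfg.ci_level) / 2.0 * 100.0

    out = []
    for name, fn in (("iqr_pct", iqr_pct), ("sigma_pct", sigma_pct)):
        null = np.array([fn(s, series_length) for s in sets])
        lo, hi = np.percentile(null, [alpha, 100.0 - alpha])
        real_val = fn(real, series_length)
        out.append(DispersionTest(
            statistic=name,  # type: ignore[arg-type]
            real_value=real_val,
            surrogate_mean=float(null.mean()),
            ci=(float(lo), float(hi)),
            outside_ci=bool(real_val < lo or real_val > hi),
        ))
    return out[0], out[1]
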