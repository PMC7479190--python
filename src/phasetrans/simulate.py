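"""Ground-truth transition generators.

Two simulators provide series with known transition windows:

* :func:`simulate_henon` — the Hénon map with a linear ramp of its control
  parameter ``a`` from 1.20 to 1.25 (step 0.002) over iterations 125-150,
  which carries the orbit from deterministic chaos into a regular rhythm.
  The x-variable of the 300-point orbit is returned together with the true
  transition window [125, 150].

* :func:`simulate_regime_shift` — a generic stochastic regime-shift process
  for controlled experiments: mean, variance, frequency, and/or
  autocorrelation ("pattern") parameters ramp linearly across a configurable
  transition window on top of Gaussian dynamic noise.  An optional
  multivariate version couples components through a shared latent factor
  whose loading ramps across the window, producing the rising
  inter-correlation probed by synchronization analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .series import MultiSeries, TimeSeries

ShiftKind = str  # 'mean' | 'variance' | 'frequency' | 'pattern'

_VALID_KINDS = {"mean", "variance", "frequency", "pattern"}


@dataclass(frozen=True)
class HenonConfig:
    """Hénon map ramp: x_{k+1} = y_k + 1 - a x_k^2, y_{k+1} = b x_k."""

    a_start: float = 1.20
    a_end: float = 1.25
    step: float = 0.002
    b: float = 0.30
    x0: float = 0.0
    y0: float = 0.0
    pre: int = 124            # iterations at a_start
    ramp_start: int = 125     # first ramped iteration
    ramp_end: int = 150       # iteration at which a reaches a_end
    post: int = 150           # iterations at a_end

    @property
    def length(self) -> int:
        return self.pre + (self.ramp_end - self.ramp_start + 1) + self.post


def simulate_henon(cfg: HenonConfig = HenonConfig()) -> tuple[TimeSeries, tuple[int, int]]:
    """Iterate the ramped Hénon map; returns (x series, true transition window).

    The control parameter is ``a_start`` for iterations ``1..ramp_start-1``,
    ``a_start + step * (k - ramp_start)`` inside the ramp (reaching ``a_end``
    at ``ramp_end``), and ``a_end`` afterwards.  The initial condition
    ``(x0, y0)`` is not part of the returned series.
    """
    x, y = cfg.x0, cfg.y0
    out = np.empty(cfg.length)
    for k in range(1, cfg.length + 1):
        if k < cfg.ramp_start:
            a = cfg.a_start
        elif k <= cfg.ramp_end:
            a = cfg.a_start + cfg.step * (k - cfg.ramp_start)
        else:
            a = cfg.a_end
        x, y = y + 1.0 - a * x * x, cfg.b * x
        if abs(x) > 1e6:
            raise FloatingPointError(f"Hénon orbit diverged at iteration {k}")
        out[k - 1] = x
    return TimeSeries(out, label="henon_x"), (cfg.ramp_start, cfg.ramp_end)


@dataclass(frozen=True)
class RegimeShiftConfig:
    """Piecewise stochastic process whose parameters ramp across a window.

    Effects are expressed relative to the baseline noise SD: the baseline is
    unit-variance Gaussian white noise, a mean shift of 3 means three noise
    SDs, and a variance shift of 4 means the noise SD quadruples.  The
    frequency kind adds a sinusoid of constant amplitude whose frequency
    ramps — a transition invisible to mean/variance statistics.  The pattern
    kind ramps an AR(1) coefficient with variance-stabilized innovations, so
    only the autocorrelation structure changes.
    """

    length: int = 300
    window: tuple[int, int] = (150, 160)
    kinds: tuple[ShiftKind, ...] = ("mean",)
    mean_shift: float = 3.0        # in units of noise_sd
    sd_ratio: float = 4.0          # post/pre noise SD
    freq_start: float = 0.05       # cycles/sample
    freq_end: float = 0.20
    amplitude: float = 2.0         # sinusoid amplitude, in units of noise_sd
    ar_start: float = 0.0
    ar_end: float = 0.8
    noise_sd: float = 1.0
    n_components: int = 1
    coupling_start: float = 0.0    # shared-factor loading before the window
    coupling_end: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        t1, t2 = self.window
        if not (1 <= t1 < t2 <= self.length):
            raise ValueError(f"invalid transition window {self.window}")
        unknown = set(self.kinds) - _VALID_KINDS
        if unknown:
            raise ValueError(f"unknown shift kind(s): {sorted(unknown)}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass(frozen=True)
class RegimeShift:
    """Simulator output: primary series, optional components, truth window."""

    series: TimeSeries
    components: Optional[MultiSeries]
    window: tuple[int, int]


def _ramp(cfg: RegimeShiftConfig) -> np.ndarray:
    """0 before the window, 1 after, linear inside; index k = time k+1."""
    t = np.arange(1, cfg.length + 1, dtype=float)
    t1, t2 = cfg.window
    return np.clip((t - t1) / (t2 - t1), 0.0, 1.0)


def _ar1(eta: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """AR(1) with time-varying coefficient and unit marginal variance."""
    e = np.empty_like(eta)
    prev = eta[0]
    e[0] = prev
    for i in range(1, eta.size):
        r = rho[i]
        prev = r * prev + np.sqrt(max(1.0 - r * r, 0.0)) * eta[i]
        e[i] = prev
    return e


def simulate_regime_shift(cfg: RegimeShiftConfig = RegimeShiftConfig()) -> RegimeShift:
    """Generate a seeded regime-shift realization with known truth window."""
    rng = np.random.default_rng(cfg.seed)
    ramp = _ramp(cfg)

    mu = cfg.mean_shift * cfg.noise_sd * ramp if "mean" in cfg.kinds else np.zeros(cfg.length)
    sd = cfg.noise_sd * (1.0 + (cfg.sd_ratio - 1.0) * ramp) if "variance" in cfg.kinds \
        else np.full(cfg.length, cfg.noise_sd)
    rho = cfg.ar_start + (cfg.ar_end - cfg.ar_start) * ramp if "pattern" in cfg.kinds \
        else np.zeros(cfg.length)

    signal = np.zeros(cfg.length)
    if "frequency" in cfg.kinds:
        freq = cfg.freq_start + (cfg.freq_end - cfg.freq_start) * ramp
        phase = 2.0 * np.pi * np.cumsum(freq) + rng.uniform(0, 2 * np.pi)
        signal = cfg.amplitude * cfg.noise_sd * np.sin(phase)

    if cfg.n_components == 1:
        noise = sd * _ar1(rng.standard_normal(cfg.length), rho)
        series = TimeSeries(mu + signal + noise, label="x")
        return RegimeShift(series=series, components=None, window=cfg.window)

    lam = cfg.coupling_start + (cfg.coupling_end - cfg.coupling_start) * ramp
    shared = rng.standard_normal(cfg.length)
    cols = []
    for v in range(cfg.n_components):
        eta = rng.standard_normal(cfg.length)
        unit = np.sqrt(np.maximum(1.0 - lam * lam, 0.0)) * _ar1(eta, rho) + lam * shared
        cols.append(unit)
    components = MultiSeries(tuple(
        TimeSeries(sd * c, label=f"x{v + 1}") for v, c in enumerate(cols)
    ))
    primary = TimeSeries(mu + signal + sd * cols[0], label="x1")
    return RegimeShift(series=primary, components=components, window=cfg.window)
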