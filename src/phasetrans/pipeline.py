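"""The convergence pipeline: second-order change-point analysis of indicators.

First-order indicators (dynamic complexity, permutation entropy,
instantaneous frequency from the Stockwell transform, synchronization) each
transform the raw series into a new series in which a qualitative transition
appears as a shift of mean or variance.  Change-point analysis is then
applied to the z-scored original series, to every indicator, and to each
indicator's moving-average and moving-variance smoothing; the recurrence
plot contributes its row-wise pooled change point.  All detections are
mapped back to original time coordinates, pooled, summarized by mean and
sample SD, and tested for clustering against uniform-random surrogates.
A transition that several independent detectors localize at the same spot
is credible in a way no single detector's output is.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .changepoint import CpaConfig, detect_mean_and_variance
from .complexity import DcConfig, PeConfig, ScaleRange, dynamic_complexity, permutation_entropy
from .recurrence import EmbeddingConfig, recurrence_matrix, rp_changepoints
from .report import ROW_ORDER, SMOOTHED_ROWS, DetectedPoint, TransitionReport
from .series import (DegenerateSeriesError, DerivedSeries, MultiSeries,
                     TimeSeries, moving_average, moving_variance, z_transform)
from .spectral import instantaneous_frequency, stockwell_transform
from .surrogates import SurrogateConfig, run_tests
from .synchronization import spa


class PipelineError(ValueError):
    """Raised when a pipeline row cannot be computed; names the failing row."""


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults follow routine daily-rating practice.

    Indicator windows are 7 points; the moving average/variance smoothing
    uses 20 points, except 5 for instantaneous frequency; recurrence plots
    use 3-dimensional embedding with delay 1; the change-point penalty is
    1.0 on z-scored data.
    """

    penalty: float = 1.0
    min_segment: int = 2
    dc_window: int = 7
    pe_window: int = 7
    pe_order: int = 3
    spa_window: int = 7
    smooth_window: int = 20
    if_smooth_window: int = 5
    embedding_dim: int = 3
    embedding_delay: int = 1
    scale_range: Optional[tuple[float, float]] = None
    n_surrogate_sets: int = 100
    seed: int = 0
    ci_level: float = 0.95
    disabled_rows: tuple[str, ...] = ()

    def cpa(self) -> CpaConfig:
        return CpaConfig(penalty=self.penalty, min_segment=self.min_segment)

    def surrogate(self) -> SurrogateConfig:
        return SurrogateConfig(n_sets=self.n_surrogate_sets, seed=self.seed,
                               ci_level=self.ci_level)


def _cpa_on_derived(values: np.ndarray, times: np.ndarray,
                    cfg: PipelineConfig) -> list[DetectedPoint]:
    """CPA on an indicator series; NaN (undefined) values are dropped along
    with their time stamps, and detected positions map through the survivors."""
    keep = np.isfinite(values)
    vals, ts = values[keep], times[keep]
    if vals.size < 2 * cfg.min_segment:
        return []
    return [
        DetectedPoint(time=int(ts[cp.index - 1]), statistic=cp.statistic,
                      cost_drop=cp.cost_drop)
        for cp in detect_mean_and_variance(vals, penalty=cfg.penalty,
                                           min_segment=cfg.min_segment)
    ]


def aggregate(points: list[int]) -> tuple[float, float]:
    """Arithmetic mean and sample SD of the pooled change points.

    A single point has undefined SD, reported as 0 (callers flag it).
    """
    if not points:
        raise ValueError("cannot aggregate an empty pool")
    mean = float(np.mean(points))
    sd = float(np.std(points, ddof=1)) if len(points) > 1 else 0.0
    return mean, sd


def _empty_report(n: int, cfg: PipelineConfig, labels: list[str]) -> TransitionReport:
    return TransitionReport(rows={lab: [] for lab in labels}, pooled=[],
                            mean=None, sd=None, surrogate=None,
                            series_length=n, no_detection=True,
                            config=asdict(cfg))


def run_pipeline(
    s: TimeSeries,
    ms: Optional[MultiSeries] = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> TransitionReport:
    """Full second-order analysis of one series (plus optional components).

    ``ms`` supplies the system's component variables for synchronization
    analysis; without it the SPA rows are absent (a univariate series carries
    no inter-variable coherence).  Raises :class:`PipelineError` naming the
    first row whose window chain does not fit the series.
    """
    n = len(s)
    if n < 40:
        raise PipelineError(f"series too short for the pipeline ({n} < 40)")

    labels = [r for r in ROW_ORDER if r not in cfg.disabled_rows]
    if ms is None:
        labels = [r for r in labels if "SPA" not in r]

    if float(np.std(s.values, ddof=1)) == 0.0:
        # A constant series carries no transition; every row is empty.
        return _empty_report(n, cfg, labels)

    z = z_transform(s)
    rows: dict[str, list[DetectedPoint]] = {}

    def add_row(label: str, values: np.ndarray, times: np.ndarray) -> None:
        if label in labels:
            try:
                rows[label] = _cpa_on_derived(values, times, cfg)
            except ValueError as exc:
                raise PipelineError(f"row {label!r} failed: {exc}") from exc

    def smooth_rows(label: str, d: DerivedSeries, w: int) -> None:
        for prefix, op in (("MA of ", moving_average), ("MV of ", moving_variance)):
            name = prefix + label
            if name not in labels:
                continue
            if len(d) < w:
                raise PipelineError(
                    f"row {name!r} failed: indicator length {len(d)} < window {w}")
            sm = op(d, w)
            rows[name] = _cpa_on_derived(sm.values, sm.times, cfg)

    add_row("original", z.values, z.times)

    scale = None if cfg.scale_range is None else ScaleRange(*cfg.scale_range)
    dc = dynamic_complexity(z, DcConfig(window=cfg.dc_window, range=scale))
    add_row("DC", dc.values, dc.times)
    smooth_rows("DC", dc, cfg.smooth_window)

    pe = permutation_entropy(z, PeConfig(window=cfg.pe_window, order=cfg.pe_order))
    add_row("PE", pe.values, pe.times)
    smooth_rows("PE", pe, cfg.smooth_window)

    inst = instantaneous_frequency(stockwell_transform(z))
    add_row("IF", inst.values, inst.times)
    smooth_rows("IF", inst, cfg.if_smooth_window)

    if ms is not None:
        coherence = spa(ms, w=cfg.spa_window)
        add_row("SPA", coherence.values, coherence.times)
        smooth_rows("SPA", coherence, cfg.smooth_window)

    if "RP" in labels:
        rm = recurrence_matrix(z, EmbeddingConfig(dimension=cfg.embedding_dim,
                                                  delay=cfg.embedding_delay))
        rows["RP"] = [DetectedPoint(time=cp.index, statistic=cp.statistic,
                                    cost_drop=cp.cost_drop)
                      for cp in rp_changepoints(rm, cfg.cpa())]

    rows = {lab: rows.get(lab, []) for lab in labels}
    return _finalize(rows, n, cfg)


def _finalize(rows: dict[str, list[DetectedPoint]], n: int,
              cfg: PipelineConfig) -> TransitionReport:
    pooled = sorted(p.time for pts in rows.values() for p in pts)
    if not pooled:
        return TransitionReport(rows=rows, pooled=[], mean=None, sd=None,
                                surrogate=None, series_length=n,
                                no_detection=True, config=asdict(cfg))
    mean, sd = aggregate(pooled)
    surrogate = None
    if len(pooled) >= 2:
        surrogate = run_tests(pooled, n, cfg.surrogate())
    return TransitionReport(rows=rows, pooled=pooled, mean=mean, sd=sd,
                            surrogate=surrogate, series_length=n,
                            no_detection=False,
                            single_point=len(pooled) == 1,
                            config=asdict(cfg))


def oversampling_variant(report: TransitionReport) -> TransitionReport:
    """Re-pool excluding the MA/MV smoothing rows.

    The smoothed rows re-analyze the same indicators, so their detections
    could oversample a transition; this variant checks that the convergence
    verdict survives without them.
    """
    rows = {lab: pts for lab, pts in report.rows.items()
            if lab not in SMOOTHED_ROWS}
    cfg_dict = dict(report.config) or asdict(PipelineConfig())
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in cfg_dict.items()})
    return _finalize(rows, report.series_length, cfg)
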