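"""Transition report container and its JSON/CSV serialization.

A :class:`TransitionReport` is the tabular summary of the second-order
analysis: one row per detector (change-point analysis applied to the
original series, to each indicator, to each indicator's moving
average/variance smoothing, and to the recurrence plot), the pooled list of
all detected change points in original time coordinates, their mean and
sample SD, and the two surrogate dispersion tests.
"""

from __future__ import annotations

import csv as _csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .surrogates import DispersionTest

SCHEMA = "phasetrans-report/1"

ROW_ORDER = [
    "original", "DC", "MA of DC", "MV of DC", "PE", "MA of PE", "MV of PE",
    "IF", "MA of IF", "MV of IF", "SPA", "MA of SPA", "MV of SPA", "RP",
]

SMOOTHED_ROWS = [r for r in ROW_ORDER if r.startswith(("MA of", "MV of"))]


@dataclass(frozen=True)
class DetectedPoint:
    """One detection, already mapped to original time coordinates."""

    time: int
    statistic: str  # 'mean' | 'variance'
    cost_drop: float


@dataclass(frozen=True)
class TransitionReport:
    rows: dict[str, list[DetectedPoint]]
    pooled: list[int]
    mean: Optional[float]
    sd: Optional[float]
    surrogate: Optional[tuple[DispersionTest, DispersionTest]]
    series_length: int
    no_detection: bool = False
    single_point: bool = False
    config: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA,
            "series_length": self.series_length,
            "config": self.config,
            "config_hash": self.config_hash,
            "rows": {label: [asdict(p) for p in pts]
                     for label, pts in self.rows.items()},
            "pooled": list(map(int, self.pooled)),
            "mean": self.mean,
            "sd": self.sd,
            "no_detection": self.no_detection,
            "single_point": self.single_point,
            "surrogate": [asdict(t) for t in self.surrogate]
            if self.surrogate is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionReport":
        surrogate = None
        if d.get("surrogate"):
            surrogate = tuple(
                DispersionTest(statistic=t["statistic"],
                               real_value=t["real_value"],
                               surrogate_mean=t["surrogate_mean"],
                               ci=tuple(t["ci"]),
                               outside_ci=t["outside_ci"])
                for t in d["surrogate"]
            )
        rows = {
            label: [DetectedPoint(**p) for p in pts]
            for label, pts in d["rows"].items()
        }
        return cls(rows=rows, pooled=list(d["pooled"]), mean=d["mean"],
                   sd=d["sd"], surrogate=surrogate,
                   series_length=d["series_length"],
                   no_detection=d.get("no_detection", False),
                   single_point=d.get("single_point", False),
                   config=d.get("config", {}))

    def summary(self) -> str:
        """Human-readable multi-line summary (printed by the CLI)."""
        lines = [f"series length: {self.series_length}"]
        for label in self.rows:
            pts = self.rows[label]
            txt = ", ".join(f"{p.time} ({p.statistic})" for p in pts) or "-"
            lines.append(f"  {label:<10s} {txt}")
        if self.no_detection:
            lines.append("no transition detected")
        else:
            lines.append(f"pooled change points (n={len(self.pooled)}): "
                         f"{sorted(self.pooled)}")
            lines.append(f"pooled mean (SD): {round(self.mean)} "
                         f"({0 if self.sd is None else round(self.sd)})")
        if self.surrogate is not None:
            for t in self.surrogate:
                verdict = "outside" if t.outside_ci else "inside"
                lines.append(
                    f"  {t.statistic}: real {t.real_value:.1f}% vs random "
                    f"{t.surrogate_mean:.1f}% CI [{t.ci[0]:.1f}%, {t.ci[1]:.1f}%]"
                    f" -> {verdict} CI"
                )
        return "\n".join(lines)


def write_report(report: TransitionReport, path: str | Path,
                 format: str = "json") -> None:
    """Serialize a report; JSON is lossless, CSV keeps the change-point table."""
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = _csv.writer(fh)
            w.writerow(["row", "time", "statistic", "cost_drop",
                        "series_length"])
            for label, pts in report.rows.items():
                for p in pts:
                    w.writerow([label, p.time, p.statistic,
                                f"{p.cost_drop:.6g}", report.series_length])
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> TransitionReport:
    """Read a report written by :func:`write_report` (format by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows: dict[str, list[DetectedPoint]] = {}
        length = 0
        with open(path, newline="", encoding="utf-8") as fh:
            for rec in _csv.DictReader(fh):
                rows.setdefault(rec["row"], []).append(DetectedPoint(
                    time=int(rec["time"]), statistic=rec["statistic"],
                    cost_drop=float(rec["cost_drop"])))
                length = int(rec["series_length"])
        pooled = sorted(p.time for pts in rows.values() for p in pts)
        mean = float(np.mean(pooled)) if pooled else None
        sd = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else (
            0.0 if pooled else None)
        return TransitionReport(rows=rows, pooled=pooled, mean=mean, sd=sd,
                                surrogate=None, series_length=length,
                                no_detection=not pooled,
                                single_point=len(pooled) == 1)
    with open(path, encoding="utf-8") as fh:
        return TransitionReport.from_dict(json.load(fh))
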