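"""Serial-variation metrics over articular-facet aspect ratios.

In extant amniotes the aspect ratio of the articular facet changes only
gradually from each vertebra to the next, so any of these quantities is
small; oblique post-mortem crushing perturbs each vertebra independently
and inflates them.  Two summary metrics are computed per column:

* the **difference metric**: the mean absolute difference between the V/H
  aspect ratios of consecutive vertebrae, times 100;
* the **ratio metric**: the mean "absolute ratio" of consecutive V/H
  values — the ratio or its inverse, whichever is >= 1 — minus 1, times 100.

Both are zero for a perfectly uniform column and grow with erratic serial
variation.  All computation uses full-precision raw extents; 3-dp rounding
is applied only when formatting reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, SerialGapError, ValidationError
from .measurements_io import ColumnSeries

__all__ = [
    "AspectRatioSeries",
    "SerialVariationSummary",
    "aspect_ratio",
    "series_ratios",
    "consecutive_diffs",
    "consecutive_abs_ratios",
    "summarize",
]


@dataclass(frozen=True)
class AspectRatioSeries:
    """Per-vertebra V/H aspect ratios for one specimen, in serial order."""

    specimen_id: str
    labels: tuple[str, ...]
    vh: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.vh):
            raise ValidationError("labels and vh must have equal length")
        if any(not v > 0 for v in self.vh):
            raise ValidationError(f"{self.specimen_id}: aspect ratios must be positive")

    def __len__(self) -> int:
        return len(self.vh)


@dataclass(frozen=True)
class SerialVariationSummary:
    """Consecutive diffs/ratios and the two x100 serial-variation metrics."""

    specimen_id: str
    n: int
    first_diffs: tuple[float, ...]
    max_diff: float
    avg_diff: float
    metric_diff_x100: float
    first_ratios: tuple[float, ...]
    max_ratio: float
    avg_ratio: float
    metric_ratio_x100: float

    def to_row(self, decimals: int | None = None) -> dict:
        """Scalar summary cells as a flat dict, optionally rounded.

        Rounding is round-half-even to match the reference table's 3-dp
        display convention.
        """
        row = {
            "specimen_id": self.specimen_id,
            "n": self.n,
            "max_diff": self.max_diff,
            "avg_diff": self.avg_diff,
            "metric_diff_x100": self.metric_diff_x100,
            "max_ratio": self.max_ratio,
            "avg_ratio": self.avg_ratio,
            "metric_ratio_x100": self.metric_ratio_x100,
        }
        if decimals is not None:
            row = {
                k: (round(v, decimals) if isinstance(v, float) else v)
                for k, v in row.items()
            }
        return row


def aspect_ratio(vertical: float, horizontal: float) -> float:
    """V/H aspect ratio of a facet; < 1 means wider than tall."""
    if not vertical > 0 or not horizontal > 0:
        raise ValidationError(
            f"extents must be positive (vertical={vertical}, horizontal={horizontal})"
        )
    return vertical / horizontal


def series_ratios(series: ColumnSeries) -> AspectRatioSeries:
    """Element-wise V/H ratios of a column, order preserved."""
    vh = []
    for m in series.measurements:
        try:
            vh.append(aspect_ratio(m.vertical, m.horizontal))
        except ValidationError as exc:
            raise ValidationError(f"{series.specimen_id} {m.element_label}: {exc}") from exc
    return AspectRatioSeries(
        specimen_id=series.specimen_id, labels=series.labels, vh=tuple(vh)
    )


def _as_vh(ratios: AspectRatioSeries | Sequence[float]) -> np.ndarray:
    vh = np.asarray(ratios.vh if isinstance(ratios, AspectRatioSeries) else ratios, float)
    if vh.size < 2:
        raise InsufficientDataError(
            f"need at least 2 vertebrae, got {vh.size}"
        )
    if not np.all(vh > 0):
        raise ValidationError("aspect ratios must be positive")
    return vh


def consecutive_diffs(ratios: AspectRatioSeries | Sequence[float]) -> list[float]:
    """|V/H[i] - V/H[i+1]| for each consecutive pair (length n-1)."""
    vh = _as_vh(ratios)
    return list(np.abs(np.diff(vh)))


def consecutive_abs_ratios(ratios: AspectRatioSeries | Sequence[float]) -> list[float]:
    """max(r, 1/r) with r = V/H[i] / V/H[i+1], for each pair; every entry >= 1."""
    vh = _as_vh(ratios)
    r = vh[:-1] / vh[1:]
    return list(np.maximum(r, 1.0 / r))


def _check_gaps(series: ColumnSeries, gap_policy: str) -> None:
    if gap_policy not in {"span", "strict"}:
        raise ValidationError(f"unknown gap policy {gap_policy!r}")
    if gap_policy == "span":
        return
    idx = series.serial_indices
    missing = [
        j
        for a, b in zip(idx, idx[1:])
        for j in range(a + 1, b)
    ]
    if missing:
        raise SerialGapError(
            f"{series.specimen_id}: missing serial positions {missing} "
            "under strict gap policy"
        )


def summarize(series: ColumnSeries, gap_policy: str = "span") -> SerialVariationSummary:
    """Both serial-variation metrics for one column, from raw extents.

    ``gap_policy='span'`` (default) treats the next preserved vertebra as
    the successor across any gap in serial position; ``'strict'`` raises
    :class:`SerialGapError` naming the missing positions.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"{series.specimen_id}: need at least 2 vertebrae, got {len(series)}"
        )
    _check_gaps(series, gap_policy)
    vh = series_ratios(series)
    diffs = consecutive_diffs(vh)
    ratios = consecutive_abs_ratios(vh)
    avg_diff = float(np.mean(diffs))
    avg_ratio = float(np.mean(ratios))
    return SerialVariationSummary(
        specimen_id=series.specimen_id,
        n=len(series),
        first_diffs=tuple(diffs),
        max_diff=float(np.max(diffs)),
        avg_diff=avg_diff,
        metric_diff_x100=avg_diff * 100.0,
        first_ratios=tuple(ratios),
        max_ratio=float(np.max(ratios)),
        avg_ratio=avg_ratio,
        metric_ratio_x100=(avg_ratio - 1.0) * 100.0,
    )
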