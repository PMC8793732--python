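"""Elongation indices and crush-aware pairwise comparisons.

The elongation index (EI) of a vertebra is centrum length divided by cotyle
height.  Because oblique crushing reshapes the cotyle, EI is sensitive to
preservation: a dorsoventrally flattened cotyle yields a spuriously high EI.
Two mitigations are provided:

* the **aEI**, which divides centrum length by the mean of cotyle height
  and width and so is partially robust to crushing that trades height for
  width (but not to oblique crushing that inflates both);
* an explicit **crush correction**, which rescales an observed cotyle width
  by the V/H ratio of a better-preserved reference facet to estimate the
  true cotyle height.

The canonical aspect ratio throughout this package is V/H
(vertical/horizontal).  Published figure discussions often quote
width:height; :func:`percent_broader` takes W/H inputs explicitly and
W/H = 1/(V/H).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .measurements_io import ColumnSeries

__all__ = [
    "ElongationRecord",
    "elongation_index",
    "average_elongation_index",
    "corrected_cotyle_height",
    "aspect_ratio_factor",
    "percent_broader",
    "elongation_report",
]


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class ElongationRecord:
    """Elongation indices for one vertebra."""

    element_label: str
    centrum_length: float
    cotyle_height: float
    cotyle_width: float | None = None

    def __post_init__(self) -> None:
        _require_positive(
            centrum_length=self.centrum_length, cotyle_height=self.cotyle_height
        )
        if self.cotyle_width is not None:
            _require_positive(cotyle_width=self.cotyle_width)

    @property
    def ei(self) -> float:
        return elongation_index(self.centrum_length, self.cotyle_height)

    @property
    def aei(self) -> float | None:
        if self.cotyle_width is None:
            return None
        return average_elongation_index(
            self.centrum_length, self.cotyle_height, self.cotyle_width
        )


def elongation_index(centrum_length: float, cotyle_height: float) -> float:
    """EI: centrum length over cotyle height (same units)."""
    _require_positive(centrum_length=centrum_length, cotyle_height=cotyle_height)
    return centrum_length / cotyle_height


def average_elongation_index(
    centrum_length: float, cotyle_height: float, cotyle_width: float
) -> float:
    """aEI: centrum length over the mean of cotyle height and width."""
    _require_positive(
        centrum_length=centrum_length,
        cotyle_height=cotyle_height,
        cotyle_width=cotyle_width,
    )
    return centrum_length / ((cotyle_height + cotyle_width) / 2.0)


def corrected_cotyle_height(observed_width: float, reference_vh: float) -> float:
    """Estimate true cotyle height from observed width and a reference V/H.

    Assumes the vertebra's true cotyle proportions matched those of the
    (caller-chosen) undistorted reference facet: height = width x V/H.
    """
    _require_positive(observed_width=observed_width, reference_vh=reference_vh)
    return observed_width * reference_vh


def aspect_ratio_factor(ratio_a: float, ratio_b: float) -> float:
    """By what factor two facet aspect ratios differ (>= 1, symmetric).

    Both ratios must use the same orientation convention (both V/H or both
    W/H); the result is invariant to jointly inverting them.
    """
    _require_positive(ratio_a=ratio_a, ratio_b=ratio_b)
    r = ratio_a / ratio_b
    return max(r, 1.0 / r)


def percent_broader(wh_a: float, wh_b: float) -> float:
    """How much proportionally broader facet a is than facet b, in percent.

    Inputs are width:height ratios; the result may be negative (a narrower
    than b).
    """
    _require_positive(wh_a=wh_a, wh_b=wh_b)
    return (wh_a / wh_b - 1.0) * 100.0


def elongation_report(
    series: ColumnSeries, reference_label: str | None = None
) -> pd.DataFrame:
    """EI/aEI report for every vertebra in a series with a centrum length.

    When ``reference_label`` names a vertebra in the series, its V/H ratio
    is used to crush-correct every other vertebra's cotyle height (and EI).
    Columns: element_label, centrum_length, cotyle_height, cotyle_width,
    EI, aEI, corrected_height, corrected_EI, reference_element.
    """
    reference_vh = None
    if reference_label is not None:
        by_label = {m.element_label: m for m in series.measurements}
        if reference_label not in by_label:
            raise ValidationError(
                f"reference element {reference_label!r} not in series "
                f"{series.specimen_id} (has {list(by_label)})"
            )
        ref = by_label[reference_label]
        reference_vh = ref.vertical / ref.horizontal

    rows = []
    for m in series.measurements:
        if m.centrum_length is None:
            continue
        rec = ElongationRecord(
            element_label=m.element_label,
            centrum_length=m.centrum_length,
            cotyle_height=m.vertical,
            cotyle_width=m.horizontal,
        )
        corrected_h = corrected_ei = None
        if reference_vh is not None and m.element_label != reference_label:
            corrected_h = corrected_cotyle_height(m.horizontal, reference_vh)
            corrected_ei = elongation_index(m.centrum_length, corrected_h)
        rows.append(
            {
                "element_label": m.element_label,
                "centrum_length": m.centrum_length,
                "cotyle_height": m.vertical,
                "cotyle_width": m.horizontal,
                "EI": rec.ei,
                "aEI": rec.aei,
                "corrected_height": corrected_h,
                "corrected_EI": corrected_ei,
                "reference_element": reference_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "element_label",
            "centrum_length",
            "cotyle_height",
            "cotyle_width",
            "EI",
            "aEI",
            "corrected_height",
            "corrected_EI",
            "reference_element",
        ],
    )
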