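"""Completeness-catalogue bookkeeping and bracket inference.

A complete neck, in the weak sense used throughout this package, preserves
at least a good part of every cervical vertebra.  Specimens fall into four
categories: complete and described, complete but undescribed, missing only
the atlas, and other near-complete necks.  The bundled catalogue holds the
28 published specimens meeting one of these standards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .measurements_io import load_catalogue_frame

__all__ = [
    "CATEGORIES",
    "CompletenessRecord",
    "CompletenessSummary",
    "read_catalogue",
    "load_catalogue",
    "completeness_summary",
    "species_per_complete_neck",
    "bracket_cervical_count",
]

CATEGORIES = (
    "complete_described",
    "complete_undescribed",
    "missing_atlas",
    "other_near_complete",
)


@dataclass(frozen=True)
class CompletenessRecord:
    specimen_id: str
    taxon: str
    clade: str
    category: str
    cervical_count: int | None = None
    described_in_english: bool | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.specimen_id}: unknown category {self.category!r}"
            )
        if self.cervical_count is not None and self.cervical_count < 1:
            raise ValidationError(
                f"{self.specimen_id}: cervical_count must be >= 1"
            )


@dataclass(frozen=True)
class CompletenessSummary:
    """Per-category totals and per-clade breakdown; totals are consistent."""

    by_category: dict[str, int]
    by_clade: dict[str, dict[str, int]]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": clade, **{c: counts.get(c, 0) for c in CATEGORIES},
             "total": sum(counts.values())}
            for clade, counts in sorted(self.by_clade.items())
        ]
        rows.append(
            {"clade": "TOTAL", **self.by_category, "total": self.total}
        )
        return pd.DataFrame(rows)


def _records_from_frame(df: pd.DataFrame) -> list[CompletenessRecord]:
    records = []
    for row in df.itertuples():
        count = row.cervical_count
        described = row.described_in_english
        records.append(
            CompletenessRecord(
                specimen_id=str(row.specimen_id),
                taxon=str(row.taxon),
                clade=str(row.clade),
                category=str(row.category),
                cervical_count=None if pd.isna(count) else int(count),
                described_in_english=None if pd.isna(described) else bool(described),
                notes="" if pd.isna(row.notes) else str(row.notes),
            )
        )
    return records


def read_catalogue(path: str | Path) -> list[CompletenessRecord]:
    """Read a completeness catalogue CSV."""
    return _records_from_frame(pd.read_csv(path, dtype={"specimen_id": str}))


def load_catalogue() -> list[CompletenessRecord]:
    """The bundled catalogue of the 28 complete / near-complete necks."""
    return _records_from_frame(load_catalogue_frame())


def completeness_summary(records: list[CompletenessRecord]) -> CompletenessSummary:
    """Counts by category and by clade; the grand total equals len(records)."""
    by_category = {c: 0 for c in CATEGORIES}
    by_clade: dict[str, dict[str, int]] = {}
    for r in records:
        by_category[r.category] += 1
        clade = by_clade.setdefault(r.clade, {})
        clade[r.category] = clade.get(r.category, 0) + 1
    return CompletenessSummary(
        by_category=by_category, by_clade=by_clade, total=len(records)
    )


def species_per_complete_neck(n_species: int, n_complete: int) -> int:
    """How many known species there are per complete neck (nearest integer)."""
    if n_species < 1 or n_complete < 1:
        raise ValidationError("both counts must be >= 1")
    return round(n_species / n_complete)


def bracket_cervical_count(count_a: int, count_b: int) -> tuple[int, int]:
    """Parsimonious cervical-count range for a taxon bracketed by two relatives.

    The two-taxon min-max heuristic: if both bracketing relatives' counts
    are known, the bracketed taxon most parsimoniously falls within their
    inclusive range.  Symmetric in its arguments.
    """
    if count_a < 1 or count_b < 1:
        raise ValidationError("cervical counts must be >= 1")
    return (min(count_a, count_b), max(count_a, count_b))
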