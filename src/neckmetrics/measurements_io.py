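"""Measurement data model, CSV schema, and bundled reference fixtures.

The unit of analysis is the :class:`ColumnSeries`: an ordered run of
articular-facet measurements along one vertebral column.  Each vertebra
carries the vertical and horizontal extent of one articular facet (the
cotyle for opisthocoelous vertebrae, the anterior facet for procoelous
ones), in units that are arbitrary but consistent within a specimen.

The CSV schema (UTF-8, header row) is::

    specimen_id,taxon,element_label,serial_index,region,facet,convention,
    vertical,horizontal,centrum_length,units

``centrum_length`` may be empty.  ``region`` is ``cervical`` or ``dorsal``,
``facet`` is ``posterior`` or ``anterior``, and ``convention`` records
whether extents are midline or maximum distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FixtureLookupError, ValidationError

__all__ = [
    "VertebralMeasurement",
    "ColumnSeries",
    "read_measurements",
    "write_measurements",
    "load_fixture",
    "load_all_fixtures",
    "load_printed_summary",
    "load_printed_rows",
    "load_figure_pixels",
    "load_elongation_example",
    "load_catalogue_frame",
    "FIXTURE_NAMES",
    "CSV_COLUMNS",
]

REGIONS = frozenset({"cervical", "dorsal"})
FACETS = frozenset({"posterior", "anterior"})
CONVENTIONS = frozenset({"midline", "maximum"})

CSV_COLUMNS = [
    "specimen_id",
    "taxon",
    "element_label",
    "serial_index",
    "region",
    "facet",
    "convention",
    "vertical",
    "horizontal",
    "centrum_length",
    "units",
]

#: Mapping from public fixture names to specimen_id values in table1.csv.
FIXTURE_NAMES = {
    "giraffe": "giraffe",
    "monitor": "monitor",
    "alligator": "alligator",
    "ostrich": "ostrich",
    "diplodocus_cm84": "CM 84",
    "giraffatitan_mbr2180": "MB.R.2180",
}


@dataclass(frozen=True)
class VertebralMeasurement:
    """One vertebra's facet extents plus identity metadata.

    ``vertical`` and ``horizontal`` are the dorsoventral and mediolateral
    extents of the measured articular facet; their ratio V/H is the facet
    aspect ratio (< 1 means wider than tall).  ``centrum_length`` is the
    anteroposterior centrum length in the same units, when available.
    """

    specimen_id: str
    taxon: str
    element_label: str
    serial_index: int
    region: str
    facet: str
    convention: str
    vertical: float
    horizontal: float
    centrum_length: float | None = None
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.serial_index < 1:
            raise ValidationError(
                f"{self.specimen_id} {self.element_label}: serial_index must be >= 1"
            )
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.facet not in FACETS:
            raise ValidationError(f"unknown facet {self.facet!r}")
        if self.convention not in CONVENTIONS:
            raise ValidationError(f"unknown convention {self.convention!r}")
        if not self.vertical > 0 or not self.horizontal > 0:
            raise ValidationError(
                f"{self.specimen_id} {self.element_label}: extents must be positive "
                f"(vertical={self.vertical}, horizontal={self.horizontal})"
            )
        if self.centrum_length is not None and not self.centrum_length > 0:
            raise ValidationError(
                f"{self.specimen_id} {self.element_label}: centrum_length must be positive"
            )
        prefix = self.element_label[:1].upper()
        expected = {"cervical": "C", "dorsal": "D"}[self.region]
        if prefix != expected:
            raise ValidationError(
                f"{self.specimen_id} {self.element_label}: label prefix does not "
                f"match region {self.region!r}"
            )

    @property
    def cotyle_width(self) -> float:
        """Alias of ``horizontal`` when the measured facet is a cotyle."""
        return self.horizontal

    @property
    def vh(self) -> float:
        return self.vertical / self.horizontal


@dataclass(frozen=True)
class ColumnSeries:
    """Ordered measurements along one specimen's vertebral column."""

    specimen_id: str
    taxon: str
    measurements: tuple[VertebralMeasurement, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if not self.measurements:
            raise ValidationError(f"{self.specimen_id}: empty series")
        idx = [m.serial_index for m in self.measurements]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"{self.specimen_id}: serial_index must be strictly increasing, got {idx}"
            )
        allow_mixed = bool(self.meta.get("allow_mixed_facets", False))
        if not allow_mixed:
            facets = {m.facet for m in self.measurements}
            conventions = {m.convention for m in self.measurements}
            if len(facets) > 1 or len(conventions) > 1:
                raise ValidationError(
                    f"{self.specimen_id}: mixed facet/convention values "
                    f"({sorted(facets)}, {sorted(conventions)}); set the "
                    "allow_mixed_facets override to permit this"
                )

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.element_label for m in self.measurements)

    @property
    def serial_indices(self) -> tuple[int, ...]:
        return tuple(m.serial_index for m in self.measurements)

    def rescaled(self, factor: float) -> "ColumnSeries":
        """Return a copy with every length multiplied by ``factor`` (> 0)."""
        if not factor > 0:
            raise ValidationError("rescale factor must be positive")
        return replace(
            self,
            measurements=tuple(
                replace(
                    m,
                    vertical=m.vertical * factor,
                    horizontal=m.horizontal * factor,
                    centrum_length=None
                    if m.centrum_length is None
                    else m.centrum_length * factor,
                )
                for m in self.measurements
            ),
        )


def _series_from_frame(df: pd.DataFrame, allow_mixed_facets: bool) -> list[ColumnSeries]:
    series: list[ColumnSeries] = []
    for specimen_id in sorted(df["specimen_id"].unique()):
        block = df[df["specimen_id"] == specimen_id].sort_values("serial_index")
        dup = block["serial_index"].duplicated()
        if dup.any():
            dupes = sorted(block.loc[dup, "serial_index"].astype(int))
            raise ValidationError(
                f"{specimen_id}: duplicate serial_index values {dupes}"
            )
        meta = {"allow_mixed_facets": True} if allow_mixed_facets else {}
        measurements = []
        for row in block.itertuples():
            cl = row.centrum_length
            measurements.append(
                VertebralMeasurement(
                    specimen_id=str(row.specimen_id),
                    taxon=str(row.taxon),
                    element_label=str(row.element_label),
                    serial_index=int(row.serial_index),
                    region=str(row.region),
                    facet=str(row.facet),
                    convention=str(row.convention),
                    vertical=float(row.vertical),
                    horizontal=float(row.horizontal),
                    centrum_length=None if pd.isna(cl) else float(cl),
                    units=str(row.units),
                )
            )
        series.append(
            ColumnSeries(
                specimen_id=specimen_id,
                taxon=measurements[0].taxon,
                measurements=tuple(measurements),
                meta=meta,
            )
        )
    return series


def read_measurements(
    path: str | Path, *, allow_mixed_facets: bool = False
) -> list[ColumnSeries]:
    """Read a measurement CSV into one :class:`ColumnSeries` per specimen.

    Series are returned sorted by ``specimen_id`` and measurements sorted by
    ``serial_index``, so output ordering is independent of input row order.
    Raises :class:`ValidationError` for non-positive extents, duplicate
    serial positions, or mixed facet values without the override.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "element_label": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        if not row.vertical > 0 or not row.horizontal > 0:
            raise ValidationError(
                f"{path} line {i} ({row.specimen_id} {row.element_label}): "
                "non-positive extent"
            )
    return _series_from_frame(df, allow_mixed_facets)


def series_to_frame(series: Iterable[ColumnSeries]) -> pd.DataFrame:
    rows = [
        {
            "specimen_id": m.specimen_id,
            "taxon": m.taxon,
            "element_label": m.element_label,
            "serial_index": m.serial_index,
            "region": m.region,
            "facet": m.facet,
            "convention": m.convention,
            "vertical": m.vertical,
            "horizontal": m.horizontal,
            "centrum_length": m.centrum_length,
            "units": m.units,
        }
        for s in series
        for m in s.measurements
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_measurements(series: Sequence[ColumnSeries], path: str | Path) -> None:
    """Write series to the measurement CSV schema (round-trips losslessly)."""
    series_to_frame(series).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("neckmetrics.data").joinpath(name)


def _read_bundled(name: str, **kwargs) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, **kwargs)


def load_all_fixtures() -> dict[str, ColumnSeries]:
    """All six bundled reference columns, keyed by public fixture name."""
    with resources.as_file(_data_path("table1.csv")) as p:
        series = read_measurements(p, allow_mixed_facets=True)
    by_id = {s.specimen_id: s for s in series}
    return {name: by_id[sid] for name, sid in FIXTURE_NAMES.items()}


def load_fixture(name: str) -> ColumnSeries:
    """Load one bundled reference column by name.

    Valid names: giraffe, monitor, alligator, ostrich, diplodocus_cm84,
    giraffatitan_mbr2180.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {sorted(FIXTURE_NAMES)}"
        )
    return load_all_fixtures()[name]


def load_printed_summary() -> pd.DataFrame:
    """Printed per-specimen summary cells (3 dp) of the reference table."""
    return _read_bundled("table1_printed_summary.csv", dtype={"specimen_id": str})


def load_printed_rows() -> pd.DataFrame:
    """Printed per-vertebra V/H, 1st-diff and 1st-ratio cells."""
    return _read_bundled("table1_printed_rows.csv", dtype={"specimen_id": str})


def load_figure_pixels() -> pd.DataFrame:
    """Pixel measurements of cotyles taken from published images."""
    return _read_bundled("figure_pixels.csv", dtype={"specimen_id": str})


def load_elongation_example() -> pd.DataFrame:
    """Centrum length / cotyle dimensions (cm) for the worked EI correction."""
    return _read_bundled("giraffatitan_elongation.csv", dtype={"specimen_id": str})


def load_catalogue_frame() -> pd.DataFrame:
    """The bundled completeness catalogue as a raw DataFrame."""
    return _read_bundled("catalogue.csv", dtype={"specimen_id": str})
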