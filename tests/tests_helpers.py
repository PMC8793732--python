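"""Small programmatically generated CSV inputs shared by the CLI tests."""

from neckmetrics.measurements_io import ColumnSeries, VertebralMeasurement, write_measurements


def _vert(label, idx, v, h, centrum=None, specimen="pair"):
    return VertebralMeasurement(
        specimen_id=specimen,
        taxon="test",
        element_label=label,
        serial_index=idx,
        region="cervical",
        facet="posterior",
        convention="midline",
        vertical=v,
        horizontal=h,
        centrum_length=centrum,
    )


def two_vertebra_csv(tmp_path):
    path = tmp_path / "two.csv"
    series = ColumnSeries("pair", "test", (_vert("C2", 2, 10, 12), _vert("C3", 3, 11, 12)))
    write_measurements([series], path)
    return path


def gappy_csv(tmp_path):
    path = tmp_path / "gappy.csv"
    series = ColumnSeries("pair", "test", (_vert("C2", 2, 10, 12), _vert("C6", 6, 11, 12)))
    write_measurements([series], path)
    return path


def mixed_facet_csv(tmp_path):
    path = tmp_path / "mixed.csv"
    series = ColumnSeries(
        "pair",
        "test",
        (_vert("C2", 2, 10, 12),
         VertebralMeasurement(
             specimen_id="pair", taxon="test", element_label="C3", serial_index=3,
             region="cervical", facet="anterior", convention="midline",
             vertical=11, horizontal=12)),
        meta={"allow_mixed_facets": True},
    )
    write_measurements([series], path)
    return path


def elongation_csv(tmp_path):
    path = tmp_path / "elong.csv"
    series = ColumnSeries(
        "pair",
        "test",
        (_vert("C4", 4, 13.8, 13.225, centrum=45.7), _vert("C6", 6, 15.0, 22.1, centrum=69.1)),
    )
    write_measurements([series], path)
    return path
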