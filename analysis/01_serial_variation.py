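#!/usr/bin/env python
"""Recompute the serial-variation metrics for all six reference columns.

Writes the per-specimen summary table and the cell-by-cell verification
against the printed reference values to results/, and prints the headline
finding: both fossil sauropod columns exceed every extant column on both
metrics, so their facet aspect ratios vary far more erratically than
biology allows — the fingerprint of taphonomic crushing.
"""

from pathlib import Path

from neckmetrics import RunConfig, load_all_fixtures, run_metrics
from neckmetrics.report import reproduce_table1

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    fixtures = load_all_fixtures()
    table = run_metrics(list(fixtures.values()), RunConfig(report_decimals=3))
    table.to_csv(RESULTS / "serial_variation_summaries.csv", index=False)
    print(table.to_string(index=False))

    verification = reproduce_table1()
    verification.cells.to_csv(RESULTS / "table1_verification.csv", index=False)
    print(
        f"\n{len(verification.cells)} printed cells rechecked from raw extents: "
        f"{len(verification.failures)} outside ±{verification.tolerance}."
    )
    print(
        "Sauropods exceed all extant columns on both metrics: "
        f"{'yes' if verification.ordering_holds else 'NO'}"
    )


if __name__ == "__main__":
    main()
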