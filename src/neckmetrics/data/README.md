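# Bundled reference data

All files are small plain-text CSV transcriptions of published comparative
measurements of vertebral columns; they are the package's reference fixtures.

- `table1.csv` — raw vertical/horizontal articular-facet extents for six
  columns: giraffe C2–C7, savannah monitor C3–C7, alligator C5–D2 (the one
  mixed cervical/dorsal series; its procoelous vertebrae were measured on the
  anterior facet, all others on the posterior), ostrich C5–C11 (maximum
  rather than midline extents, because of the saddle-shaped facets),
  *Diplodocus carnegii* CM 84 C2–C15, and *Giraffatitan brancai* MB.R.2180
  C2–C7. Units are arbitrary but consistent within a specimen (mm or image
  pixels). Provenance notes: the source table heads the *Diplodocus* block
  "CM 82", an apparent slip for the holotype number CM 84 used everywhere
  else; the fixture uses "CM 84".
- `table1_printed_summary.csv` — the summary cells as printed in the source
  table (3 dp), used by the `reproduce-table1` verification mode. One cell is
  corrected: the *Diplodocus* max-ratio cell prints 1.139 in the source, but
  the table's own 1st-ratio column (and recomputation from the raw
  measurements) gives 1.361 for the C13→C14 pair; the corrected value is
  stored and the `note` column flags it.
- `table1_printed_rows.csv` — the per-vertebra printed V/H, 1st-diff and
  1st-ratio cells (blank on each specimen's last row).
- `figure_pixels.csv` — pixel measurements of cotyle width/height taken from
  published photographs/plates of *Giraffatitan* MB.R.2180 C4 and C6 and
  *Diplodocus* CM 84 C13 and C14. These deliberately differ from the
  `table1.csv` values for the same elements (different images, different
  measurement sessions) and are kept as a separate, provenance-tagged
  fixture.
- `giraffatitan_elongation.csv` — centrum length and cotyle height (and,
  for C6, cotyle width) of MB.R.2180 C4 and C6 in cm, the worked example for
  the crush-corrected elongation index.
- `catalogue.csv` — the 28 complete and near-complete sauropod neck
  specimens with completeness categories. Clade labels follow the running
  text of the source survey and are curator-entered, not printed values;
  cervical counts are filled only where the survey states them.
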