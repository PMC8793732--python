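# Methods

## Serial-variation metrics

The unit of analysis is a `ColumnSeries`: an ordered run of per-vertebra
facet measurements for one specimen, with strictly increasing serial
indices. For each consecutive pair of aspect ratios rᵢ = Vᵢ/Hᵢ the package
computes the absolute difference |rᵢ − rᵢ₊₁| and the "absolute ratio"
max(rᵢ/rᵢ₊₁, rᵢ₊₁/rᵢ) ≥ 1, and summarizes a column by the mean of each,
rescaled for readability (×100, and −1 then ×100 respectively). Both
summaries are zero if and only if the aspect-ratio series is constant,
scale-invariant under joint rescaling of all extents (ratios are unit
free), and invariant under reversing the serial order (max and mean of the
pairwise quantities are direction-blind; the pairwise diff is symmetric
and the absolute ratio normalizes direction away).

All computation uses the full-precision raw extents. The bundled reference
table prints V/H and the pairwise columns at 3 dp; recomputation from raw
integers reproduces every printed cell to within ±0.005 (half a printing
unit), which is also the default tolerance of the `reproduce-table1`
verification mode. Report rounding is round-half-even at 3 dp, matching
the reference table's apparent convention. One printed summary cell is
internally inconsistent with its own table (a max-of-column cell that does
not equal the maximum of the printed column entries); the bundled
printed-values fixture stores the value implied by the table's own column,
with a note flagging the substitution.

**Gap policy.** Fossil series may lack intermediate vertebrae. The default
`span` policy treats the next *preserved* vertebra as the successor, which
matches how the reference columns were scored (each is an uninterrupted
preserved run, one of them spanning the cervicodorsal junction). The
`strict` policy instead raises an error naming the missing serial
positions, for workflows where silent spanning would bias the metric
downward-or-upward unpredictably. The one mixed cervical/dorsal reference
series (alligator C5–D2) includes the junction pair in the metrics; there
is no special-casing of the junction.

Series of length 2 are legal (one pair); length < 2 is an error rather
than a zero, since a zero would be indistinguishable from a genuinely
uniform column.

## Elongation indices and crush correction

EI = centrum length / cotyle height (the definition in current use for
sauropod cervicals; older competing definitions are not implemented). aEI
divides by the mean of cotyle height and width instead, which cancels
crushing that trades height for width but not oblique crushing that
inflates both. The explicit correction `corrected_cotyle_height(w, r)` =
w × r assumes the vertebra's true facet proportions equalled those of a
caller-chosen, better-preserved reference facet; the reference is supplied
by the caller deliberately — choosing which facet is "undistorted enough"
is a judgement the package does not automate.

Orientation conventions: the canonical aspect ratio throughout the package
is V/H. Published figure discussions usually quote width:height, so the
pairwise comparison `percent_broader` takes W/H inputs explicitly
(W/H = 1/(V/H)); `aspect_ratio_factor` is symmetric and invariant to
jointly inverting both inputs, so either convention works as long as it is
consistent.

## The crushing model

No standard parametric model exists for compaction crushing of a thin
elliptical facet, so the package defines a minimal two-parameter family.
A facet is an ellipse with semi-axes (width/2, height/2). Crushing is the
linear map M = R(θ)·diag(k^(−γ), k)·R(−θ): uniaxial compression by factor
k ∈ (0, 1] along an axis at angle θ (degrees, counterclockwise from the
vertical; at θ = 0 the vertical extent is scaled by k), with the
perpendicular axis responding by k^(−γ). The exponent γ ∈ [0, 1]
interpolates between the two regimes seen in real material: γ = 0 is pure
volume-loss compression (porous bone collapsing into internal air space;
M is then a metric contraction with singular values {k, 1}), and γ = 1 is
area-preserving plastic flow (|det M| = k^(1−γ) = 1), under which oblique
crushing *inflates both* apparent height and width — e.g. a circular facet
crushed at 45° with k = 0.5 gains ≈ 46% in both axis-aligned extents.
This is precisely the regime that makes the aEI unreliable.

Apparent extents are the axis-aligned bounding extents of the mapped
ellipse — what a caliper or an on-screen pixel measurement records on a
distorted facet — not the mapped principal axes. They are computed exactly
by the support-function rule: the extent of the ellipse {Bu : ‖u‖ = 1}
along a unit direction e is 2‖Bᵀe‖, with B = M·diag(width/2, height/2).
Tests check this against a dense boundary-sampling oracle.

**A sharp limit of the contraction intuition.** At γ = 0 the map is a
metric contraction, so the mapped ellipse's *diameter* never exceeds the
original's, and its area shrinks by k. But the individual axis-aligned
extents are *not* unconditionally non-increasing: tilting a strongly
anisotropic ellipse projects its long axis onto the short direction. Let
ρ = height/width. Working through the support function, the horizontal
extent is non-increasing for every θ iff ρ² ≤ 2/(1−k), and the vertical
extent iff (1/ρ)² ≤ 2/(1−k). Within the regime the generator emulates —
facet V/H in roughly [0.5, 2], k ≥ 0.5 — the condition holds with margin,
and the contraction property is asserted there (10⁴ random sections in the
acceptance-level test); the unconditional statements (diameter and area)
are tested separately without any restriction.

**θ convention.** θ is drawn uniform on [0, 180) when randomized; the map
is invariant under θ → θ + 180°, and because the uniform draw is rotation
symmetric, measuring θ from the vertical rather than the horizontal axis
has no distributional consequence.

## The synthetic-column generator

`TrueColumnModel` emits the null hypothesis for an undistorted neck:
aspect ratios following a smooth monotone trend (linear or geometric)
between `vh_start` and `vh_end` — the signature expected from gradual
mechanical influences such as a neck broadening toward its base — with
small multiplicative lognormal jitter (`noise_sd`, default 1%) for
biological individuality, and facet heights growing linearly along the
column. Defaults (n = 14, V/H 0.85 → 0.90, heights 30 → 160 arbitrary
units) emulate a long sauropod-like cervical series at the scale of the
bundled diplodocid column. Centrum lengths are not generated and crushing
leaves them unchanged: the model operates on the facet plane only, and
anteroposterior shortening is a separate, rarer distortion mode.

What the generator deliberately does *not* emulate: real serial trends
need not be monotone overall (the reference extant columns wobble a few
percent); facets are not true ellipses; crushing of adjacent in-matrix
vertebrae is spatially correlated rather than independent; and shear/
torsion modes are excluded. Passing the discrimination experiment
therefore shows that the metrics separate *independent random oblique
crushing* from *smooth serial structure*, not that they classify any real
specimen.

`discrimination_experiment` draws, per replicate, a fresh jittered column
and an independently crushed copy, and reports the fraction of replicates
in which the crushed column scores strictly higher. Seeding: the two
user-facing seeds (model, intensity) feed one `SeedSequence`, which spawns
one child per replicate and two grandchildren (generation, crushing) per
child; all derived seeds are reduced below 2³¹. Under the default
conditions (k ~ U(0.7, 1.0), γ = 1, 200 replicates) the crushed column
exceeds the uncrushed on the difference metric in 100% of replicates
(mean ≈ 28 vs ≈ 1.0), comfortably above the ≥ 95% bar frozen in the test
from a pilot run.

## Catalogue

Completeness uses the weak field sense — at least a good part of every
cervical is present — in four categories: complete and described,
complete but undescribed, missing only the atlas, other near-complete.
The bundled catalogue holds the 28 published specimens meeting one of
these standards; clade labels are curator-entered free text following the
source survey's running text (no taxonomy service), and cervical counts
are recorded only where stated. The rarity statistic divides known species
by complete-described necks and rounds to the nearest integer.
Phylogenetic bracketing is the two-taxon min–max heuristic only: the
inclusive range of the two bracketing taxa's counts, symmetric in its
arguments; no tree-based ancestral-state reconstruction is attempted.

## Numerical and interface choices

- Validation is eager: frozen dataclasses check invariants at
  construction, and CSV readers report the offending file line.
- `read_measurements` sorts specimens by id and vertebrae by serial index,
  so results are independent of input row order; duplicate serial
  positions are an error, not a silent overwrite.
- Within-series facet/convention mixing requires an explicit override
  (one reference series legitimately mixes regions, none mixes facets).
- CLI exit codes: 0 success, 1 validation/verification failure, 2 usage.
  JSON reports use a stable `{meta, rows}` schema with no timestamps, so
  identical inputs and seed give byte-identical outputs.
- Problem sizes in tests and drivers (200 Monte-Carlo replicates, 10⁴
  random sections, 4 × 10⁴-point boundary oracles) were chosen as the
  smallest sizes at which the stochastic assertions are stable across
  seeds.

## Known limitations

The crushing model is two-dimensional and per-vertebra independent; it
cannot represent shear, torsion, or correlated deformation of articulated
runs. The metrics quantify distortion only through facet aspect ratio, so
crushing that happens to preserve the ratio (axis-aligned with γ = 0.5,
say) is invisible to them. The catalogue encodes specimen-level
categories, not per-vertebra damage, and its clade labels are editorial.
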